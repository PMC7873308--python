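import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagenet.io import make_trait_matrix
from stagenet.network import GREY, ModuleEigengenes, ModulePartition, module_eigengene
from stagenet.synthetic import SyntheticConfig, generate_expression, generate_stage_design
from stagenet.traits import (
    ModuleTraitCorrelation,
    module_trait_correlation,
    ordinal_trait_correlation,
    select_progression_modules,
)


def eigengenes_from(matrix: np.ndarray, samples, names) -> ModuleEigengenes:
    df = pd.DataFrame(matrix, index=samples, columns=names)
    ve = pd.Series(1.0, index=names)
    return ModuleEigengenes(df, ve)


@pytest.fixture()
def design36(four_stage_annotation):
    tm = make_trait_matrix(four_stage_annotation)
    return four_stage_annotation, tm


class TestModuleTraitCorrelation:
    def test_centered_indicator_gives_r_one(self, design36):
        ann, tm = design36
        centered = tm.indicators["cancer"].to_numpy() - tm.indicators["cancer"].mean()
        eig = eigengenes_from(centered[:, None], tm.indicators.index, ["m"])
        mtc = module_trait_correlation(eig, tm)
        assert mtc.r.loc["m", "cancer"] == pytest.approx(1.0, abs=1e-12)
        assert mtc.p.loc["m", "cancer"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profile_r_zero_p_one(self, design36):
        ann, tm = design36
        # sums to zero within every stage block: orthogonal to all indicators
        profile = np.tile([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 0.0], 4)
        eig = eigengenes_from(profile[:, None], tm.indicators.index, ["m"])
        mtc = module_trait_correlation(eig, tm)
        assert np.abs(mtc.r.loc["m"]).max() < 1e-12
        assert np.allclose(mtc.p.loc["m"], 1.0)

    def test_matches_pearsonr_oracle(self, design36):
        ann, tm = design36
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, (36, 3))
        eig = eigengenes_from(scores, tm.indicators.index, ["a", "b", "c"])
        mtc = module_trait_correlation(eig, tm)
        for i, m in enumerate(["a", "b", "c"]):
            for stage in tm.stage_order:
                r, p = stats.pearsonr(scores[:, i], tm.indicators[stage])
                assert mtc.r.loc[m, stage] == pytest.approx(r, abs=1e-10)
                assert mtc.p.loc[m, stage] == pytest.approx(p, abs=1e-10)

    def test_misaligned_samples_rejected(self, design36):
        ann, tm = design36
        eig = eigengenes_from(np.zeros((36, 1)) + np.arange(36)[:, None],
                              list(tm.indicators.index)[::-1], ["m"])
        with pytest.raises(ValueError, match="sample order"):
            module_trait_correlation(eig, tm)


class TestOrdinalCorrelation:
    def test_eigengene_equal_to_ordinal(self, four_stage_annotation):
        ords = four_stage_annotation.ordinal.to_numpy(dtype=float)
        eig = eigengenes_from(ords[:, None], four_stage_annotation.sample_ids, ["m"])
        out = ordinal_trait_correlation(eig, four_stage_annotation)
        assert out.loc["m", "r_ord"] == pytest.approx(1.0, abs=1e-12)

    def test_noisy_ramp_approaches_one(self, four_stage_annotation):
        rng = np.random.default_rng(0)
        means = np.array([-3.0, -1.0, 1.0, 3.0])
        profile = means[four_stage_annotation.ordinal.to_numpy()] + rng.normal(0, 1e-4, 36)
        eig = eigengenes_from(profile[:, None], four_stage_annotation.sample_ids, ["m"])
        out = ordinal_trait_correlation(eig, four_stage_annotation)
        assert out.loc["m", "r_ord"] > 0.99

    def test_single_stage_rejected(self):
        ann = generate_stage_design(3, ["only"])
        eig = eigengenes_from(np.arange(3.0)[:, None], ann.sample_ids, ["m"])
        with pytest.raises(ValueError, match="2 stages"):
            ordinal_trait_correlation(eig, ann)

    def test_planted_progression_modules_have_high_r_ord(self):
        """r_ord >= 0.8 for planted monotone modules across seeds."""
        for seed in range(5):
            cfg = SyntheticConfig(n_shifted_degs=0, seed=seed)
            expr, ann, truth = generate_expression(cfg)
            labels = truth.module_of_gene.replace("background", GREY)
            eig = module_eigengene(expr, ModulePartition(labels, 2, 1.0, 0.0))
            out = ordinal_trait_correlation(eig, ann)
            for m in truth.progression_modules:
                assert out.loc[m, "r_ord"] >= 0.8


def mtc_from_rows(rows: dict[str, tuple], stages) -> ModuleTraitCorrelation:
    r = pd.DataFrame.from_dict(rows, orient="index", columns=stages)
    p = pd.DataFrame(0.5, index=r.index, columns=r.columns)
    return ModuleTraitCorrelation(r, p, n_samples=36)


class TestSelectionRule:
    stages = ["normal", "pancreatitis", "cancer", "metastatic"]

    def test_verdicts_on_canonical_patterns(self):
        mtc = mtc_from_rows(
            {
                "rising": (-0.6, -0.2, 0.3, 0.7),
                "falling": (0.5, 0.2, -0.1, -0.4),
                "zigzag": (-0.6, 0.7, -0.2, 0.3),
            },
            self.stages,
        )
        report = select_progression_modules(mtc, self.stages, epsilon=0.05)
        assert bool(report.loc["rising", "selected"])
        assert not report.loc["falling", "selected"]
        assert not report.loc["zigzag", "selected"]
        assert not report.loc["zigzag", "monotone_within_eps"]

    def test_small_dip_absorbed_by_epsilon(self):
        mtc = mtc_from_rows({"dip": (-0.5, -0.1, -0.13, 0.6)}, self.stages)
        assert select_progression_modules(mtc, self.stages, epsilon=0.05).loc["dip", "selected"]
        assert not select_progression_modules(mtc, self.stages, epsilon=0.0).loc[
            "dip", "selected"
        ]

    def test_monotone_in_epsilon(self):
        rng = np.random.default_rng(4)
        rows = {f"m{i}": tuple(rng.uniform(-0.8, 0.8, 4)) for i in range(40)}
        mtc = mtc_from_rows(rows, self.stages)
        previous: set[str] = set()
        for eps in (0.0, 0.02, 0.05, 0.1, 0.3):
            report = select_progression_modules(mtc, self.stages, epsilon=eps)
            current = set(report.index[report["selected"]])
            assert previous <= current
            previous = current

    def test_ordinal_filter_vetoes_insignificant_trend(self):
        mtc = mtc_from_rows({"rising": (-0.6, -0.2, 0.3, 0.7)}, self.stages)
        ordinal = pd.DataFrame({"r_ord": [0.9], "p_ord": [0.2]}, index=["rising"])
        report = select_progression_modules(
            mtc, self.stages, epsilon=0.05, ordinal=ordinal, alpha=0.05
        )
        assert not report.loc["rising", "selected"]
        assert not report.loc["rising", "ordinal_significant"]

    def test_relabeling_invariance(self):
        rows = {"a": (-0.6, -0.2, 0.3, 0.7), "b": (0.1, 0.2, 0.1, 0.3)}
        renamed = {"x": rows["a"], "y": rows["b"]}
        r1 = select_progression_modules(mtc_from_rows(rows, self.stages), self.stages)
        r2 = select_progression_modules(mtc_from_rows(renamed, self.stages), self.stages)
        assert r1["selected"].tolist() == r2["selected"].tolist()

    def test_fewer_than_two_stages_rejected(self):
        mtc = mtc_from_rows({"m": (0.5,)}, ["only"])
        with pytest.raises(ValueError):
            select_progression_modules(mtc, ["only"])

    def test_selected_modules_have_positive_ordinal_r(self):
        """One-hot selection and the ordinal view agree in sign on data."""
        for seed in range(3):
            cfg = SyntheticConfig(n_shifted_degs=0, seed=seed)
            expr, ann, truth = generate_expression(cfg)
            labels = truth.module_of_gene.replace("background", GREY)
            eig = module_eigengene(expr, ModulePartition(labels, 2, 1.0, 0.0))
            tm = make_trait_matrix(ann, sample_order=list(expr.columns))
            mtc = module_trait_correlation(eig, tm)
            ordinal = ordinal_trait_correlation(eig, ann)
            report = select_progression_modules(mtc, ann.stage_order, ordinal=ordinal)
            for m in report.index[report["selected"]]:
                assert ordinal.loc[m, "r_ord"] > 0
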