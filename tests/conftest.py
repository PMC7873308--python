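import numpy as np
import pandas as pd
import pytest

from stagenet.io import SampleAnnotation
from stagenet.synthetic import SyntheticConfig, generate_expression


@pytest.fixture(scope="session")
def four_stage_annotation() -> SampleAnnotation:
    from stagenet.synthetic import generate_stage_design

    return generate_stage_design(9)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (read-only)."""
    return generate_expression(SyntheticConfig(seed=0))


@pytest.fixture()
def toy_expr() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.normal(8.0, 1.0, (10, 6)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(6)],
    )


@pytest.fixture()
def two_group_annotation() -> SampleAnnotation:
    stages = pd.Series(
        ["a", "a", "a", "b", "b", "b"],
        index=pd.Index([f"s{i}" for i in range(6)], name="sample"),
    )
    return SampleAnnotation(stages, ("a", "b"))
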