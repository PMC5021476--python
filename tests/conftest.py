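import numpy as np
import pandas as pd
import pytest

from mirlink import (
    ExpressionMatrix,
    SampleAnnotation,
    SimulationConfig,
    simulate_expression,
)


@pytest.fixture
def small_annot() -> SampleAnnotation:
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "group": ["cPTC", "cPTC", "fvPTC", "fvPTC"],
                "batch": ["b1", "b1", "b2", "b2"],
            }
        )
    )


@pytest.fixture
def small_matrix(small_annot) -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.uniform(1, 100, size=(6, 4)),
        index=[f"f{i}" for i in range(6)],
        columns=small_annot.sample_ids,
    )
    return ExpressionMatrix(df, "linear")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    return cfg, simulate_expression(cfg)
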