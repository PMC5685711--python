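import numpy as np
import pandas as pd
import pytest

from mirnapanel import CohortDesign, CountMatrix, ExpressionTable, simulate_expression


@pytest.fixture
def small_counts() -> CountMatrix:
    """20 miRNAs x 20 samples (6 healthy / 6 early / 8 advanced) with one
    strongly shifted marker (m01) and one all-or-none marker (m07)."""
    rng = np.random.default_rng(7)
    counts = rng.negative_binomial(4, 0.02, size=(20, 20))
    counts[0, 6:] *= 6                 # m01 elevated in cancer
    counts[6, :6] = 0                  # m07 absent in healthy
    counts[6, 6:] = rng.negative_binomial(4, 0.02, size=14) + 30
    ids = [f"m{i:02d}" for i in range(1, 21)]
    samples = [f"s{i:02d}" for i in range(1, 21)]
    groups = pd.Series(["healthy"] * 6 + ["early"] * 6 + ["advanced"] * 8, index=samples)
    return CountMatrix(pd.DataFrame(counts, index=ids, columns=samples), groups)


@pytest.fixture
def signal_table() -> ExpressionTable:
    """Expression cohort with two informative markers out of six."""
    design = CohortDesign(
        n_healthy=30, n_benign=0, n_early=20, n_advanced=20, n_mirnas=6,
        informative_effects={
            "miR-001": {"early": 2.0, "advanced": 2.0},
            "miR-002": {"early": 1.2, "advanced": 1.2},
        },
        seed=11,
    )
    return simulate_expression(design)[0]


@pytest.fixture
def null_table() -> ExpressionTable:
    design = CohortDesign(n_healthy=30, n_benign=0, n_early=15, n_advanced=15,
                          n_mirnas=4, seed=5)
    return simulate_expression(design)[0]
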