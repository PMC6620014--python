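import numpy as np
import pandas as pd
import pytest

from riskpc import PanelDataset, SimCondition, simulate_study1, simulate_study2


@pytest.fixture(scope="session")
def study1_panel():
    """Moderate study-1 replication with all three effects active."""
    return simulate_study1(SimCondition(1.0, 0.2, 0.2, n=10_000, seed=42))


@pytest.fixture(scope="session")
def study2_panel():
    return simulate_study2(SimCondition(0.4, 0.2, 0.2, gamma=0.6,
                                        n=10_000, seed=7))


@pytest.fixture()
def tiny_panel():
    """Six-record hand-made table for brute-force OLS oracles."""
    rng = np.random.default_rng(5)
    table = pd.DataFrame({
        "outcome": [1.0, 2.5, -0.5, 3.0, 0.0, 1.5],
        "age": [31.0, 45.0, 52.0, 60.0, 71.0, 80.0],
        "sep": rng.standard_normal(6),
        "activity": [0.0, 1.0, 2.0, 0.0, 1.0, 3.0],
    })
    return PanelDataset(table, {"design": "hand-made"})
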