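import numpy as np
import pytest

from scprognosis import (ExpressionMatrix, ScSimConfig, simulate_bulk_survival,
                         simulate_emt_scrnaseq)


@pytest.fixture
def toy_matrix():
    """4 genes x 5 cells with simple integer values."""
    values = np.array([
        [0.0, 1.0, 2.0, 3.0, 4.0],
        [5.0, 5.0, 5.0, 5.0, 5.0],
        [1.0, 0.0, 2.0, 0.0, 3.0],
        [2.0, 4.0, 6.0, 8.0, 10.0],
    ])
    return ExpressionMatrix(values, ["g1", "g2", "g3", "g4"],
                            ["c1", "c2", "c3", "c4", "c5"])


@pytest.fixture(scope="session")
def small_sim():
    """A small EMT simulation shared by the cheaper integration tests."""
    cfg = ScSimConfig(G=120, C=150, n_switch=8, n_hub=2, m=4,
                      dropout_rate=0.2, seed=7)
    return simulate_emt_scrnaseq(cfg)


@pytest.fixture(scope="session")
def null_bulk():
    """Bulk cohort whose survival is independent of every gene."""
    genes = [f"g{i}" for i in range(10)]
    return simulate_bulk_survival(genes, n_samples=500,
                                  effect=np.zeros(10), censor_rate=0.3, seed=3)
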