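import numpy as np
import pytest

from scbiodisc.io import ExpressionTable
from scbiodisc.synthetic import SyntheticSpec, simulate


@pytest.fixture
def tiny_table() -> ExpressionTable:
    counts = np.array([[6, 7, 0], [6, 0, 0], [3, 3, 3]], dtype=float)
    return ExpressionTable(["G1", "G2", "ERCC-1"], ["C1", "C2", "C3"], counts,
                           np.array([False, False, True]))


@pytest.fixture(scope="session")
def three_cluster_dataset():
    """Well-separated three-cluster dataset with markers and spike-ins."""
    return simulate(SyntheticSpec(n_genes=300, n_cells=120, k_clusters=3, seed=42))


def blob_table(centers: np.ndarray, n_per: int, sd: float, seed: int) -> ExpressionTable:
    """Gaussian blobs in count space (shifted positive), genes x cells."""
    rng = np.random.default_rng(seed)
    cols = []
    for c in centers:
        cols.append(rng.normal(c, sd, size=(n_per, len(c))))
    X = np.vstack(cols)  # cells x features
    X = np.maximum(X - X.min() + 1.0, 0.0)
    n_cells, n_feat = X.shape
    return ExpressionTable(
        [f"G{i}" for i in range(n_feat)], [f"C{j}" for j in range(n_cells)], X.T
    )
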