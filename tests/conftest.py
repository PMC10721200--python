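import numpy as np
import pytest

from capchic import BinTable, ContactMatrix, GenomicInterval


def random_symmetric_matrix(
    n: int, rng: np.random.Generator, low: float = 0.5, high: float = 2.0
) -> np.ndarray:
    """Dense symmetric positive matrix with mild decay structure."""
    m = rng.uniform(low, high, size=(n, n))
    m = (m + m.T) / 2
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return m / (1.0 + d)


def as_balanced(values: np.ndarray, resolution: int = 5_000) -> ContactMatrix:
    """Wrap a symmetric array as a single-region balanced ContactMatrix."""
    n = values.shape[0]
    bt = BinTable(resolution, [GenomicInterval("chrT", 0, n * resolution)])
    return ContactMatrix(bt, [values.astype(float)], kind="balanced")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
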