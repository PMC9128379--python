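import numpy as np
import pytest

from dynreconf import CanonicalPartition, TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_connectivity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric non-negative matrix with NaN diagonal (stack convention)."""
    a = np.abs(rng.standard_normal((n, n)))
    conn = 0.5 * (a + a.T)
    np.fill_diagonal(conn, np.nan)
    return conn


def block_connectivity(
    sizes: list[int], within: float, between: float, jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Block-structured connectivity: `within` inside blocks, `between` across."""
    n = sum(sizes)
    codes = np.repeat(np.arange(len(sizes)), sizes)
    conn = np.where(codes[:, None] == codes[None, :], within, between).astype(float)
    if jitter and rng is not None:
        noise = rng.normal(0.0, jitter, (n, n))
        conn = np.abs(conn + 0.5 * (noise + noise.T))
    np.fill_diagonal(conn, np.nan)
    return conn


def block_timeseries(
    rng: np.random.Generator,
    codes_per_volume: np.ndarray,
    rho_w: float = 0.9,
    rho_b: float = 0.05,
    tr: float = 1.0,
) -> TimeSeriesMatrix:
    """Factor-model series whose block membership may change per volume."""
    n, t = codes_per_volume.shape
    k = int(codes_per_volume.max()) + 1
    g0 = rng.standard_normal(t)
    gb = rng.standard_normal((k, t))
    eps = rng.standard_normal((n, t))
    cols = np.arange(t)
    x = (
        np.sqrt(rho_b) * g0[None, :]
        + np.sqrt(rho_w - rho_b) * gb[codes_per_volume, cols[None, :]]
        + np.sqrt(1 - rho_w) * eps
    )
    return TimeSeriesMatrix(values=x, tr_seconds=tr)


@pytest.fixture
def small_partition():
    """12 regions over 3 named networks (4 each)."""
    labels = {f"r{i:03d}": ["A", "B", "C"][i // 4] for i in range(12)}
    return CanonicalPartition(labels=labels, network_names=("A", "B", "C"))
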