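import numpy as np
import pandas as pd
import pytest

from gutkeystone.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset reused by read-only tests."""
    cfg = SimulationConfig(
        cohort_sizes=(150, 180, 160),
        n_genera=80,
        n_keystones=4,
        hub_degree=5,
        seed=11,
    )
    return simulate_cohorts(cfg)


@pytest.fixture()
def toy_counts():
    """4 samples x 5 genera with hand-checkable values."""
    return pd.DataFrame(
        [
            [3, 0, 2, 0, 1],
            [1, 1, 2, 0, 0],
            [0, 0, 5, 5, 0],
            [2, 2, 2, 2, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c", "d", "e"],
    )


def hand_bh(pvals):
    """Independent Benjamini-Hochberg: p*m/rank with a tail cummin."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def power_iteration_centrality(adj: np.ndarray, tol: float = 1e-14) -> np.ndarray:
    """Leading-eigenvector oracle: shifted power iteration, max-normalized."""
    n = adj.shape[0]
    shift = adj.sum() + 1.0  # guarantees the leading eigenvalue is dominant
    m = np.abs(adj) + shift * np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(100000):
        w = m @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            break
        v = w
    v = np.abs(v)
    return v / v.max()
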