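"""Community structure: Bray-Curtis dissimilarity, PCoA, PERMANOVA.

PERMANOVA is computed directly from the distance matrix (Anderson's
formulation via within-group sums of squared distances), with a seeded
permutation RNG and the +1/+1 p-value convention so p is never zero.
Pairwise group comparisons are run on restricted distance submatrices and
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bray_curtis",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "PcoaResult",
    "PermanovaResult",
]


def bray_curtis(table: pd.DataFrame, normalize: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = sum|x_a - x_b| / sum(x_a + x_b).

    Computed on relative abundances by default so that sequencing depth does
    not masquerade as community difference.
    """
    x = table.to_numpy(dtype=float)
    depth = x.sum(axis=1)
    if (depth <= 0).any():
        raise ValueError("all-zero samples present; filter before Bray-Curtis")
    if normalize:
        x = x / depth[:, None]
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in table.index])


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame  # samples x retained axes, sqrt(eigenvalue) scale
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    explained_fraction: np.ndarray  # per retained axis, relative to sum of positive


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Principal coordinate analysis (classical metric scaling).

    Double-centers -0.5 * d^2, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues. Negative eigenvalues are
    reported but never used for coordinates; explained fractions are relative
    to the sum of positive eigenvalues. Axis signs are fixed by forcing each
    axis's largest-magnitude loading positive, so output is deterministic.
    """
    dm = d.data
    n = dm.shape[0]
    b = dm**2
    b = -0.5 * b
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ b @ centerer
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    n_pos = int((evals > 1e-10).sum())
    k = min(n_axes, n_pos)
    if k < n_axes:
        import warnings

        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k} axes", stacklevel=2
        )
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        if coords[np.abs(coords[:, j]).argmax(), j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = evals[evals > 0].sum()
    explained = evals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"PCo{j + 1}" for j in range(k)]
    )
    return PcoaResult(coordinates=frame, eigenvalues=evals, explained_fraction=explained)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from a squared-distance matrix and integer labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    d: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), labels
    permuted with a seeded generator.
    """
    labels = np.asarray(pd.Series(groups).loc[list(d.ids)])
    codes, counts = np.unique(labels, return_counts=True)
    if len(codes) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups each with >= 2 samples")
    d2 = d.data**2
    f_obs, r2 = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_stats(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PermanovaResult(pseudo_F=f_obs, R2=r2, p_value=p, n_permutations=n_permutations)


def pairwise_permanova(
    d: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """One PERMANOVA per group pair on the restricted distance submatrix.

    Returns a tidy frame with BH-adjusted p-values across pairs; a pair is
    called significant at adjusted p < 0.05.
    """
    groups = pd.Series(groups).loc[list(d.ids)]
    codes = sorted(groups.unique())
    rows = []
    rng = np.random.default_rng(seed)
    for i, ga in enumerate(codes):
        for gb in codes[i + 1 :]:
            ids = groups.index[groups.isin([ga, gb])]
            sub = d.filter([str(s) for s in ids])
            res = permanova(
                sub,
                groups.loc[ids],
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "pseudo_F": res.pseudo_F,
                    "R2": res.R2,
                    "p_value": res.p_value,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_adjusted"] < 0.05
    return out
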