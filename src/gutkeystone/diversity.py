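"""Alpha-diversity indices and per-cohort standardization.

Four indices: observed richness (genera with nonzero count), Shannon entropy,
Pielou evenness, and Faith's phylogenetic diversity on a genus tree. Indices
are computed on unrarefied counts; sequencing depth is handled downstream as a
model covariate. Cohort-wise z-scoring puts indices on the SD scale used by
the group-contrast models.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity import alpha_diversity as _skbio_alpha_diversity

__all__ = [
    "observed_richness",
    "shannon",
    "pielou",
    "faith_pd",
    "zscore_by_cohort",
    "alpha_diversity_table",
    "rarefy",
]

_LOG = {"e": np.log, "2": np.log2, "10": np.log10}


def observed_richness(table: pd.DataFrame) -> pd.Series:
    """Number of taxa with count > 0 per sample."""
    if table.shape[0] == 0:
        raise ValueError("empty count table")
    return (table > 0).sum(axis=1).rename("observed_otus")


def shannon(table: pd.DataFrame, log_base: str = "e") -> pd.Series:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    log = _LOG[log_base]
    x = table.to_numpy(dtype=float)
    depth = x.sum(axis=1)
    if (depth <= 0).any():
        raise ValueError("samples with zero depth")
    p = x / depth[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.index, name="shannon")


def pielou(table: pd.DataFrame) -> pd.Series:
    """Pielou evenness J = H / ln(richness); NaN when richness is 1."""
    h = shannon(table, log_base="e")
    s = observed_richness(table).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = h / np.log(s)
    j[s <= 1] = np.nan
    return j.rename("pielou")


def faith_pd(table: pd.DataFrame, tree: str | TreeNode) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    Sum of branch lengths of the minimal rooted subtree spanning the sample's
    present taxa (root included). ``tree`` is a Newick string or an skbio
    TreeNode whose leaves must cover every taxon observed in the table.
    """
    if isinstance(tree, str):
        # taxon labels keep literal underscores (no newick space convention)
        tree = TreeNode.read(io.StringIO(tree), convert_underscores=False)
    leaves = {t.name for t in tree.tips()}
    observed = set(table.columns[(table > 0).any(axis=0)])
    missing = sorted(observed - leaves)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}")
    values = _skbio_alpha_diversity(
        "faith_pd",
        table.to_numpy(dtype=float),
        ids=list(table.index),
        taxa=list(table.columns),
        tree=tree,
    )
    return pd.Series(values.to_numpy(), index=table.index, name="faith_pd")


def zscore_by_cohort(values: pd.Series, cohorts: pd.Series) -> pd.Series:
    """Standardize within cohort: (x - cohort mean) / cohort SD (ddof=1).

    NaN values are ignored when estimating the cohort moments and propagate
    unchanged. A cohort with fewer than 2 non-missing values or zero variance
    is an error — the SD-unit contract would be meaningless.
    """
    values = values.astype(float)
    out = pd.Series(np.nan, index=values.index, dtype=float, name=values.name)
    for cohort, idx in values.groupby(cohorts.loc[values.index]).groups.items():
        v = values.loc[idx]
        ok = v.dropna()
        if len(ok) < 2:
            raise ValueError(f"cohort {cohort!r} has < 2 usable samples")
        sd = ok.std(ddof=1)
        if sd == 0:
            raise ValueError(f"cohort {cohort!r} has zero variance")
        out.loc[idx] = (v - ok.mean()) / sd
    return out


def rarefy(table: pd.DataFrame, depth: int | None, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample to a common depth without replacement.

    Optional robustness mode; the default pipeline does not rarefy. Samples
    below the target depth are dropped.
    """
    rng = np.random.default_rng(seed)
    depths = table.sum(axis=1)
    if depth is None:
        depth = int(depths.min())
    keep = table.index[depths >= depth]
    x = table.loc[keep].to_numpy(dtype=np.int64)
    out = np.zeros_like(x)
    for i, row in enumerate(x):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=keep, columns=table.columns)


def alpha_diversity_table(
    table: pd.DataFrame,
    cohorts: pd.Series | None = None,
    tree: str | TreeNode | None = None,
) -> pd.DataFrame:
    """All alpha indices per sample, plus cohort z-scored columns (`*_z`)."""
    out = pd.DataFrame(
        {
            "observed_otus": observed_richness(table),
            "shannon": shannon(table),
            "pielou": pielou(table),
        }
    )
    if tree is not None:
        out["faith_pd"] = faith_pd(table, tree)
    if cohorts is not None:
        for col in list(out.columns):
            out[f"{col}_z"] = zscore_by_cohort(out[col], cohorts)
    return out
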