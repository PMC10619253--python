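"""Co-abundance network inference and keystone-taxon analysis.

Three estimators produce weighted undirected genus-genus networks:

* ``pearson_network`` — Pearson correlation of CLR abundances (zeros handled
  upstream by multiplicative replacement), edges kept when |r| > 0.3 and
  BH-FDR p < 0.05;
* ``sparcc`` — basis correlations inferred from log-ratio variances under the
  sparse-correlation approximation, with iterative exclusion of strongly
  correlated pairs and a permutation null for p-values; edges at |rho| > 0.2
  and BH-FDR p < 0.05;
* ``spieceasi`` — conditional-dependence graph by neighborhood selection
  (sparse per-taxon lasso regressions on CLR data, OR-rule symmetrization)
  with the penalty chosen by StARS stability selection; no further edge
  thresholding.

Keystone taxa are nodes whose eigenvector centrality (leading eigenpair of
the adjacency matrix, Ac = lambda c) exceeds the network's empirical 95%
quantile. Keystones called per cohort by majority vote across the three
estimators are intersected across cohorts, and the shared set defines a
per-sample keystone-taxa index: the sum of CLR(count + 1) abundances of the
shared keystones, z-scored within cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from statsmodels.stats.multitest import multipletests

from gutkeystone.preprocess import clr_transform

__all__ = [
    "CoAbundanceNetwork",
    "pearson_network",
    "sparcc",
    "spieceasi",
    "detect_modules",
    "eigenvector_centrality",
    "call_keystones",
    "combine_methods",
    "shared_keystones",
    "keystone_index",
    "rank_richness_correlates",
]


@dataclass
class CoAbundanceNetwork:
    """Weighted undirected network over retained genera.

    ``adjacency`` holds non-negative association magnitudes (zero diagonal);
    ``signs`` the sign of the underlying association. Centrality and module
    assignments are filled in lazily by :func:`eigenvector_centrality` and
    :func:`detect_modules`.
    """

    adjacency: pd.DataFrame
    method: str
    signs: pd.DataFrame | None = None
    centrality: pd.Series | None = None
    leading_eigenvalue: float | None = None
    modules: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    @property
    def taxon_ids(self) -> list:
        return list(self.adjacency.index)

    @property
    def n_edges(self) -> int:
        a = self.adjacency.to_numpy()
        return int((a[np.triu_indices(a.shape[0], 1)] > 0).sum())

    def edge_list(self) -> pd.DataFrame:
        a = self.adjacency.to_numpy()
        s = self.signs.to_numpy() if self.signs is not None else np.ones_like(a)
        rows = []
        taxa = self.taxon_ids
        for i, j in zip(*np.triu_indices(len(taxa), 1)):
            if a[i, j] > 0:
                rows.append(
                    {
                        "taxon_a": taxa[i],
                        "taxon_b": taxa[j],
                        "weight": a[i, j],
                        "sign": int(s[i, j]) if s[i, j] else 1,
                        "method": self.method,
                    }
                )
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "weight", "sign", "method"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.taxon_ids)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["taxon_a"], row["taxon_b"], weight=row["weight"])
        return g


def _symmetric_frame(a: np.ndarray, taxa) -> pd.DataFrame:
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame((a + a.T) / 2, index=taxa, columns=taxa)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson/Spearman correlations via the t approx."""
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def _threshold_edges(
    rho: np.ndarray, pvals: np.ndarray, r_threshold: float, fdr_alpha: float
) -> np.ndarray:
    """BH-adjust upper-triangle p-values; keep |rho| > threshold & FDR < alpha."""
    p = rho.shape[0]
    iu = np.triu_indices(p, 1)
    adj = np.zeros_like(rho)
    if len(iu[0]) == 0:
        return adj
    padj = multipletests(pvals[iu], method="fdr_bh")[1]
    keep = (np.abs(rho[iu]) > r_threshold) & (padj < fdr_alpha)
    adj[iu] = np.where(keep, np.abs(rho[iu]), 0.0)
    return adj + adj.T


def pearson_network(
    clr: pd.DataFrame,
    r_threshold: float = 0.3,
    fdr_alpha: float = 0.05,
) -> CoAbundanceNetwork:
    """Pearson correlation network on CLR-transformed abundances.

    Constant taxa have undefined correlations and are excluded with a warning.
    Edge weight is |r|; the correlation sign is kept as an attribute.
    """
    n = clr.shape[0]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation inference")
    variances = clr.var(axis=0)
    constant = variances[variances == 0].index
    if len(constant):
        warnings.warn(
            f"excluding {len(constant)} constant taxa from Pearson network",
            stacklevel=2,
        )
        clr = clr.drop(columns=constant)
    x = clr.to_numpy(dtype=float)
    if x.shape[1] < 2:
        return CoAbundanceNetwork(
            adjacency=_symmetric_frame(np.zeros((x.shape[1],) * 2), clr.columns),
            method="pearson_clr",
        )
    r = np.corrcoef(x, rowvar=False)
    pvals = _corr_pvalues(r, n)
    adj = _threshold_edges(r, pvals, r_threshold, fdr_alpha)
    return CoAbundanceNetwork(
        adjacency=_symmetric_frame(adj, clr.columns),
        method="pearson_clr",
        signs=pd.DataFrame(np.sign(r) * (adj > 0), index=clr.columns, columns=clr.columns),
    )


# ---------------------------------------------------------------------------
# SparCC


def _sparcc_rho(
    log_frac: np.ndarray,
    n_iterations: int,
    exclusion_threshold: float,
) -> np.ndarray:
    """One SparCC fit: basis correlations from the log-ratio variance matrix.

    T_ij = var(log x_i / x_j) expands to C_ii + C_jj - 2 C_ij with C the
    covariance of log fractions. Under the sparsity approximation the basis
    variances omega^2 solve a linear system; the most strongly correlated
    pair above ``exclusion_threshold`` is removed from the system and the
    solve repeated, up to ``n_iterations`` times.
    """
    p = log_frac.shape[1]
    c = np.cov(log_frac, rowvar=False)
    d = np.diag(c)
    t_mat = d[:, None] + d[None, :] - 2 * c
    include = ~np.eye(p, dtype=bool)  # pairs still in the system

    rho = np.eye(p)
    for _ in range(n_iterations + 1):
        deg = include.sum(axis=1)
        if (deg < 2).any():
            break  # system close to singular; keep last estimate
        m = include.astype(float) + np.diag(deg.astype(float))
        t_vec = (t_mat * include).sum(axis=1)
        try:
            omega2 = np.linalg.solve(m, t_vec)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError("SparCC basis system singular after exclusions") from exc
        omega2 = np.clip(omega2, 1e-12, None)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t_mat) / (2 * np.outer(omega, omega))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # exclude the strongest remaining pair, if any above the threshold
        cand = np.abs(rho) * include
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
    return rho


def sparcc(
    table: pd.DataFrame,
    r_threshold: float = 0.2,
    fdr_alpha: float = 0.05,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> CoAbundanceNetwork:
    """SparCC co-abundance network from raw counts.

    Fractions are formed with a pseudocount of 1. p-values come from a
    permutation null: each taxon's counts are independently shuffled across
    samples ``n_bootstrap`` times and SparCC is re-fit. The null |rho| values
    are pooled across pairs (the permutation null is exchangeable over
    pairs), so the two-sided p-value per pair has resolution ~1/(B x number
    of pairs) rather than 1/B — without pooling no pair could survive BH
    adjustment at B = 100. Edges are kept at |rho| > ``r_threshold`` and
    BH-FDR p < ``fdr_alpha``.
    """
    if table.shape[1] < 3:
        raise ValueError("SparCC needs >= 3 taxa")
    x = table.to_numpy(dtype=float) + 1.0
    frac = x / x.sum(axis=1, keepdims=True)
    log_frac = np.log(frac)
    rho = _sparcc_rho(log_frac, n_iterations, exclusion_threshold)

    rng = np.random.default_rng(seed)
    p = rho.shape[0]
    iu = np.triu_indices(p, 1)
    abs_obs = np.abs(rho[iu])
    null_pool = np.empty((n_bootstrap, len(iu[0])))
    for b in range(n_bootstrap):
        perm = np.empty_like(log_frac)
        for j in range(p):
            perm[:, j] = rng.permutation(log_frac[:, j])
        rho_null = _sparcc_rho(perm, n_iterations, exclusion_threshold)
        null_pool[b] = np.abs(rho_null[iu])
    pool = np.sort(null_pool.ravel())
    n_ge = len(pool) - np.searchsorted(pool, abs_obs, side="left")
    pvals = np.ones_like(rho)
    pvals[iu] = (1 + n_ge) / (1 + len(pool))
    pvals[(iu[1], iu[0])] = pvals[iu]

    adj = _threshold_edges(rho, pvals, r_threshold, fdr_alpha)
    return CoAbundanceNetwork(
        adjacency=_symmetric_frame(adj, table.columns),
        method="sparcc",
        signs=pd.DataFrame(
            np.sign(rho) * (adj > 0), index=table.columns, columns=table.columns
        ),
        extras={"rho": pd.DataFrame(rho, index=table.columns, columns=table.columns)},
    )


# ---------------------------------------------------------------------------
# SPIEC-EASI (neighborhood selection + StARS)


def _mb_adjacency(
    x: np.ndarray, alphas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood-selection support and coefficients along a penalty path.

    ``x`` is standardized CLR data (n x p). Returns (support, coefs) with
    shapes (n_alphas, p, p); support is OR-rule symmetrized.
    """
    n, p = x.shape
    gram = x.T @ x
    coefs = np.zeros((len(alphas), p, p))
    for i in range(p):
        mask = np.arange(p) != i
        xi = x[:, mask]
        _, path_coefs, _ = lasso_path(
            xi,
            x[:, i],
            alphas=alphas,
            precompute=gram[np.ix_(mask, mask)],
            Xy=gram[mask, i],
        )
        coefs[:, i, mask] = path_coefs.T
    support = (coefs != 0) | np.transpose(coefs != 0, (0, 2, 1))
    return support, coefs


def spieceasi(
    table: pd.DataFrame,
    variant: str = "mb",
    lambda_path: np.ndarray | None = None,
    stars_threshold: float = 0.05,
    n_subsamples: int = 50,
    seed: int = 0,
    n_lambda: int = 15,
    lambda_min_ratio: float = 0.05,
    subsample_ratio: float = 0.8,
) -> CoAbundanceNetwork:
    """Conditional-dependence network by sparse neighborhood selection.

    Counts are CLR-transformed (pseudocount 1) and standardized; each taxon
    is lasso-regressed on all others along a decreasing penalty path, and
    edges are the OR-rule union of nonzero coefficients. The penalty is
    chosen by StARS: the graph is re-estimated on ``n_subsamples`` random
    subsamples (80% without replacement) and the densest penalty whose
    monotonized average edge instability stays below ``stars_threshold`` is
    selected. The final graph is fit on the full data at that penalty; no
    additional edge thresholding is applied.

    Only the ``mb`` (neighborhood selection) variant is implemented; the
    graphical-lasso variant raises ``NotImplementedError``.
    """
    if variant != "mb":
        raise NotImplementedError("only the 'mb' neighborhood-selection variant is implemented")
    n, p = table.shape
    if n < 20:
        raise ValueError("SPIEC-EASI needs >= 20 samples")
    clr = clr_transform(table, pseudocount=1).to_numpy()
    x = clr - clr.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = x / sd

    if lambda_path is None:
        corr = np.abs(np.corrcoef(x, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        lam_max = max(corr.max(), 1e-3)
        lambda_path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    lambda_path = np.asarray(sorted(lambda_path, reverse=True), dtype=float)

    rng = np.random.default_rng(seed)
    n_sub = int(np.floor(subsample_ratio * n))
    freq = np.zeros((len(lambda_path), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=n_sub, replace=False)
        xs = x[idx]
        xs = xs - xs.mean(axis=0)
        support, _ = _mb_adjacency(xs, lambda_path)
        freq += support
    freq /= n_subsamples

    iu = np.triu_indices(p, 1)
    instability = np.array([(2 * f * (1 - f))[iu].mean() for f in freq])
    monotone = np.maximum.accumulate(instability)  # sparse -> dense
    ok = np.flatnonzero(monotone <= stars_threshold)
    sel = int(ok[-1]) if len(ok) else 0

    support, coefs = _mb_adjacency(x, lambda_path)
    beta = np.abs(coefs[sel])
    weight = np.maximum(beta, beta.T) * support[sel]
    sign = np.sign(coefs[sel] + coefs[sel].T)
    if support[sel][iu].sum() == 0:
        warnings.warn("StARS-selected SPIEC-EASI graph is empty", stacklevel=2)
    return CoAbundanceNetwork(
        adjacency=_symmetric_frame(weight.copy(), table.columns),
        method="spieceasi",
        signs=pd.DataFrame(
            sign * (weight > 0), index=table.columns, columns=table.columns
        ),
        extras={
            "selected_lambda": float(lambda_path[sel]),
            "lambda_path": lambda_path,
            "instability": instability,
        },
    )


# ---------------------------------------------------------------------------
# Topology: modules, centrality, keystones


def detect_modules(net: CoAbundanceNetwork) -> pd.Series:
    """Greedy modularity agglomeration (Clauset-Newman-Moore) on |weights|.

    Isolated nodes form singleton modules. The assignment is stored on the
    network and returned as a Series of integer module ids.
    """
    g = net.to_networkx()
    connected = [n for n in g if g.degree(n) > 0]
    modules = pd.Series(-1, index=net.taxon_ids, dtype=int, name="module")
    next_id = 0
    if connected:
        sub = g.subgraph(connected)
        communities = nx.community.greedy_modularity_communities(sub, weight="weight")
        for community in communities:
            for node in community:
                modules.loc[node] = next_id
            next_id += 1
    for node in net.taxon_ids:
        if modules.loc[node] == -1:
            modules.loc[node] = next_id
            next_id += 1
    net.modules = modules
    return modules


def eigenvector_centrality(net: CoAbundanceNetwork) -> pd.Series:
    """Eigenvector centrality from the leading eigenpair of A (Ac = lambda c).

    Computed on the largest connected component with absolute weights —
    there the leading eigenvector is strictly positive by Perron-Frobenius —
    and zero elsewhere. Sign-fixed non-negative and max-normalized to 1.
    """
    taxa = net.taxon_ids
    cent = pd.Series(0.0, index=taxa, name="centrality")
    g = net.to_networkx()
    comps = [c for c in nx.connected_components(g) if len(c) > 1]
    if not comps:
        warnings.warn("network has no edges; all centralities zero", stacklevel=2)
        net.centrality = cent
        net.leading_eigenvalue = 0.0
        return cent
    comp = sorted(max(comps, key=len))
    a = net.adjacency.loc[comp, comp].to_numpy()
    evals, evecs = np.linalg.eigh(a)
    lead = evecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    lead = np.abs(lead)
    cent.loc[comp] = lead / lead.max()
    net.centrality = cent
    net.leading_eigenvalue = float(evals[-1])
    return cent


def call_keystones(net: CoAbundanceNetwork, quantile: float = 0.95) -> set:
    """Taxa with centrality strictly above the network's empirical quantile.

    The quantile uses linear interpolation; values tied with the quantile are
    excluded (strict inequality), so a constant centrality vector yields an
    empty keystone set.
    """
    if net.centrality is None:
        eigenvector_centrality(net)
    cut = float(np.quantile(net.centrality.to_numpy(), quantile))
    return set(net.centrality.index[net.centrality > cut])


def combine_methods(method_sets: dict[str, set], rule: str = "majority") -> set:
    """Combine per-method keystone sets within one cohort.

    ``any`` = union, ``all`` = intersection, ``majority`` (default) = taxa
    called by at least half of the methods (>= 2 of 3).
    """
    sets = list(method_sets.values())
    if rule == "any":
        return set().union(*sets)
    if rule == "all":
        return set.intersection(*map(set, sets))
    if rule == "majority":
        counts = pd.Series([t for s in sets for t in s]).value_counts() if any(sets) else pd.Series(dtype=int)
        need = int(np.ceil(len(sets) / 2))
        return set(counts.index[counts >= need])
    raise ValueError(f"unknown combination rule {rule!r}")


def shared_keystones(cohort_sets: list[set]) -> set:
    """Strict intersection of per-cohort combined keystone sets."""
    if len(cohort_sets) < 2:
        raise ValueError("need >= 2 cohorts to intersect")
    shared = set.intersection(*map(set, cohort_sets))
    if not shared:
        warnings.warn("no shared keystone taxa across cohorts", stacklevel=2)
    return shared


def keystone_index(
    table: pd.DataFrame,
    shared: set,
    cohorts: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample keystone-taxa index.

    Counts get a pseudocount of 1, are CLR-transformed over the full genus
    table, and the index is the sum of the CLR values of the shared keystone
    taxa ("total abundance" on the log-ratio scale). A keystone absent from
    the table contributes through its pseudocount (a zero column is added
    before the transform). With cohort labels, a per-cohort z-scored column
    is included — the SD-unit scale used by the association models.
    """
    if not shared:
        raise ValueError("shared keystone set is empty")
    table = table.copy()
    for taxon in sorted(shared):
        if taxon not in table.columns:
            table[taxon] = 0
    clr = clr_transform(table, pseudocount=1)
    raw = clr[sorted(shared)].sum(axis=1)
    out = pd.DataFrame({"index": raw})
    if cohorts is not None:
        from gutkeystone.diversity import zscore_by_cohort

        out["index_z"] = zscore_by_cohort(raw, cohorts)
    return out


def rank_richness_correlates(
    abundance: pd.DataFrame,
    richness: pd.Series,
    keystones: set | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of every genus with observed richness, ranked.

    Returns one row per genus with Spearman r, BH-FDR q, rank (1 = largest
    positive r), and a keystone flag. Used to show keystone taxa sit at the
    top of the richness-association ranking.
    """
    if abundance.shape[0] < 10:
        raise ValueError("need >= 10 samples for rank correlations")
    richness = richness.loc[abundance.index].astype(float)
    r_rank = stats.rankdata(richness)
    n = len(r_rank)
    rs = np.empty(abundance.shape[1])
    for j, col in enumerate(abundance.columns):
        a_rank = stats.rankdata(abundance[col].to_numpy())
        rs[j] = np.corrcoef(a_rank, r_rank)[0, 1]
    pvals = _corr_pvalues(rs, n)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "taxon": abundance.columns,
            "spearman_r": rs,
            "p_value": pvals,
            "q_value": qvals,
            "significant": qvals < fdr_alpha,
        }
    )
    out["rank"] = out["spearman_r"].rank(ascending=False, method="min").astype(int)
    out["keystone"] = out["taxon"].isin(keystones or set())
    return out.sort_values("rank").reset_index(drop=True)
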