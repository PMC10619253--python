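"""Synthetic multi-cohort microbiome generator with planted effects.

The generator emulates the statistical structure the famine analysis assumes,
so every downstream stage is testable without any cohort download:

* three cohorts of unequal size with cohort-level compositional offsets;
* sparse, overdispersed genus counts from a logistic-normal-multinomial
  model whose latent correlation matrix contains planted hub structure —
  each of ``n_keystones`` hub taxa drives ``hub_degree`` satellite taxa with
  one-factor correlation ``latent_correlation`` (so corr(hub, satellite) =
  rho and corr(satellite, satellite') = rho^2), and the hubs themselves
  share a weak common factor (``hub_hub_correlation``) so the planted
  network forms a single connected structure, as real gut co-abundance
  networks do — the eigenvector-centrality keystone definition operates on
  the largest connected component and is degenerate on disjoint blocks;
* birth years spanning 1930-1990, with the group born in 1959 (famine
  exposure over the first 1000 days of life) carrying a depressed keystone
  signal: hub latent means reduced by ``famine_effect_delta`` SD (satellites
  shift through the shared factor) and a ``diversity_effect`` fraction of
  rare taxa zeroed per exposed sample (a direct richness deficit);
* a binary type 2 diabetes outcome whose log-odds decrease with the
  standardized true keystone index (slope ``t2d_beta_index``) plus small age
  and BMI nuisance terms.

All randomness flows from a single generator seeded by the config: identical
configs give bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_cohorts", "simulate_tree"]

FAMINE_BIRTH_YEAR = 1959


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-cohort study.

    Defaults model three 16S cohorts of unequal size at genus resolution with
    a moderate planted famine effect (0.8 latent SD on hub taxa), a 10% rare
    -taxon richness deficit in the exposed group (roughly a one-SD drop in
    observed richness), and a protective keystone-index association with
    diabetes of -0.14 log-odds per SD (odds ratio 0.87) at a 12% base rate.
    """

    n_cohorts: int = 3
    cohort_sizes: tuple[int, ...] = (400, 800, 600)
    n_genera: int = 300
    n_keystones: int = 6
    hub_degree: int = 8
    latent_correlation: float = 0.7
    hub_hub_correlation: float = 0.6  # shared hub factor; the hub backbone must
    # remain above edge thresholds after softmax/CLR attenuation (~0.5x)
    birth_year_range: tuple[int, int] = (1930, 1990)
    survey_years: tuple[int, ...] = (2017, 2016, 2015)
    famine_effect_delta: float = 0.8
    diversity_effect: float = 0.1
    t2d_beta_index: float = -0.14
    t2d_base_rate: float = 0.12
    depth_lognormal_params: tuple[float, float] = (np.log(30000.0), 0.35)
    mean_sd: float = 1.5  # SD of baseline taxon mean log-abundances
    cohort_shift_sd: float = 0.3  # per-cohort compositional offset SD
    hub_mean: float = 1.5  # hub mean log-abundance: moderate, reliably detected
    hub_mean_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts < 1 or len(self.cohort_sizes) != self.n_cohorts:
            raise ValueError("cohort_sizes length must equal n_cohorts (>= 1)")
        if len(self.survey_years) != self.n_cohorts:
            raise ValueError("survey_years length must equal n_cohorts")
        if min(self.cohort_sizes) < 1 or self.n_genera < 2 or self.n_keystones < 1:
            raise ValueError("counts must be >= 1")
        if self.n_keystones >= self.n_genera:
            raise ValueError("n_keystones must be < n_genera")
        if self.n_keystones * (1 + self.hub_degree) > self.n_genera:
            raise ValueError(
                "infeasible hub structure: n_keystones x (1 + hub_degree) "
                "exceeds n_genera"
            )
        if not 0 < self.latent_correlation < 1:
            raise ValueError("latent_correlation must be in (0, 1)")
        if not 0 <= self.hub_hub_correlation < 1:
            raise ValueError("hub_hub_correlation must be in [0, 1)")
        if not 0 < self.t2d_base_rate < 1:
            raise ValueError("t2d_base_rate must be in (0, 1)")
        if not 0 <= self.diversity_effect <= 1:
            raise ValueError("diversity_effect must be in [0, 1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be ordered")


@dataclass
class SyntheticDataset:
    """Generated cohorts plus the ground truth the pipeline should recover."""

    counts: dict[str, pd.DataFrame]  # cohort -> samples x genera integer counts
    metadata: dict[str, pd.DataFrame]  # cohort -> per-sample covariates
    tree: str  # Newick over all genera
    truth: dict = field(default_factory=dict)

    @property
    def cohorts(self) -> list[str]:
        return list(self.counts)

    def combined_metadata(self) -> pd.DataFrame:
        return pd.concat(self.metadata.values())

    def write(self, outdir: str | Path) -> None:
        """Write counts/metadata TSVs, the Newick tree, and the truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cohort in self.cohorts:
            self.counts[cohort].to_csv(outdir / f"counts_{cohort}.tsv", sep="\t")
            self.metadata[cohort].to_csv(outdir / f"metadata_{cohort}.tsv", sep="\t")
        (outdir / "tree.nwk").write_text(self.tree)
        truth = {k: v for k, v in self.truth.items() if k != "latent_correlation_matrix"}
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str))


def _true_correlation_matrix(
    n_genera: int, hubs: dict[int, list[int]], rho: float, c_hh: float
) -> np.ndarray:
    corr = np.eye(n_genera)
    hub_list = list(hubs)
    for h, sats in hubs.items():
        for s in sats:
            corr[h, s] = corr[s, h] = rho
            for s2 in sats:
                if s2 != s:
                    corr[s, s2] = rho**2
    for i, h1 in enumerate(hub_list):
        for h2 in hub_list[i + 1 :]:
            corr[h1, h2] = corr[h2, h1] = c_hh
            for s1 in hubs[h1]:
                corr[s1, h2] = corr[h2, s1] = rho * c_hh
                for s2 in hubs[h2]:
                    corr[s1, s2] = corr[s2, s1] = rho**2 * c_hh
            for s2 in hubs[h2]:
                corr[h1, s2] = corr[s2, h1] = rho * c_hh
    return corr


def simulate_cohorts(config: SimulationConfig) -> SyntheticDataset:
    """Generate the multi-cohort dataset described by ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p, k, m = config.n_genera, config.n_keystones, config.hub_degree
    genus_ids = [f"genus_{j:04d}" for j in range(p)]

    # hub/satellite layout: hubs and satellites drawn without replacement
    layout = rng.permutation(p)
    hub_idx = np.sort(layout[:k])
    sat_pool = layout[k : k + k * m]
    hubs = {int(h): sorted(int(s) for s in sat_pool[i * m : (i + 1) * m]) for i, h in enumerate(hub_idx)}
    structured = set(hub_idx) | {s for sats in hubs.values() for s in sats}

    base_mu = rng.normal(0.0, config.mean_sd, size=p)
    # hubs get moderate, tightly distributed abundance: keystone taxa are
    # consistently detected, never dominant, never at the detection limit
    base_mu[hub_idx] = rng.normal(config.hub_mean, config.hub_mean_sd, size=k)

    # rare taxa eligible for the richness deficit: bottom half of baseline
    # means among unstructured (background) taxa
    background = np.array(sorted(set(range(p)) - structured))
    rare_cut = np.median(base_mu[background])
    rare_idx = background[base_mu[background] <= rare_cut]

    rho = config.latent_correlation
    counts_by_cohort: dict[str, pd.DataFrame] = {}
    meta_by_cohort: dict[str, pd.DataFrame] = {}
    lo, hi = config.birth_year_range

    for ci in range(config.n_cohorts):
        n = config.cohort_sizes[ci]
        cohort = f"cohort{ci + 1}"
        mu = base_mu + rng.normal(0.0, config.cohort_shift_sd, size=p)

        birth_year = rng.integers(lo, hi + 1, size=n)
        exposed = (birth_year == FAMINE_BIRTH_YEAR).astype(float)

        z = mu[None, :] + np.zeros((n, p))
        noise = rng.normal(size=(n, p))
        c_hh = config.hub_hub_correlation
        shared_factor = rng.normal(size=n)  # weak common driver of all hubs
        hub_factors = (
            np.sqrt(c_hh) * shared_factor[:, None]
            + np.sqrt(1 - c_hh) * rng.normal(size=(n, k))
        )
        hub_factors -= config.famine_effect_delta * exposed[:, None]
        for hi_pos, h in enumerate(hub_idx):
            z[:, h] += hub_factors[:, hi_pos]
            for s in hubs[int(h)]:
                z[:, s] += rho * hub_factors[:, hi_pos] + np.sqrt(1 - rho**2) * noise[:, s]
        for j in background:
            z[:, j] += noise[:, j]

        weights = np.exp(z - z.max(axis=1, keepdims=True))
        # richness deficit: zero a fraction of rare taxa per exposed sample
        if config.diversity_effect > 0 and len(rare_idx):
            n_zero = int(round(config.diversity_effect * len(rare_idx)))
            for i in np.flatnonzero(exposed):
                drop = rng.choice(rare_idx, size=n_zero, replace=False)
                weights[i, drop] = 0.0
        comp = weights / weights.sum(axis=1, keepdims=True)

        mu_d, sd_d = config.depth_lognormal_params
        depth = np.maximum(rng.lognormal(mu_d, sd_d, size=n).astype(np.int64), 100)
        counts = np.empty((n, p), dtype=np.int64)
        for i in range(n):
            counts[i] = rng.multinomial(depth[i], comp[i])

        # true keystone index: standardized sum of hub latent values
        hub_sum = z[:, hub_idx].sum(axis=1)
        index_z = (hub_sum - hub_sum.mean()) / hub_sum.std(ddof=1)

        age = config.survey_years[ci] - birth_year
        sex = rng.binomial(1, 0.55, size=n)
        bmi = np.clip(rng.normal(23.5, 3.5, size=n), 15, 40)
        logit0 = np.log(config.t2d_base_rate / (1 - config.t2d_base_rate))
        lin = (
            logit0
            + config.t2d_beta_index * index_z
            + 0.02 * (age - age.mean())
            + 0.05 * (bmi - 23.5)
        )
        t2d = rng.binomial(1, 1 / (1 + np.exp(-lin)))
        hypoglycemic = np.where(t2d == 1, rng.binomial(1, 0.5, size=n), rng.binomial(1, 0.02, size=n))
        hypolipidemic = rng.binomial(1, 0.08 + 0.10 * t2d)

        sample_ids = [f"{cohort}_s{i:04d}" for i in range(n)]
        counts_by_cohort[cohort] = pd.DataFrame(counts, index=sample_ids, columns=genus_ids)
        meta_by_cohort[cohort] = pd.DataFrame(
            {
                "cohort": cohort,
                "birth_year": birth_year,
                "age": age,
                "sex": sex,
                "bmi": bmi,
                "hypoglycemic": hypoglycemic,
                "hypolipidemic": hypolipidemic,
                "t2d": t2d,
                "depth": depth,
                "antibiotics": False,
                "true_index_z": index_z,
            },
            index=sample_ids,
        )

    tree = simulate_tree(genus_ids, seed=int(rng.integers(2**31 - 1)))
    truth = {
        "keystone_taxa": [genus_ids[h] for h in hub_idx],
        "hub_satellites": {
            genus_ids[h]: [genus_ids[s] for s in sats] for h, sats in hubs.items()
        },
        "latent_correlation": rho,
        "hub_hub_correlation": config.hub_hub_correlation,
        "latent_correlation_matrix": _true_correlation_matrix(
            p, hubs, rho, config.hub_hub_correlation
        ),
        "famine_effect_delta": config.famine_effect_delta,
        "diversity_effect": config.diversity_effect,
        "t2d_beta_index": config.t2d_beta_index,
        "config": asdict(config),
    }
    return SyntheticDataset(
        counts=counts_by_cohort, metadata=meta_by_cohort, tree=tree, truth=truth
    )


def simulate_tree(genus_ids: list[str], seed: int = 0) -> str:
    """Random bifurcating tree with positive branch lengths over ``genus_ids``.

    Built by repeatedly joining two uniformly chosen subtrees with
    exponential(0.1) + 0.01 branch lengths; the leaf set equals the input ids
    exactly. Deterministic for a fixed seed.
    """
    if len(genus_ids) < 2:
        raise ValueError("need >= 2 genera for a tree")
    if len(set(genus_ids)) != len(genus_ids):
        raise ValueError("duplicate genus ids")
    rng = np.random.default_rng(seed)
    nodes = [str(g) for g in genus_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bl_a, bl_b = rng.exponential(0.1, size=2) + 0.01
        merged = f"({nodes[i]}:{bl_a:.6f},{nodes[j]}:{bl_b:.6f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return nodes[0] + ";"
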