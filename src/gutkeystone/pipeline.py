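"""End-to-end orchestration of the famine-microbiome study replica.

Stage order mirrors the cohort analysis: simulate (or load) -> sample filters
-> exposure classification -> alpha diversity -> community structure (Bray-
Curtis, PCoA, PERMANOVA) -> prevalence filter -> three co-abundance networks
-> keystone calling and the shared keystone index -> covariate-adjusted
association models per cohort -> random-effects meta-analysis. The report is
a plain JSON-serializable dict; when the input is synthetic it also carries
the recovered-vs-planted comparison (keystone recall/precision, contrast
signs, pooled CIs vs the planted effects).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from gutkeystone import associations, community, diversity, exposure, meta, network, preprocess
from gutkeystone.simulate import SimulationConfig, SyntheticDataset, simulate_cohorts

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("gutkeystone")


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the study's stated values:
    5000-read depth filter, 10% prevalence filter, Pearson |r| > 0.3 and
    SparCC |rho| > 0.2 at FDR 0.05, 999 permutations, 95% centrality
    quantile.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_depth: int = 5000
    min_prevalence: float = 0.10
    pearson_r_threshold: float = 0.3
    sparcc_r_threshold: float = 0.2
    fdr_alpha: float = 0.05
    sparcc_bootstrap: int = 100
    sparcc_iterations: int = 20
    spieceasi_subsamples: int = 50
    stars_threshold: float = 0.05
    keystone_quantile: float = 0.95
    combine_rule: str = "majority"
    n_permutations: int = 999
    compute_faith_pd: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def validate_inputs(
    tables: dict[str, pd.DataFrame],
    metadata: dict[str, pd.DataFrame],
    tree: str | None = None,
    required_columns: tuple[str, ...] = ("birth_year", "age", "sex", "bmi",
                                         "hypoglycemic", "hypolipidemic", "t2d"),
) -> dict:
    """Check id consistency, value ranges, and required metadata columns.

    Returns {"fatal": [...], "warnings": [...]}; callers should abort on any
    fatal issue.
    """
    fatal, warnings_ = [], []
    for cohort, table in tables.items():
        if cohort not in metadata:
            fatal.append(f"{cohort}: no metadata table")
            continue
        md = metadata[cohort]
        mismatch = table.index.symmetric_difference(md.index)
        if len(mismatch):
            fatal.append(f"{cohort}: sample id mismatch: {sorted(map(str, mismatch))[:5]}")
        if (table.to_numpy() < 0).any():
            fatal.append(f"{cohort}: negative counts")
        for col in required_columns:
            if col not in md.columns:
                fatal.append(f"{cohort}: metadata missing column {col!r}")
        if "birth_year" in md.columns:
            by = md["birth_year"].dropna()
            if len(by) and ((by < 1890) | (by > 2024)).any():
                warnings_.append(f"{cohort}: implausible birth years present")
        if tree is not None:
            import io
            from skbio import TreeNode

            leaves = {
                t.name
                for t in TreeNode.read(io.StringIO(tree), convert_underscores=False).tips()
            }
            extra_taxa = set(table.columns) - leaves
            if extra_taxa:
                fatal.append(f"{cohort}: {len(extra_taxa)} taxa missing from tree")
            elif leaves - set(table.columns):
                warnings_.append(f"{cohort}: tree has extra leaves (superset) — allowed")
    return {"fatal": fatal, "warnings": warnings_}


def _cohort_analysis(
    cohort: str,
    counts: pd.DataFrame,
    md: pd.DataFrame,
    config: PipelineConfig,
    tree: str | None,
    seed: int,
) -> dict:
    """All single-cohort stages; returns intermediates + tidy results."""
    out: dict = {"cohort": cohort}

    counts, exclusions = preprocess.filter_samples(
        counts, md, min_depth=config.min_depth
    )
    md = md.loc[counts.index]
    out["n_samples"] = int(counts.shape[0])
    out["n_excluded"] = int(len(exclusions))

    groups = exposure.classify_series(md["birth_year"])
    out["group_counts"] = groups.value_counts().to_dict()

    cohort_series = pd.Series(cohort, index=counts.index)
    alpha = diversity.alpha_diversity_table(
        counts, cohorts=cohort_series, tree=tree if config.compute_faith_pd else None
    )

    dm = community.bray_curtis(counts)
    ord_res = community.pcoa(dm, n_axes=2)
    out["pcoa_explained_fraction"] = [float(v) for v in ord_res.explained_fraction]
    coords = ord_res.coordinates.copy()
    coords.index = counts.index
    pcoa_z = pd.DataFrame(
        {
            f"{c}_z": diversity.zscore_by_cohort(coords[c], cohort_series)
            for c in coords.columns
        }
    )

    # two-group community contrast: first-1000-days exposed vs control
    e1_ids = groups.index[groups == "E1"]
    ne2_ids = groups.index[groups == "NE2"]
    if len(e1_ids) >= 2 and len(ne2_ids) >= 2:
        ids = [str(s) for s in list(e1_ids) + list(ne2_ids)]
        res = community.permanova(
            dm.filter(ids), groups.loc[list(e1_ids) + list(ne2_ids)],
            n_permutations=config.n_permutations, seed=seed,
        )
        out["permanova_E1_vs_NE2"] = {
            "pseudo_F": res.pseudo_F, "R2": res.R2, "p_value": res.p_value,
        }

    filtered = preprocess.filter_prevalence(counts, config.min_prevalence)
    out["n_genera_retained"] = int(filtered.shape[1])

    comp = preprocess.multiplicative_impute(filtered)
    clr_pearson = preprocess.clr_transform(comp)
    nets = {
        "pearson_clr": network.pearson_network(
            clr_pearson, config.pearson_r_threshold, config.fdr_alpha
        ),
        "sparcc": network.sparcc(
            filtered,
            config.sparcc_r_threshold,
            config.fdr_alpha,
            n_iterations=config.sparcc_iterations,
            n_bootstrap=config.sparcc_bootstrap,
            seed=seed + 1,
        ),
        "spieceasi": network.spieceasi(
            filtered,
            stars_threshold=config.stars_threshold,
            n_subsamples=config.spieceasi_subsamples,
            seed=seed + 2,
        ),
    }
    method_keystones = {}
    for name, net in nets.items():
        network.eigenvector_centrality(net)
        network.detect_modules(net)
        method_keystones[name] = network.call_keystones(net, config.keystone_quantile)
    combined = network.combine_methods(method_keystones, rule=config.combine_rule)
    out["keystones_per_method"] = {k: sorted(v) for k, v in method_keystones.items()}
    out["keystones_combined"] = sorted(combined)
    out["n_edges"] = {name: net.n_edges for name, net in nets.items()}

    out["_internals"] = {
        "counts": counts,
        "filtered": filtered,
        "metadata": md,
        "groups": groups,
        "alpha": alpha,
        "pcoa_z": pcoa_z,
        "networks": nets,
        "combined_keystones": combined,
    }
    return out


def run_pipeline(
    config: PipelineConfig | None = None,
    dataset: SyntheticDataset | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full study replica; returns the JSON-serializable report.

    With no ``dataset``, one is simulated from ``config.simulation``. When
    ``outdir`` is given, intermediate artifacts (counts, metadata, tree,
    edge lists, estimates, report) are written there as TSV/Newick/JSON.
    """
    config = config or PipelineConfig()
    if dataset is None:
        with _stage("simulate"):
            dataset = simulate_cohorts(config.simulation)
    base_seed = int(config.simulation.seed)

    check = validate_inputs(dataset.counts, dataset.metadata, tree=dataset.tree)
    if check["fatal"]:
        raise ValueError(f"input validation failed: {check['fatal']}")

    cohort_results = {}
    for i, cohort in enumerate(dataset.cohorts):
        with _stage(f"cohort:{cohort}"):
            cohort_results[cohort] = _cohort_analysis(
                cohort,
                dataset.counts[cohort],
                dataset.metadata[cohort],
                config,
                dataset.tree,
                seed=base_seed + 1000 * (i + 1),
            )

    with _stage("keystone_index"):
        shared = network.shared_keystones(
            [set(r["keystones_combined"]) for r in cohort_results.values()]
        )
        per_cohort_index = {}
        for cohort, res in cohort_results.items():
            internals = res["_internals"]
            if shared:
                idx = network.keystone_index(
                    internals["filtered"], shared,
                    cohorts=pd.Series(cohort, index=internals["filtered"].index),
                )
                per_cohort_index[cohort] = idx

    with _stage("associations"):
        estimates: list[dict] = []
        e1_index, index_or, richness_or = [], [], []
        for cohort, res in cohort_results.items():
            internals = res["_internals"]
            md, groups, alpha = internals["metadata"], internals["groups"], internals["alpha"]
            cov1 = md[associations.MODEL1.resolve(md)]
            cov_log = md[associations.LOGISTIC_MODEL.resolve(md)]

            outcomes = {
                f"{idx}_z": alpha[f"{idx}_z"]
                for idx in ("observed_otus", "shannon", "pielou", "faith_pd")
                if f"{idx}_z" in alpha.columns
            }
            outcomes.update(internals["pcoa_z"])
            if cohort in per_cohort_index:
                outcomes["keystone_index_z"] = per_cohort_index[cohort]["index_z"]

            for name, values in outcomes.items():
                try:
                    ests = associations.linear_group_contrast(
                        values, groups, exposure.REFERENCE_CODE, cov1,
                        cohort=cohort, model="model1",
                    )
                except ValueError as exc:
                    log.warning("%s %s contrast skipped: %s", cohort, name, exc)
                    continue
                for est in ests:
                    row = dict(est.to_dict(), outcome=name)
                    estimates.append(row)
                    if name == "keystone_index_z" and est.term.startswith("E1 "):
                        e1_index.append(est)
                try:
                    logit = associations.logistic_outcome(
                        values, md["t2d"], cov_log, cohort=cohort,
                        term=f"{name} per SD",
                    )
                except ValueError as exc:
                    log.warning("%s %s logistic skipped: %s", cohort, name, exc)
                    continue
                estimates.append(dict(logit.to_dict(), outcome=name))
                if name == "keystone_index_z":
                    index_or.append(logit)
                if name == "observed_otus_z":
                    richness_or.append(logit)

    with _stage("meta"):
        pooled = {}
        if len(e1_index) >= 2:
            pooled["keystone_index_E1_vs_NE2"] = meta.pool_random_effects(e1_index).to_dict()
        if len(index_or) >= 2:
            pooled["keystone_index_vs_t2d"] = meta.pool_random_effects(index_or).to_dict()
        if len(richness_or) >= 2:
            pooled["observed_otus_vs_t2d"] = meta.pool_random_effects(richness_or).to_dict()

    report = {
        "config": config.to_dict(),
        "cohorts": {
            cohort: {k: v for k, v in res.items() if not k.startswith("_")}
            for cohort, res in cohort_results.items()
        },
        "shared_keystones": sorted(shared),
        "estimates": estimates,
        "meta": pooled,
    }

    if dataset.truth:
        true_set = set(dataset.truth["keystone_taxa"])
        recovered = set(report["shared_keystones"])
        tp = len(true_set & recovered)
        report["truth_comparison"] = {
            "true_keystones": sorted(true_set),
            "recovered_shared": sorted(recovered),
            "recall": tp / len(true_set) if true_set else float("nan"),
            "precision": tp / len(recovered) if recovered else float("nan"),
            "planted_famine_effect_delta": dataset.truth["famine_effect_delta"],
            "planted_t2d_beta_index": dataset.truth["t2d_beta_index"],
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dataset.write(outdir / "data")
        pd.DataFrame(estimates).to_csv(outdir / "estimates.tsv", sep="\t", index=False)
        for cohort, res in cohort_results.items():
            for name, net in res["_internals"]["networks"].items():
                net.edge_list().to_csv(
                    outdir / f"network_{cohort}_{name}.tsv", sep="\t", index=False
                )
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
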