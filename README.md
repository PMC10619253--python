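# gutkeystone

Cross-cohort gut-microbiome analysis of early-life famine exposure, keystone
taxa, and type 2 diabetes.

## The problem

The Developmental Origins of Health and Disease (DOHaD) hypothesis holds that
adverse exposures in early life — especially the first 1000 days, from
conception to age two — shape adult disease risk. The Great Chinese Famine of
1959–1961 is a natural experiment for this question: adults born in 1959 were
exposed through the whole first-1000-days window, while those born in
1962–1964 were not exposed at all. `gutkeystone` implements the full
statistical pipeline for asking whether that exposure leaves a lasting
imprint on the adult gut microbiome, and whether the imprinted signal —
summarized as a *keystone taxa index* — is associated with type 2 diabetes
(T2D), replicated across several independent 16S rRNA cohorts and pooled by
random-effects meta-analysis.

It is written for microbiome epidemiologists who have per-cohort genus-level
count tables and sample metadata (birth year, age, sex, BMI, medication
flags, T2D status, sequencing depth) and want a tested, reproducible
implementation of each analysis stage — plus a synthetic multi-cohort
generator with planted effects, so every stage can be validated end to end
without access to restricted cohort data.

## The analysis

1. **Preprocessing** — samples with sequencing depth < 5000 reads, unknown
   birth year, or recent antibiotic use are excluded; genera detected in
   < 10% of samples are removed before network inference. Compositional
   handling follows two conventions used on different paths: multiplicative
   zero replacement + centered log-ratio (CLR) for Pearson networks, and
   CLR with pseudo-count 1 for the keystone index.
2. **Exposure classification** — birth year → ten famine-exposure groups
   (E1 = born 1959, first 1000 days exposed; NE2 = born 1962–1964,
   reference), with sensitivity regroupings (post-1978 reference, age-
   balanced NE2+E4 reference, combined in-utero group).
3. **Diversity and community structure** — observed richness, Shannon,
   Pielou, Faith's PD, z-scored within cohort; Bray–Curtis dissimilarity,
   principal-coordinate analysis, and PERMANOVA (999 permutations, pairwise
   comparisons BH-adjusted).
4. **Co-abundance networks** — three estimators per cohort: Pearson on CLR
   (|r| > 0.3, FDR < 0.05), SparCC (|ρ| > 0.2, FDR < 0.05), and SPIEC-EASI
   (neighborhood selection with StARS stability selection, no additional
   thresholding). Modules by greedy modularity agglomeration.
5. **Keystone taxa** — eigenvector centrality from the leading eigenpair of
   the adjacency matrix, *Ac* = *λc*; keystones are nodes above the
   network's empirical 95% centrality quantile; per-cohort calls are
   combined by majority vote across the three estimators and intersected
   across cohorts. The **keystone taxa index** of a sample is the sum of
   CLR(count + 1) abundances of the shared keystones, z-scored within
   cohort.
6. **Association models** — linear regression of each outcome (SD units)
   on exposure-group indicators against the NE2 reference, adjusted for
   age, sex, BMI, and hypoglycemic/hypolipidemic medication; logistic
   regression of T2D on each per-SD exposure variable adjusted for age,
   sex, BMI.
7. **Meta-analysis** — DerSimonian–Laird random-effects pooling of the
   per-cohort estimates (odds ratios pooled on the log scale), with Q, τ²
   and I² heterogeneity statistics.

## Worked example

```python
from gutkeystone.pipeline import PipelineConfig, run_pipeline
from gutkeystone.simulate import SimulationConfig

config = PipelineConfig(
    simulation=SimulationConfig(cohort_sizes=(1300, 2000, 1500), seed=42),
    sparcc_bootstrap=100, spieceasi_subsamples=25, n_permutations=999,
)
report = run_pipeline(config)

print(report["shared_keystones"])
m = report["meta"]["keystone_index_E1_vs_NE2"]
print(f"E1 vs NE2 keystone index: {m['pooled_beta']:.2f} "
      f"[{m['ci_low']:.2f}, {m['ci_high']:.2f}]")
m = report["meta"]["keystone_index_vs_t2d"]
print(f"index vs T2D OR per SD:   {m['pooled_odds_ratio']:.2f} "
      f"[{m['or_ci_low']:.2f}, {m['or_ci_high']:.2f}]")
print(report["truth_comparison"]["recall"], report["truth_comparison"]["precision"])
```

prints (three synthetic cohorts, 4800 participants, six planted hub taxa):

```
['genus_0026', 'genus_0061', 'genus_0098', 'genus_0166', 'genus_0184', 'genus_0253', 'genus_0261', 'genus_0293', 'genus_0297']
E1 vs NE2 keystone index: -0.82 [-1.08, -0.56]
index vs T2D OR per SD:   0.93 [0.85, 1.02]
1.0 0.6666666666666666
```

All six planted hub taxa are recovered among the nine shared keystones
(recall 1.0, precision 0.67; the extra calls are strongly co-varying
satellite taxa of the planted hubs); the group exposed in the first 1000
days shows the planted deficit in the keystone index, and a higher index is
associated with lower T2D odds — the measured association is attenuated
relative to the planted log-odds because the measured index is a noisy proxy
of the latent one.

The same pipeline runs from the shell:

```bash
gutkeystone run-all --seed 42 --outdir results/run1
gutkeystone simulate --seed 7 --outdir data/synth
gutkeystone classify --metadata data/synth/metadata_cohort1.tsv --out meta_grouped.tsv
```

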