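# Methods

This note documents the statistical machinery implemented in `gutkeystone`,
the modelling choices behind the synthetic-data generator, and the numerical
conventions the tests rely on.

## Pipeline model

The analysis treats each cohort's genus-level 16S count table as a
composition observed through multinomial sampling at a per-sample read
depth. All inference that needs real-valued inputs goes through the
centered log-ratio (CLR) transform, clr(x)_j = log x_j − mean_k log x_k.
Two zero-handling conventions coexist deliberately, mirroring common
practice on the two analysis paths:

* **Pearson network path** — multiplicative zero replacement: each zero is
  replaced by δ = 0.65 × the sample's smallest nonzero relative abundance
  and nonzero parts are rescaled by (1 − total imputed mass), preserving
  ratios among observed parts; then CLR.
* **Keystone-index path** — pseudo-count 1 added to raw counts, then
  closure and CLR. This keeps the index defined for every sample,
  including ones where a keystone taxon was not observed.

### Co-abundance networks

Three estimators are run per cohort on prevalence-filtered (≥ 10%) genera:

* **Pearson on CLR.** Edges at |r| > 0.3 with Benjamini–Hochberg FDR < 0.05
  across all pairs; edge weight |r|, sign kept as an attribute.
* **SparCC.** Basis correlations inferred from the log-ratio variance
  matrix T_ij = var(log x_i/x_j) = C_ii + C_jj − 2C_ij under the
  sparse-correlation approximation: basis variances ω² solve the linear
  system (I_pairs + diag(deg)) ω² = Σ_pairs T, and
  ρ_ij = (ω_i² + ω_j² − T_ij)/(2ω_iω_j). The most strongly correlated pair
  with |ρ| above the exclusion threshold (0.1) is removed from the system
  and the solve repeated, up to 20 iterations. Fractions use pseudo-count 1
  rather than Dirichlet resampling — deterministic and adequate at the read
  depths modelled here. Significance comes from a permutation null (each
  taxon's counts shuffled independently, 100 rounds, full refit); the null
  |ρ| values are **pooled across pairs** before computing p-values. The null
  is exchangeable over pairs, and pooling gives p-value resolution of about
  1/(100 × #pairs); without pooling the smallest attainable p (1/101)
  could never survive BH adjustment over thousands of pairs, and the
  stated edge rule (|ρ| > 0.2, FDR < 0.05) would be unsatisfiable at any
  effect size. Edges at |ρ| > 0.2, FDR < 0.05.
* **SPIEC-EASI (mb).** CLR (pseudo-count 1), columns standardized; each
  taxon lasso-regressed on all others along a 15-point geometric penalty
  path from λ_max (the largest absolute pairwise correlation) down to
  0.05 λ_max, with precomputed Gram matrices for speed. Edge support is the
  OR-rule union. The penalty is selected by StARS: the graph is refit on
  random 80% subsamples and the **densest** penalty whose monotonized mean
  edge instability 2θ̂(1−θ̂) stays ≤ 0.05 is chosen (the canonical StARS
  rule; selecting the sparsest such penalty would always return the empty
  graph, whose instability is zero). The final graph is the full-data fit
  at the selected penalty with no further thresholding. Only the
  neighborhood-selection variant is implemented; the graphical-lasso
  variant raises `NotImplementedError`.

### Keystone taxa and the index

Eigenvector centrality solves Ac = λc on the absolute-weight adjacency
matrix, restricted to the largest connected component (where the leading
eigenvector is strictly positive by Perron–Frobenius); other nodes get
centrality 0. The vector is sign-fixed non-negative and max-normalized.
Keystones are nodes **strictly above** the network's empirical 95% quantile
of centralities (linear-interpolation quantile; ties at the quantile are
excluded, so a constant vector yields no keystones). With ~300 genera this
rule calls ~15 nodes per network. Per-cohort calls are combined across the
three estimators by majority vote (≥ 2 of 3; configurable to union or
intersection), and the per-cohort combined sets are intersected across
cohorts. The keystone taxa index is the per-sample sum of CLR(count+1)
values of the shared keystones ("total abundance" on the log-ratio scale;
a CLR-of-summed-counts variant was considered and rejected because the sum
of CLR values is the one that makes the index additive in its taxa),
z-scored within cohort.

### Community structure and models

Bray–Curtis dissimilarity is computed on relative abundances; PCoA is
classical metric scaling (double-centered −½d², eigendecomposition,
coordinates scaled by √λ; negative eigenvalues reported but unused; axis
signs fixed by making the largest-magnitude loading positive). PERMANOVA
uses Anderson's pseudo-F computed directly from within-group sums of
squared distances, a seeded permutation RNG, and the +1/+1 p-value
convention so p ≥ 1/(B+1); the exposed-vs-control comparison runs on the
two-group distance submatrix. Group contrasts are OLS with reference-coded
group indicators (reference NE2, born 1962–1964), adjusted for age, sex,
BMI, and the two medication flags ("model 1"; "model 2" adds sequencing
depth and any diet/lifestyle columns present); T2D models are
maximum-likelihood logistic regressions adjusted for age, sex, BMI, with
Wald 95% CIs throughout. Missing covariates are handled complete-case per
model. Meta-analysis is DerSimonian–Laird: moment estimator
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), random weights 1/(se² + τ²),
I² = max(0, (Q − (k−1))/Q); odds ratios are pooled on the log scale.

## The synthetic-data generator

`simulate_cohorts` draws, per cohort, latent genus log-abundances from a
structured multivariate normal, maps them through a softmax to a
composition, and samples multinomial counts at lognormal depths
(median ≈ 30 000 reads, σ = 0.35). Its parameters are the study conditions
every downstream test assumes:

| parameter | default | meaning |
|---|---|---|
| `cohort_sizes` | (400, 800, 600) | three cohorts of unequal size |
| `n_genera` | 300 | genus-level table width |
| `n_keystones` / `hub_degree` | 6 / 8 | planted hub taxa and satellites per hub |
| `latent_correlation` | 0.7 | hub–satellite latent correlation ρ |
| `hub_hub_correlation` | 0.6 | inter-hub correlation via a shared factor |
| `birth_year_range` | 1930–1990 | uniform birth years |
| `famine_effect_delta` | 0.8 SD | latent hub-mean deficit for 1959 births |
| `diversity_effect` | 0.1 | fraction of rare taxa zeroed per exposed sample |
| `t2d_beta_index` | −0.14 | log-odds of T2D per SD of the true index (OR 0.87) |
| `t2d_base_rate` | 0.12 | baseline T2D prevalence |

Each hub h is a latent factor f_h; its satellites are ρf_h + √(1−ρ²)ε, so
corr(hub, satellite) = ρ and corr(satellite, satellite′) = ρ². The hubs
themselves load on one weak shared factor with pairwise correlation
`hub_hub_correlation`. This inter-hub backbone is essential, not cosmetic:
eigenvector centrality is defined on the largest connected component, and
with mutually independent hubs the planted network decomposes into disjoint
blocks on which at most one block can carry nonzero centrality — hub
recovery would be impossible by construction. Real gut co-abundance
networks form a single connected structure. The default 0.6 is chosen so
that the backbone survives the softmax/CLR attenuation (observed inter-hub
CLR correlation ≈ 0.3–0.35, above all edge thresholds); at 0.45 the
observed backbone (~0.21) drops below the SparCC edge rule and the network
fragments. Hub mean log-abundances are drawn from N(1.5, 0.5²) — keystone
taxa are modelled as consistently detected but not dominant; a hub at the
detection limit has its correlations destroyed by count noise and is not a
meaningful recovery target.

The famine effect enters as a −`famine_effect_delta` shift of the hub
factors for samples born in 1959 (satellites shift through ρ), plus a
direct richness deficit: for each exposed sample, a `diversity_effect`
fraction of the rare background taxa (bottom half of baseline means) is
zeroed before count sampling. The default 0.1 produces roughly a one-SD
drop in observed richness — a deliberately clear planted signal; mean
shifts alone would not reduce richness. T2D is Bernoulli with logit =
logit(base rate) + `t2d_beta_index` × (standardized true hub-factor sum)
+ 0.02(age − mean age) + 0.05(BMI − 23.5).

What the generator does **not** emulate: read-level sequencing error,
chimeras, primer/batch effects beyond a per-cohort compositional offset,
taxonomic misassignment, age- or diet-dependent microbiome drift, and any
real famine biology. Passing tests therefore demonstrate that the pipeline
recovers effects of the assumed logistic-normal-multinomial form at
realistic sample sizes — not that the famine findings themselves are
reproduced.

## Numerical conventions

* z-scores use the n−1 SD denominator; zero-variance cohorts are an error.
* Prevalence boundary: exactly 10% prevalence is retained ("< 10%" dropped).
* Depth boundary: depth 4999 is excluded, 5000 retained.
* Quantile convention for keystone calling: linear interpolation, strict >.
* Permutation p-values: (1 + #{T* ≥ T})/(1 + B) — never zero.
* PCoA axis signs: largest-magnitude loading positive.
* All stochastic stages (simulation, SparCC permutations, StARS subsamples,
  PERMANOVA permutations) take explicit seeds; a fixed seed reproduces the
  pipeline report byte for byte.
* Degenerate inputs fail loudly: all-zero samples at imputation, empty
  post-filter tables, empty reference groups, complete separation in
  logistic fits, mixed scales in meta-analysis.

## Problem sizes used in the tests

The validation suite exercises the pipeline at sizes chosen to make every
planted effect statistically decidable on one CPU: keystone recovery runs
five single-cohort replicates of 500 samples × 300 genera with 10 planted
hubs (10 hubs rather than 6 because the strict 95%-quantile rule calls ~15
of 300 nodes, so precision against 6 planted hubs is capped at 0.4 even
under perfect ranking — with 10 hubs, matching the 10–18 keystones per
cohort that full-scale analyses report, precision is informative); the
end-to-end study replica uses three cohorts of 1300/2000/1500 samples
(≈ 4800 participants, about half the real consortium's scale) with 6
planted hubs; SPIEC-EASI uses 25 StARS subsamples and SparCC 100
permutation rounds in these runs. Null calibration uses 500 PERMANOVA and
200 linear-contrast replicates.

Per-cohort sign tests for the famine deficit are run on the measured
richness (planted directly, ≈ 1 SD) and on the latent true index; the
measured keystone-index contrast is assessed at the pooled level only. With
E1 groups of 16–33 samples — the realistic share of 1959 births — the
per-cohort measured-index contrast has a standard error near 0.25 while CLR
attenuation shrinks the planted −0.98 SD latent shift to roughly −0.4 to
−0.7 measured, so its per-cohort sign is not statistically identifiable and
asserting it would test luck, not correctness.

## Known limitations

* SparCC p-values assume pair-exchangeability of the permutation null;
  strongly heteroskedastic taxa could violate this mildly.
* The StARS search is over a fixed 15-point path; a pathological λ_max
  (all correlations tiny) falls back to a floor of 10⁻³.
* The measured keystone index is an attenuated proxy of the latent one, so
  measured-index associations are biased toward the null relative to the
  planted parameters; the acceptance checks quantify parameter recovery on
  the latent truth and direction/pooled significance on the measured path.
* Covariate adjustment for age is near-collinear with birth-year-derived
  group indicators (age is deterministic given birth year and survey
  year), inflating contrast standard errors — the same issue the
  age-balanced sensitivity regrouping addresses.
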