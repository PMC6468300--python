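# Methods

This note documents the statistical procedures, the synthetic-data models
behind the test suite, the defaults and why they were chosen, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Screen normalization and hit calling

A screen is a probe × sample matrix of nonnegative integer counts with a
probe annotation (endogenous / housekeeping / positive_spike /
negative_spike / tag) and a sample design (perturbation id, arm, group).
Normalization is the conventional two-stage control-probe scheme:

1. *Positive spikes* (lane efficiency): for sample s with spike geometric
   mean g_s, the factor is mean_s(g) / g_s.
2. *Housekeeping probes* (RNA content): the same construction applied to the
   spike-normalized housekeeping values.

Both factors multiply the counts. Note the numerator mean_s(g) is a global
constant shared by all samples: rescaling one sample's raw counts therefore
leaves all between-sample ratios invariant but moves the whole matrix by one
common constant. Zero counts in any control probe are an error (they would
make a geometric mean zero); the offending probe and sample are named.
Negative-control background (per-sample mean + 2 SD over negative probes) is
recorded and used only to flag values below background — it is never
subtracted, since subtraction would break the multiplicative error model.

Hit calling standardizes log2(normalized + 1) per probe across **all**
samples of an arm, controls included, with the n−1 sample SD. Rationale for
pooling controls and experiments: for tissue-restricted genes almost all
perturbations are expected to be inert, so the pooled distribution is a
serviceable null; the cost is a slightly conservative z for true hits (they
inflate the pooled SD). Flags:

* `hit_2p5`, `hit_3p5` — strict one-sided exceedance (z > 2.5, z > 3.5); the
  upper flag always implies the lower. Control samples are scored but never
  flagged.
* `probe_normal` — per-probe Shapiro–Wilk at α = 0.05, advisory only: some
  probes are genuinely non-normal (near-zero counts are discrete), which is
  why hits are defined by SD exceedance rather than by a parametric p.
* `below_background` — normalized value under the negative-control
  background.

`z_to_pvalue` maps z to standard-normal tails (one- or two-tailed). The
mapping is exact, not rounded: z = 2.5 one-tailed is 0.62%, not "1%".

Defaults: pseudocount 1 before log2 (counts of 0 are common for silenced
genes); thresholds (2.5, 3.5); sample SD estimator with n−1. All are
configurable.

## Signature derivation

Contrasts are computed on log2 expression: fold change 2^(Δmean) and a
two-sided Welch t-test (unequal variances; identical-group degenerates get
p = 1). The moderated-t machinery of empirical-Bayes pipelines is
deliberately not reimplemented: the classifier consumes only (fc, p) pairs,
so a moderated front end can be swapped in by the caller. Consequently exact
reproduction of class sizes from any particular published microarray
reanalysis is not expected from this code path.

Classification, evaluated in this fixed order so the classes partition the
gene set:

1. `not_responsive` unless fc_t > 1.5 and p_t < 0.05 (raw p, matching the
   original procedure; a Benjamini–Hochberg option exists but is off by
   default);
2. `dependent` if the treated+inhibitor contrast fails that same criterion
   ("lost induction");
3. `repressed` if fc_ti / fc_t ≥ 1.5 (induced more strongly under the
   inhibitor);
4. `independent` otherwise (the residual class — "induced equally well" is
   interpreted as residual, with no extra margin).

The 1.5 potentiation ratio mirrors the responsiveness fold cutoff; neither
the "lost induction" nor the "more strongly" rule has a published numeric
cutoff, so both are parameters.

## Cohort scoring

*Size factors* are median-of-ratios: reference genes are those with no zero
in any sample; factor_s = median_g(count_gs / geomean_g). This matches the
DESeq2 scheme (cross-checked in the tests against pydeseq2 — the only
difference is median interpolation on even reference counts, ~1e-4
relative).

*Decile strata*: tumors ranked by the marker's log2 normalized expression;
lowest and highest ⌈n/10⌉ are `low_decile` / `high_decile`. Ties are broken
by stable input order (deterministic), with a logged warning when ties
straddle a boundary.

*Activation score*: per tumor, Σ over signature genes of
log2((x + 1)/(normal mean + 1)). The log2 scale is the default because it is
symmetric in induction/repression and robust to single-gene outliers; a
linear-ratio option exists. The normal reference is the arithmetic mean of
normalized normal-sample values per gene. Signature genes absent from the
matrix are skipped and reported. The score is additive over disjoint
signature partitions (log2 scale), which the tests verify.

*Clustering*: Ward linkage on Euclidean distances between samples over
signature-gene log2 values, in the squared-distance (Ward.D2-equivalent)
Lance–Williams formulation (scipy's `ward`); the alternative "apply the Ward
update to unsquared distances" variant is available behind a flag. Merge
heights are non-decreasing; small cases are verified against an exhaustive
minimal-SSE-increase oracle. Cuts use `maxclust`; agreement with reference
labels is an adjusted Rand index.

*Random-signature null*: draws of k genes uniformly without replacement from
the matrix genes minus the correlate gene and an optional exclusion set; each
draw's activation score is correlated with the marker. A Gumbel(μ, β) is
fitted to the null correlations by method of moments (β̂ = s√6/π,
μ̂ = m − γβ̂, γ = 0.57721…) and the observed correlation's upper tail
1 − exp(−exp(−(r − μ̂)/β̂)) is the p-value; a negative observed correlation
is assessed on the negated values. The Gumbel is fitted to *all* null
correlations (not block maxima): the aim is a smooth right-tail summary that
can resolve p below 1/n_draws, and the fit is deterministic. A
maximum-likelihood fit is not provided; the moment fit is closed-form and is
verified to recover (μ, β) within ±0.02 from 10⁵ draws.

### Calibration and its limits

Two properties of this null are worth knowing:

* **Exchangeable calibration holds approximately, not exactly.** When the
  tested signature is itself a random gene set, the resulting p-values over
  many simulated uncoupled cohorts are approximately uniform, but the Gumbel
  is a skewed summary of a nearly symmetric null, so the p transform carries
  a systematic distortion of roughly 0.05–0.1 in CDF distance. A
  Kolmogorov–Smirnov test on 200 cohorts sits near its detection boundary
  for an effect of that size: across independent seed blocks the KS p
  ranges from ~0.25 to below 0.01. Treat the Gumbel p as a tail
  approximation (its purpose — resolving p far below 1/n_draws), not as an
  exactly calibrated body.
* **Testing a structured signature on an uncoupled marker is conservative.**
  All normalized values share the per-sample size-factor estimation residual
  (≈ 0.025 log2 here). That common mode shifts null-draw correlations
  (score SD ≈ 9) much more than the correlation of a score dominated by a
  real latent factor (score SD ≈ 190), so the p-value for a genuinely
  structured but uncoupled signature concentrates near 1 rather than being
  uniform. This is conservatism, not anti-conservatism — it does not inflate
  false positives.
* **Null universe.** By default the drawn universe includes the tested
  signature's own genes (only the correlate gene is excluded). In real
  transcriptomes, where thousands of genes carry shared programs, the
  overlap of a random draw with any one signature is a negligible part of
  the null spread. In the synthetic cohort the planted signature genes are
  the *only* carriers of the latent factor, so un-excluded draws (~12 of 190
  genes expected at 3000 genes) are strongly contaminated and the null is
  badly miscalibrated against the planted signature; significance tests on
  synthetic cohorts therefore pass `exclude=<signature genes>`. With real
  data the default (no exclusion) is the faithful choice.

## Synthetic-data generators

`generate_screen(n_endogenous=42, n_perturbations=160, n_controls=12,
n_hits=3, hit_effect=8.0, baseline_low=20, dispersion=10, lane_sigma=0.2)`:
counts are NegativeBinomial(mean = lane_s × baseline_p × effect, size =
dispersion) for endogenous probes. Endogenous baselines scatter
U(0.5, 1.5) × 20 counts (tissue-restricted genes are near-silent);
housekeeping sits near 5000; the positive-spike ladder is the six-point
geometric series 128/32/8/2/0.5/0.125 (× 150 counts per unit); negative
probes sit at 2 counts. Lane factors are log-normal (σ = 0.2). Control-class
probes (spikes, housekeeping, negatives) are Poisson rather than NB: spikes
are synthetic oligos and housekeeping genes are selected for stability, so
counting noise dominates; giving them the endogenous genes' biological
overdispersion would make control-based normalization impossible in
principle (the factor noise would exceed the lane noise it removes).
Planted hits multiply the mean by `hit_effect` (8× ≈ 3 log2 units, far above
the NB noise at mean 20, size 10). Measured behaviour at defaults: all
planted hits exceed 2.5σ and null screens produce zero 3.5σ calls, in
~100/100 seeds each.

`generate_three_condition_experiment(n_genes=2000, n_responsive=516,
n_dependent=190, n_repressed=155, n_reps=3, noise_sd=0.25)`: log2 expression
= U(4, 10) baseline + condition effect + N(0, 0.25). Responsive genes draw a
treated effect from U(1.0, 2.5) log2 units (≥ 2-fold, matching the
responsiveness cutoff with margin: at effect 1.0, Welch power at n = 3 is
≈ 0.88 and rises above 0.99 by effect 1.3). Dependent genes have the
inhibitor-condition effect set to 0; repressed genes have it multiplied by
U(2.0, 3.0) — the amplification must sit clearly above the 1.5 detection
ratio, otherwise the repressed class is not identifiable at n = 3 (at
amplification exactly 1.5 the observed ratio straddles the threshold);
independent genes keep the treated effect. The planted 190/155/171 partition
of 516 responsive among 2000 genes is the reference condition throughout.

`generate_cohort(n_genes=3000, n_signature=190, n_normal=112, n_tumor=500,
coupling=1.0, noise_sd=0.5, lib_sigma=0.3)`: per-tumor latent activation
a_t ~ N(0, 1) (normals have a = 0); signature gene g adds a_t·w_g to its
log2 mean with loadings w_g ~ U(0.5, 1.5); one target marker adds
+coupling·a_t and one anti-marker −coupling·a_t; per-gene-per-sample
log-normal noise N(0, 0.5) supplies overdispersion; counts are
Poisson(2^log2mean × library factor) with log-normal library factors
(σ = 0.3). Baselines are U(3, 9) log2 counts.

What the generators do **not** emulate: probe chemistry and cross-
hybridization; batch structure beyond one multiplicative lane/library
factor; correlated gene programs other than the single planted factor; tumor
subtype structure; gene length or GC effects. Passing tests therefore show
that the *procedures* behave as specified under their own model assumptions
— not that real screens or cohorts satisfy those assumptions.

## Numerical and interface choices

* TSV is canonical (CSV via a flag); gene sets are GMT; all matrices dense.
* Identifiers are case-sensitive and matched exactly; no alias resolution.
* Floats are written with `%.10g`, JSON with sorted keys; combined with
  seeded generators this makes equal-seed reruns byte-identical, and every
  stage writes an audit JSON (version, config echo, SHA-256 of the config,
  seed).
* Probes with zero SD yield NaN z-scores plus a QC flag rather than raising.
* All-tied decile stratification is resolved by stable input order and
  logged.
* Degenerate Welch tests (both groups constant and equal) report p = 1.
* Sub-seeds in scripts are derived from the user seed and kept below 2³¹.

## Problem sizes

Recovery and calibration statements are computed at the default condition
sizes above, with 100 seeds for screen recovery/false positives, 20 for
signature class sizes and cohort score recovery, 10 for clustering ARI, and
200 uncoupled cohorts (1000 null draws each) for calibration.

## Known limitations

* The hit-z pools controls and perturbations; a screen where many
  perturbations are truly active would inflate the pooled SD and mask hits.
* Welch-t on n = 3 replicates is noisy; variance-moderated alternatives will
  classify boundary genes differently.
* The "sum of fold changes" score weights every signature gene equally; a
  dominant outlier gene can move scores on the linear scale (the log2
  default limits this).
* The Gumbel moment fit summarises the whole null sample; if the null is
  strongly multi-modal (e.g. a contaminated universe, see above) the tail
  extrapolation is unreliable.
* ⌈n/10⌉ decile strata do not reproduce ad-hoc groupings used in specific
  published cohorts (e.g. 113-of-1104), which follow no standard decile
  rule.
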