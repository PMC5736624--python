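# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices a maintainer
should know about. Notation: β is the fraction methylated of a CpG probe
in [0, 1]; M = log₂(β/(1 − β)) is its logit2 transform; EFS is 4-year
event-free survival, dichotomized as event / no event.

## Clustering and classification model

Samples are clustered on β values (not M) restricted to high-variance
probes, SD > 0.25 across samples with the n − 1 denominator; a
top-fraction mode (e.g. top 0.5% by SD) is provided as an alternative
because the two selection rules are not numerically equivalent in
general. Clustering is agglomerative under Ward's minimum-variance
criterion on Euclidean distances between sample profiles — the
Lance–Williams formulation whose merge cost is
Δ(A,B) = |A||B|/(|A|+|B|)·‖c_A − c_B‖², as implemented by
`scipy.cluster.hierarchy.linkage(method="ward")`; merge heights are
non-decreasing. The tree is cut at k = 3 and clusters are named
low/intermediate/high by mean β over all member samples and signature
probes; exact ties take the lower original cluster index.

Independent cohorts are classified by minimum Euclidean distance to the
discovery centroids (per-probe arithmetic mean β of the cluster
members). Equidistant samples go to the lower-methylation cluster — a
deterministic tie-break, exercised only by constructed fixtures in
practice.

**Typicality and distillation.** A probe's typicality score is
Σ_samples (β[probe, s] − centroid[probe, cluster(s)])², i.e. squared
distance (the absolute-distance variant would change only near-tied
ranks; squared matches the Euclidean geometry used everywhere else, and
is the documented choice). Validation samples are re-classified using
the top-k most typical probes, k on a 5…200 grid in steps of 5 (grid
truncated, with the full signature size appended, when the signature is
smaller), and disagreements with the full-signature calls count as
errors. "Recapitulation" means ≤ 1 error, exposed as a flag.

## Outcome statistics

Logistic regressions are maximum-likelihood fits (IRLS via the binomial
GLM); factors use treatment coding with the first-seen level as
reference (cluster reference = low). Significance is by likelihood-ratio
test: p = P(χ²_df > 2Δℓ). Quasi-complete separation is flagged on the
result object (|log-odds| > 15 or non-convergence) instead of raising.
The multivariable model of interest is
event ~ cluster + mutations(>1) + age(>12 mo), with per-term LRTs by
dropping each term.

Odds ratios for 2×2 tables take rows as (reference, exposed) and columns
as (events, non-events), OR = odds(exposed)/odds(reference). The default
95% CI inverts the profile likelihood of the log-OR at the χ²₁ cutoff
(Wald available behind a flag); on the reconstructed univariable tables
the profile intervals reproduce the published bounds to rounding, which
Wald intervals do not. Event proportions get exact Clopper–Pearson
intervals from Beta quantiles. Contingency tables of cluster membership
against categorical covariates use the Freeman–Halton exact test:
exhaustive enumeration of fixed-margin tables, summing probabilities
≤ the observed table's (relative tolerance 1e-7), with a 10⁷-table
budget and a seed-controlled Monte Carlo fallback. Survival curves are
Kaplan–Meier product-limit estimates (via lifelines) honoring right
censoring. Display percentages round half-up to integer percent; raw
fractions are retained everywhere.

## Moderated differential testing

Per feature, the two-group contrast is tested with the moderated
t-statistic: pooled residual variance s² on d = n₁ + n₂ − 2 df is shrunk
toward a prior, s̃² = (d₀s₀² + d s²)/(d₀ + d), and t̃ = Δ/(s̃·√(1/n₁+1/n₂))
is referred to t with d + d₀ df. The hyperparameters (d₀, s₀²) come from
moment matching of a scaled-F distribution to the s² on the log scale
(digamma/trigamma inversion, Newton iteration for the trigamma inverse);
d₀ is capped at 10⁶ to represent the no-heterogeneity limit, and a
`d0_override` exposes the limiting cases (0 → ordinary t; ∞ → pooled
prior variance). The implementation agrees with the reference R
implementation (limma's `eBayes`) to machine precision on shared
fixtures, and its null p-values are uniform (KS < 0.03 on 5000 null
features).

Methylation is tested on M-values, but the effect-size filter Δβ is
computed on the β scale as the difference of group mean β (not the
back-transform of mean M — the two differ by Jensen's inequality; group
β means are the documented choice). Calls require p < 0.05 (strict) and
|Δβ| ≥ 0.1 (inclusive); no multiple-testing correction is applied,
mirroring the emulated analysis, though an FDR column can be added by
users. Expression testing uses log₂(TPM+1), all-zero genes removed, with
p < 0.05 alone. Significant probes project to genes through strand-aware
promoter windows: closed interval [TSS−1500, TSS+1000] on +, flipped on
−, 1-based inclusive coordinates; a probe may hit several genes.
Expression clustering keeps genes with SD > 2.5 and median-centers rows
before reusing the Ward machinery.

## Paired-methylome concordance

Coverage files are bismark-style (chromosome, start=end, percent,
methylated, unmethylated counts; 1-based; "chr" prefixes normalized;
calls assumed destranded). Sites need ≥ 10 total reads; pairs intersect
on (chromosome, position). Lin's concordance correlation coefficient
uses population (1/n) moments per the original definition (sample-moment
variant behind a flag); degenerate conventions: both vectors constant
and equal → 1, constant and unequal → 0. Variable-site clustering keeps
sites with percent-scale SD > 30 (fraction-scale input is rescaled with
a warning) and reuses Ward clustering of samples.

## Synthetic-data model

The generator emulates the structure the analysis assumes, not array
physics (no raw intensities, dye bias or batch effects — so passing
tests demonstrate correctness of the analysis code, not robustness to
array artifacts).

* **Cohort structure.** Defaults are the study conditions: discovery
  clusters of 15/11/13 patients with event rates 1/15, 5/11, 8/13
  (validation: 12/11/17 with 1/12, 4/11, 13/17), 22 healthy controls,
  1527 signature probes among 20 000 total.
* **β model.** Signature probes carry per-cluster archetypes: ordered
  cluster means (0.2 / 0.5 / 0.8) plus a per-probe jitter (SD 0.05)
  applied to all clusters jointly, preserving the ordering. Sample
  values are Beta-distributed, reparameterized by (mean, sd) and clamped
  to [1e-6, 1−1e-6]; within-cluster SD defaults to 0.10 and the shared
  background (mean 0.5) to SD 0.05. The dispersion values are free
  parameters — not reported by the emulated study — chosen once as
  typical inter-sample β dispersion at variable array CpGs; with them
  the across-sample SD of signature probes (~0.27) clears the 0.25
  selection threshold while background probes (~0.05) never do.
  Controls are drawn from the low-cluster archetype with halved noise,
  so they sit adjacent to (slightly tighter than) the low cluster.
* **Outcomes and covariates.** Events are allocated exactly
  (round(rate·n) per cluster, random positions) by default, or as
  independent Bernoulli draws. Covariates have cluster-dependent
  probabilities (older age, elevated HbF, > 1 somatic mutation all rise
  with methylation; tissue source is cluster-independent; spontaneous
  resolution is essentially a low-cluster phenomenon) so univariable
  associations exist without determinism.
* **Paired call sets.** Sites carry latent fractions from Beta(0.3, 0.3)
  (the bimodal genome-wide shape); each member observes the latent value
  through an independent Gaussian perturbation (reflected into [0, 1])
  plus binomial sampling at coverage 1 + Poisson(mean − 1). The
  perturbation SD is solved analytically from the target concordance
  after subtracting the expected binomial noise variance
  E[m(1−m)]·E[1/coverage], so the realized coefficient lands on the
  target (±0.01 at 50 000 sites, coverage 50).
* **Reproducibility.** One seed per cohort; per-component sub-streams
  derive from it through `SeedSequence`, so identical configs are
  bit-identical. Probe archetypes and annotation use a separate
  `structure_seed` (shared by default) so discovery and validation
  cohorts inhabit the same probe space.

## Problem sizes and determinism in the test suite

Unit tests run on reduced probe spaces (3000 probes / 300 signature)
where the statistical behavior is unchanged; the acceptance checks use
the full default structure across 20 fixed seeds for cluster recovery,
classification agreement and distillation, 50 000 sites for concordance,
and 5000 features for null calibration — sizes at which the measured
quantities are stable to well within their acceptance margins. All
stochastic tests are seeded.

## Known limitations

* The generator does not model probe-type (Infinium I/II) effects,
  cross-reactive probe structure beyond a boolean flag, cell-type
  composition, or age-related methylation drift.
* The real study's data-dependent counts (e.g. number of retained
  probes, genome-wide DMP counts) are functions of the actual cohort and
  manifest and are deliberately not targets.
* Freeman–Halton enumeration is exponential in table size; large sparse
  tables must use the Monte Carlo mode.
* Perfect-separation logistic fits report flagged, unpenalized
  estimates; a Firth-corrected fit is out of scope.
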