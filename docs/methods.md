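# Methods

## The analysis chain

`ldsig` links strain-differential and radiation-responsive mouse
transcription to human breast-cancer survival in seven stages (see the
README for the narrative order). The statistical core is deliberately
simple and fully specified:

* **Two-group contrasts.** Every two-group comparison is an unequal-variance
  (Welch) t-test on log2 intensities with Welch–Satterthwaite degrees of
  freedom. One test everywhere keeps gene lists comparable across arms. If
  both groups have zero variance the convention is p = 1 for equal means and
  p → 0 otherwise. Benjamini–Hochberg q-values are attached to every
  contrast table for information but never enter list membership: list
  construction intentionally uses raw graded p cutoffs.
* **Graded lists.** A gene is listed when |log2 fc| ≥ log2 1.5 and
  p ≤ 0.01 (HD), ≤ 0.1 (LD) or ≤ 0.05 (baseline). The 1.5-fold criterion is
  symmetric on the log2 scale, so down-regulation is treated identically.
  The graded cutoffs trade specificity for sensitivity at low dose, where
  effects are small; lists feed enrichment-style downstream analyses, not
  per-gene claims.
* **Systemic signature.** "Same relative ratio in both tissues" is
  operationalized as: significant (p ≤ 0.05, |log2 fc| ≥ log2 1.5) in both
  blood and mammary gland with the same sign, ratios oriented sensitive
  minus resistant. r² of the two tissues' ratios over qualifying genes is
  descriptive output, not a filter. Both thresholds are exposed so users
  can sweep toward a target signature size. With fewer than 3 qualifying
  genes r² is undefined and reported as NaN with a warning.
* **Negative control.** The k genes minimizing max(|blood fc|, |MG fc|),
  ties broken by larger min p then symbol. Pure ranking — no explicit
  exclusion of signature genes — so disjointness from the signature is an
  emergent property that holds whenever at least k near-null genes exist.
* **Ortholog mapping.** Table-driven; unmapped genes are reported, not
  errors. One-to-many mappings resolve to the lexicographically first human
  symbol (deterministic and auditable; a flag expands to all targets);
  many-to-one collisions keep the first occurrence with a warning.
* **Survival association.** Scores are per-gene z-scored before summing by
  default, which makes the sum scale-free across genes; a `raw` mode sums
  stored intensities for fidelity experiments, and every report logs which
  mode ran. Median split sends ties (and the median itself) below — a rule
  that changes group sizes on discrete data, hence documented and fixed.
  The Kaplan–Meier estimator counts subjects censored at an event time as
  at risk at that time. The log-rank statistic sums observed-minus-expected
  events over distinct event times with the hypergeometric variance, which
  is exact under ties; p comes from chi-square with 1 df. Zero events
  yield p = 1, flagged. Cohort pooling, when needed, is plain
  concatenation; no Cox modelling or covariate adjustment is in scope.
* **COA refinement.** Welch t per gene between the above/below groups at
  alpha = 0.01 (configurable). Genes lower in the above-median group form
  the inverse subset; scored with −1 signs it reproduces the negated
  undirected score exactly (linearity), which the tests assert.
* **Overlap and concordance.** Overlap significance is the hypergeometric
  upper tail within a stated universe; the reported fraction rounds to the
  nearest integer percent, matching the display convention of the printed
  overlap table. Concordance is the fixed three-way direction rule;
  "no change" means failing the LD list criteria, not a tested
  equivalence, and human genes reported in both directions are never
  concordant but are counted separately.
* **Micronucleus statistics.** Frequencies are analyzed untransformed on
  the per-10⁴ scale (an arcsine-square-root column is available but off by
  default). Dose groups are compared against sham within one cell class and
  time point — the design is ambiguous on this point, so one ANOVA per
  (cell class × time point) is fitted and documented. The Dunnett
  family-wise adjustment is computed by Monte Carlo from the equicorrelated
  multivariate t (correlations √(nᵢnⱼ/((nᵢ+n_c)(nⱼ+n_c))), exact for
  unbalanced designs), default 10⁵ draws with a logged seed; adjusted p is
  floored at the per-comparison p. This avoids hard-coded tables and is
  testable against an independent reference implementation.

## Dose-response classification

Per gene, four conditions (strain × dose vs sham at one time point) give a
fold change and a significance flag (dose-appropriate graded criteria).
Classes are checked in order: *thresholded* (HD significant with the same
sign in both strains, LD significant in the sensitive strain only), then
*plateau* (within either strain, LD and HD significant, same sign,
|fc| ratio inside [2/3, 3/2]), then *opposite* (within either strain, LD
and HD significant with opposing signs), else *other*. The plateau band is
symmetric on the log scale; "similar magnitude" has no canonical number, so
the band is a package choice and is configurable in spirit (the classifier
takes raw flags/values, so any rule can be re-derived from a stored row).
The ordering means a gene matching both the thresholded and the plateau
pattern is reported as thresholded — the rarer, more informative call.

The magnitude comparison between condition response vectors is a paired
two-sided t-test on |log2 fc| (identical vectors return p = 1). The choice
of a paired test is a package decision; an unpaired Welch variant is
available.

## The synthetic-data generator

The generator emulates the study design the analysis assumes, with defaults
fixed at the emulated study's stated scale:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 10 000 | gene universe |
| `n_reps_per_group` | 4 | arrays per strain × tissue × dose × time |
| `residual_sd` | 0.25 | log2 residual noise (typical array replicate spread) |
| `n_baseline_signature` | 131 | planted systemic-signature genes |
| `baseline_effect` | 1.0 | log2 strain offset, concordant in both tissues |
| `n_ld_response` | 313 / 78 | LD responders per strain per time point |
| `n_thresholded`, `n_plateau`, `n_opposite` | 28 / 76 / 35 | planted nonlinearity subsets |
| `ld_effect`, `hd_effect` | 1.0 / 1.5 | log2 response magnitudes |
| `n_patients` | 159 | cohort size |
| `score_log_hr` | ln 2.5 | log hazard ratio per SD of the latent score |
| `censor_fraction` | 0.3 | target censored fraction |
| `mn_baseline` | RET 27.2/20.0, NCE 15.7/10.0 per 10⁴ | strain baselines (36% / 57% gaps) |
| `mn_animals_per_group` | 6 | animals per MN group |

Choices worth stating:

* **Gaussian log2 residuals, not counts.** The emulated data are normalized
  microarray intensities; additive Gaussian noise on the log2 scale is the
  standard surrogate. Probe-level artifacts, batch effects and estrous-cycle
  covariates are not modelled.
* **Response genes are planted in mammary gland only**; blood enters the
  analysis through the baseline signature, mirroring how the two tissues are
  used downstream.
* **Single latent factor drives cohort signature genes** (loading 1.0 on a
  standard-normal factor, unit noise). This guarantees the sum-score is the
  planted risk direction without per-gene hazard tuning. Event times are
  exponential with log-hazard `score_log_hr · z(u)` (proportional hazards by
  construction); censoring is independent uniform with its upper bound
  calibrated by bisection to the target censored fraction.
* **Micronucleus counts are binomial** with per-10⁴ rates = strain baseline
  × dose/time multiplier; cells scored is fixed (20 000) per record. The
  late HD multiplier persists above 1 only in the sensitive strain,
  reproducing the persistent-instability pattern.
* **Ortholog loss is Bernoulli** at `drop_fraction` (pipeline default 0.28,
  so 131 mouse genes retain ≈ 94 human orthologs in expectation); retained
  genes map to their upper-cased symbol.
* **Determinism.** Each generator draws from one
  `numpy.random.Generator` seeded from the config seed plus a fixed
  per-generator stream offset; same seed, same output, no global state.

What passing tests on these data do *not* show: performance under probe-set
redundancy, cross-platform cohort normalization, non-proportional hazards,
correlated gene-gene noise, or real ortholog ambiguity structure. The
synthetic cohort is a calibration instrument, not a stand-in for the human
cohorts' effect sizes; its variance and hazard parameters are package
choices where the emulated study states none.

## Numerical choices and degenerate inputs

* Median-split ties go below; all-identical scores are an error.
* Constant genes contribute 0 to a z-scored sum (warning logged).
* Signature genes missing from a cohort are skipped with a warning; an
  entirely missing signature is an error.
* Log-rank with no events, or with degenerate risk sets (zero variance),
  returns p = 1 flagged rather than NaN.
* Dunnett Monte Carlo is floored at the per-comparison t p-value, ensuring
  adjusted ≥ unadjusted even at finite draw counts.
* Percent rounding in overlap reports is round-half-to-even via Python's
  built-in rounding of the exact ratio.
* Fixture tables preserve duplicated category rows (two genes appear under
  two categories each in the baseline COA table); unique-gene counts
  deduplicate by symbol, category row counts do not.

## Problem sizes used by the test and acceptance runs

Unit tests run a down-scaled generator (600 genes, 40-gene signature,
80 patients) for speed; calibration suites use the design scale where it is
the point of the check: type-I error of the median-split log-rank at
100 patients per arm over 1000 null replicates (rejection within
[0.03, 0.07] at α = 0.05), power at hazard ratio 2.5 with n = 159 over 100
replicates (≥ 90% at p < 0.001), signature recovery at the full
10 000-gene / 131-signature defaults (sensitivity ≥ 90%, r² ≥ 0.8), the
negative control over 120 cohort replicates (rejection ≤ the 99% binomial
band around α), and Dunnett agreement with an independent reference within
0.005 at 4 × 10⁵ draws. `scripts/acceptance.py` runs the full pipeline at
the default design scale in a few seconds.

## Known limitations

* The criteria that produced the original 131-gene signature are not
  recoverable from its description; the both-tissue same-sign rule here is
  a faithful operationalization, and the thresholds are exposed rather than
  tuned to hit 131 on real data.
* The magnitude-comparison test behind the printed strain-contrast p-values
  is unstated in the source material; the paired-t choice here computes
  different values from the printed fold-change table alone.
* No multiple-testing control in list membership (by design), so list sizes
  are threshold-sensitive; q-values are reported alongside.
* Concordance treats absence from a list as "no change"; low-powered
  conditions therefore inflate apparent concordance, which is why the
  classifier reports the three directions per gene for auditing.
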