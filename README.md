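# ldsig

Cross-species analysis of low-dose ionizing-radiation expression signatures
and their association with breast-cancer survival.

`ldsig` is for researchers studying how genetic background shapes tissue
responses to low-dose (LD, fractionated 7.5 cGy) versus high-dose (HD,
fractionated 1.8 Gy) radiation, using a radiation-sensitive and a
radiation-resistant mouse strain as the model contrast. It implements, as a
tested and reusable pipeline, the full inference chain from mouse expression
arrays to human survival:

1. **Graded differential expression.** Per-gene unequal-variance (Welch)
   t-tests on log2 intensities; gene lists at fold change ≥ 1.5 with
   p ≤ 0.01 (HD), p ≤ 0.1 (LD) or p ≤ 0.05 (strain baseline).
2. **Systemic baseline signature.** Genes differentially expressed between
   strains with the *same direction* in both mammary gland and blood; the
   squared Pearson correlation r² of the two tissues' log-ratios is reported
   descriptively. A negative control takes the genes *least* changed in both
   tissues.
3. **Ortholog-mapped survival scoring.** Mouse signatures are translated to
   human symbols through a lossy ortholog table; each patient gets the sum of
   z-scored signature-gene expression
   `score_i = Σ_g s_g · z_{gi}` (optional per-gene signs `s_g`); patients
   are dichotomized at the cohort median score (ties below); disease-free
   survival is compared by the Kaplan–Meier product-limit estimator and the
   two-group log-rank test (hypergeometric variance at tied event times).
4. **COA refinement.** Per-gene Welch t-tests between above- and
   below-median patients flag cancer-outcome-associated (COA) genes at
   p < 0.01; genes expressed *lower* in the above-median group form a
   directed (−1) sub-signature that is re-tested.
5. **Concordance and overlap.** Hypergeometric gene-set overlap tests, and
   the cross-species direction rule: concordant ⇔ up in the sensitive
   strain, down-or-unchanged in the resistant strain, and up in the human
   comparator — or the full mirror image.
6. **Dose nonlinearity.** Genes classified as *thresholded* (HD response in
   both strains, LD response only in the sensitive strain), *plateau*
   (LD ≈ HD magnitude) or *opposite* (LD and HD signs opposed).
7. **Micronucleus statistics.** Per-animal MN frequencies per 10⁴ cells,
   Welch baseline strain comparison, and dose-vs-sham comparisons by one-way
   ANOVA with a Monte-Carlo Dunnett adjustment.

A synthetic-data module generates every input — the two-strain, two-tissue
expression study, a right-censored survival cohort driven by a latent
signature factor, ortholog tables and binomial micronucleus counts — with
recorded ground truth, so the entire chain is testable without downloads.
The package also ships transcriptions of the printed COA gene tables,
overlap counts and thresholded-gene fold-change table as fixtures.

## Worked example

```python
from ldsig import RunConfig, run_all

report = run_all(RunConfig(seed=1))
sig = report["systemic_signature"]
print(f"signature: {sig['n_genes']} genes, r^2 = {sig['r_squared']:.3f}")
print(f"orthologs mapped: {report['orthologs']['n_human']} of "
      f"{report['orthologs']['n_mouse']}")
surv = report["survival"]
print(f"median-split log-rank p = {surv['logrank_p']:.3g}; "
      f"COA genes = {surv['n_coa']}")
print(f"negative control p = {surv['negative_control']['p_value']:.3g}")
```

prints

```
signature: 131 genes, r^2 = 0.973
orthologs mapped: 97 of 131
median-split log-rank p = 2.22e-13; COA genes = 97
negative control p = 0.985
```

All 131 planted baseline-signature genes are recovered with strongly
correlated cross-tissue ratios; after ortholog loss, the 97-gene human score
splits the synthetic cohort into groups with sharply different survival
(log-rank p ≈ 2 × 10⁻¹³), while the least-differential control signature
shows no association (p ≈ 0.99) — the qualitative behaviour the method is
designed to detect.

The same run is available from the shell:

```sh
ldsig run --seed 1 --out results/run1     # full pipeline + report bundle
ldsig simulate --seed 1 --out data/       # write synthetic inputs as TSV
ldsig fixtures                            # printed-table fixture summaries
```

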