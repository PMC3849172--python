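# Methods

## The classification model

The deployed classifier is a nearest-centroid rule in correlation space.
A tumor's profile over the reporter genes is summarized by the correlation
index `CI = r(x, c_good)`, the Pearson correlation with the mean profile of
good-prognosis training tumors, and thresholded: `CI > t → good prognosis`.
Because Pearson correlation is invariant to shifting or positively scaling a
profile, the rule is unaffected by per-sample global intensity effects
(array brightness, RNA amount) — the reason this family of classifiers
travels well across hybridizations.

During signature *selection*, leave-one-out cross-validation instead uses a
two-centroid comparison (`r` against the good and the poor centroid, each
recomputed without the held-out tumor; ties go to poor, the conservative
call). The deployed single-centroid + threshold rule and the two-centroid
LOOCV rule are both implemented because the method is naturally described
both ways: the two-centroid rule needs no calibration and is the right
objective during selection; the single-centroid rule with an FNR-calibrated
threshold is the right deployment form when a validation cohort may have a
different class mix.

## Stage-by-stage choices

**Normalization.** Per-sample median-centering on the normalization probes
after log2 transformation. This is the minimal scheme that actually uses a
declared normalization-probe set; no background correction or quantile
scheme is layered on. The operation is idempotent, and the per-sample
median of normalization probes is exactly zero afterwards.

**Differential screening.** Paired t-test on per-patient log2 differences
(the design is paired: each patient contributes both lesion types), with
selection requiring fold change > `fc_min` (default 2) *and* p ≤ `p_max`
(default 0.05) jointly. A Welch unpaired mode exists for unpaired designs.
Zero-variance probes get the degenerate p-values 1 (zero mean difference)
or 0 (nonzero), logged. No multiple-testing correction is applied by
default — the screening is a filter, not an inference — but
Benjamini–Hochberg is available (`adjust="bh"`).

**Clustering.** Distance `1 − Pearson r` between item profiles, average
linkage. The two prognosis groups are the subtrees under the final merge.
Agglomeration is delegated to scipy's deterministic nearest-neighbor-chain
implementation and validated against a brute-force agglomeration oracle in
the tests. The outcome labeling of the two clusters is the one degree of
freedom the data must fix: the cluster with the longer mean observed
survival is called *good* (labeling from the 5-year metastasis flag is
available as `outcome_coding="metastasis"`).

**SVM confirmation.** A linear soft-margin SVM (C = 1) under LOOCV confirms
the malignant/premalignant split and names misclassified samples. Linear
kernel and C = 1 are the natural defaults in the n ≪ p regime; both are
exposed.

**Ranking and forward selection.** Pearson correlation of each screened
probe with the binary outcome (good = 1, poor = 0), filtered at
|r| > `r_min` (default 0.3, strict), ranked by |r| with ties broken by
probe ID for determinism. Candidate signature sizes are batch multiples
(default 5) up to the pool size; the selected size is the *smallest* size
attaining the maximum of the LOOCV accuracy curve. Smallest-at-max is
deterministic and favors minimality; when the curve saturates early the
signature is small, which is the intended behavior of a minimal-panel
procedure.

**Threshold calibration.** `t` is the largest cutoff such that at most a
fraction `target_fnr` (default 0.13) of good-prognosis training tumors have
CI ≤ t. Concretely `t` is placed midway between the critical good score
and the largest score strictly below it, so with `target_fnr = 0` and
separated classes it is the midpoint of the separating gap. The achieved
FNR never exceeds the target by construction.

**Evaluation.** ROC by sweeping all score thresholds (tied scores produce
diagonal segments; the trapezoidal AUC equals the Mann–Whitney statistic
with the ½-tie convention). The AUC confidence interval is a stratified
bootstrap percentile interval (default 2,000 resamples; resampling within
class keeps every replicate two-class); in a binormal simulation with true
AUC 0.75 at n = 200 the nominal 95% interval covers at ~94% (the test suite
checks [0.92, 0.98]). The positive class is *good prognosis* throughout;
reversing it reflects the AUC about 0.5. Kaplan–Meier estimation and the
unweighted two-sample log-rank test come from `lifelines`; Fisher's exact
test (two-sided, conditional odds ratio) from `scipy`. A plain two-group
comparison is reported; no multivariable proportional-hazards adjustment is
attempted.

## The synthetic study generator

All values are simulated directly on the log2 scale:

```
x[p, s] = b[p] + o[patient(s)] + de[p]·1{tumor}
          + prog[p]·1{tumor, poor patient} + ε[p, s]
```

| parameter | default | meaning |
| --- | --- | --- |
| `n_pairs` | 20 | patients, each with tumor + premalignant sample |
| `n_candidate_probes` / `n_panel_probes` / `n_normalization_probes` | 696 / 98 / 915 | array composition (98 = 44 collagen-like + 54 hormone-like) |
| `n_de_genes` | 371 | planted tumor-vs-premalignant genes |
| `n_prognosis_genes` | 74 | subset of the DE genes carrying a good/poor shift |
| `de_log2_effect` | 2.0 | magnitude of each planted DE effect (random sign) |
| `prognosis_log2_effect` | 1.5 | magnitude of each planted prognostic shift (random sign) |
| `noise_sd` | 0.5 | per-observation Gaussian noise, log2 scale |
| `baseline_mean`, `baseline_sd` | 8.0, 1.5 | per-probe baseline level (typical one-color log2 intensity spread) |
| `patient_sd` | 0.3 | scalar per-patient offset shared by both samples |
| `poor_fraction` | 0.5 | fraction of poor-prognosis patients |
| `hazard_ratio`, `median_survival_good`, `censor_time` | 4.0, 60, 60 months | exponential survival, administrative censoring |
| `n_validation` | 11 | independent tumor-only validation patients |

Design notes:

- The per-patient offset is a *scalar* (constant across probes). It cancels
  exactly in paired differences — making the paired test strictly more
  powerful than an unpaired one, as a paired design should be — and, being a
  profile shift, is invisible to correlation-distance clustering and to the
  CI classifier. Noiseless configurations are therefore exactly recoverable
  end to end, which the tests exploit.
- Planted effects have fixed magnitude and random sign; survival is
  exponential with a group-specific hazard (good-group median equal to the
  60-month horizon, a mixed-stage resected-cohort figure) and the 5-year
  metastasis flag is simply event-before-horizon.
- The validation cohort reuses the training run's baselines and effects on
  an RNG stream derived from the seed, so probe sets match and repeated
  calls are reproducible.

What the generator does *not* emulate: batch and dye effects, probe-level
variance heterogeneity, correlated gene modules, non-exponential hazards,
informative censoring, or annotation errors. Passing recovery tests
therefore demonstrate the pipeline's correctness under its own model, not
clinical performance on real cohorts.

A note on the selected signature size: with the default planted shift
(1.5 log2 units against ~0.58 total noise), a handful of reporters already
separates the groups, so the LOOCV curve saturates in the first batches and
smallest-at-max returns a small signature (typically 5–15 genes) whose
members are almost all planted prognostic genes. Recovering a signature
whose *size* matches the planted 74 would require much weaker per-gene
effects; the recovery tests accordingly score overlap precision and
held-out accuracy, not size.

## Numerical conventions

- Ties: rank ties by probe ID; CI ties classify poor; scores equal to the
  threshold are negative (poor) calls; cluster 1 is the cluster containing
  the first leaf.
- Degenerate inputs raise typed errors naming the offending item (constant
  profiles, zero-variance clustering items, single-class label sets, empty
  pools, nonpositive raw intensities), except where a convention is stated
  (degenerate t-test p-values; Fisher zero margin → p = 1, odds ratio
  undefined).
- Missing values are allowed on input (`NA`), excluded pairwise in
  correlations, never imputed.
- Matrix files are UTF-8 TSV; floats are written with `%.17g`, so a
  write→read round trip is value-identical.
- One RNG stream per generated dataset, keyed by the seed; the pipeline
  derives per-stage streams (e.g. the bootstrap) from its own seed, and no
  output embeds timestamps, so identical configurations give byte-identical
  artifacts.

## Problem sizes used by the test suite

The unit suite exercises a scaled-down study (12 pairs, 130 probes, 30
planted DE / 10 prognostic genes); the acceptance suite re-runs the full
study scale (20 pairs, 1,709 probes, 371/74 planted genes, 11 validation
tumors) across 20 seeds for parameter recovery, 5,551 exhaustive 2×2 tables
for Fisher's test, and 500 binormal replicates for bootstrap coverage.

## Known limitations

- The outcome labels that feed the ranking step come from an unsupervised
  split; when the clustering is wrong, downstream correlation ranking
  inherits the error (mitigated by `outcome_coding="metastasis"`).
- The |r| filter and LOOCV reuse the same training tumors, so the reported
  LOOCV accuracy curve is optimistically biased — the validation cohort is
  the honest estimate.
- ROC metrics on an 11-tumor validation cohort are extremely noisy; the
  bootstrap CI reflects, but cannot repair, that.
- Gene-level collapsing of multiple probes, moderated-variance statistics,
  and regularized feature selection are deliberately out of scope.
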