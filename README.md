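# pdpatterns

Longitudinal plasma-proteomic biomarker analysis for placebo-controlled
trials, built around three questions a trial proteomics team asks of a
multiplex immunoassay panel measured at baseline, week 4 and week 16:

1. **Which analytes track disease severity?** L1-regularized (Lasso)
   selection of analytes against clinical severity scores (PASI, ASDAS,
   DAS28, BASDAI, BASFI), repeated per visit and filtered for cross-visit
   robustness (constant sign, significant at every visit), followed by
   age/gender-adjusted regression models and an aggregated biomarker
   score `S = Σᵢ βᵢ·xᵢ` compared between placebo, responders and
   non-responders by Mann–Whitney U.
2. **Which analytes does the drug move?** Differential expression
   placebo-vs-treated per visit with empirical-Bayes variance moderation
   (per-analyte residual variances shrunk toward a moment-matched
   scaled-F prior, moderated t on d₀+d degrees of freedom, BH FDR),
   subject-random-intercept mixed models pooling the two post-baseline
   visits, and a pooled-disease fixed-effect meta-analysis on the analyte
   intersection.
3. **What are the temporal response patterns?** An uncertainty-weighted
   non-negative matrix factorization of the analyte × (subgroup, visit)
   mean-expression matrix D with standard-error matrix S, minimizing
   χ² = Σ((D − AP)/S)² over non-negative amplitudes A and unit-norm
   patterns P, run many times from random seeds; patterns are merged
   across runs by RMSD (5% of the relative-strength scale), analytes are
   assigned per run by the trajectory-distance marker statistic and kept
   only when their occurrence frequency strictly exceeds 50% of runs.
   The top decliners of a response-associated pattern feed a
   responder-vs-non-responder geometric-mean-decline test.

The measurements behind the original three trials are not public, so the
package includes a first-class synthetic cohort generator
(`pdpatterns.cohort`) that emulates their structure — log-normal analyte
concentrations with subject random effects, LLOQ censoring (~15% of
analytes censored nearly everywhere, ~5% partially), planted
severity-linked analytes and planted subgroup trajectory templates — with
a ground-truth object so every stage is testable against known answers.
Preprocessing (`pdpatterns.preprocess`) reproduces the panel workflow:
drop analytes/samples with >50% missing-or-censored cells, impute missing
cells with the analyte mean and censored cells with ½·LLOQ, then log2 +
quantile normalization.

## Worked example

```python
from pdpatterns.cohort import default_config, generate_cohort
from pdpatterns import preprocess as prep, severity as sev

cohort = generate_cohort(default_config(seed=42))   # 526 subjects, 3 trials
raw = cohort.panels["PSOR"]
kept, report = prep.qc_filter(raw)
panel = prep.log2_quantile_normalize(prep.impute(kept))
print(f"PSOR panel: {raw.values.shape[1]} analytes -> "
      f"{panel.values.shape[1]} after QC")

meta = cohort.meta
results = {v: sev.lasso_select(panel, meta.loc[meta.visit == v, "PASI"],
                               seed=42, visit=v)
           for v in ("week0", "week4", "week16")}
selection = sev.robust_biomarkers(results)
print("robust severity biomarkers:", selection.robust)

pasi0 = meta.loc[meta.visit == "week0", "PASI"]
fit = sev.fit_adjusted(panel, pasi0, meta, selection.robust[:2], visit="week0")
for analyte in selection.robust[:2]:
    beta, p = fit.terms[analyte]
    print(f"  {analyte}: beta = {beta:.2f}, p = {p:.2g}")
print(f"additive model R^2 = {fit.r2:.2f}")
```

Output:

```
PSOR panel: 122 analytes -> 103 after QC
robust severity biomarkers: ['ANL0001', 'ANL0002']
  ANL0001: beta = 3.62, p = 2.9e-07
  ANL0002: beta = 3.31, p = 1.6e-08
additive model R^2 = 0.33
```

The generator planted exactly two PASI-linked analytes (slopes 3.5 and
3.4 per log2 unit, residual noise set for a combined R² near 0.3); the
cross-visit robust selection recovers exactly that pair, and the
age/gender-adjusted additive model estimates their slopes and explained
variance at the planted magnitudes.

The full study replica — cohort → preprocessing → severity → differential
expression → consensus patterns, with a reproducibility manifest — runs
from one command:

```sh
pdpatterns run --out results/study --seed 0
```

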