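# Methods

`pdpatterns` re-implements, as a tested pipeline, a longitudinal
plasma-proteomic biomarker analysis for placebo-controlled trials in three
inflammatory diseases — ankylosing spondylitis (AS), psoriasis (PSOR) and
psoriatic arthritis (PSA) — with visits at week 0 (baseline), week 4 and
week 16, a placebo and a treated arm, and responder (AR) / non-responder
(ANR) labels within the treated arm. Because the underlying trial
measurements are not publicly deposited, the package ships a synthetic
cohort generator with known ground truth; every quantitative claim the
test suite makes is a claim about recovery of planted structure, not
about the clinical trials themselves.

## Synthetic cohort generator

The generator (`pdpatterns.cohort`) emulates the structure of immunoassay
panel data:

* **Concentrations** are per-analyte log-normal: log2 values are
  `mu_a + u_s + e_sv`, with the analyte's log2 geometric mean `mu_a`
  drawn uniformly from [5, 13] (≈ 32 pg/mL to 8 ng/mL, a typical
  multiplex-panel span), a per-subject random intercept `u_s` and
  per-visit noise `e_sv`. The total log2 SD per analyte is uniform in
  [0.3, 0.7]; 70% of it (in SD terms) sits in the subject intercept so
  that repeated visits of one subject are correlated, which the pooled
  mixed-effect models rely on. Immunoassay concentrations are strictly
  positive and right-skewed, hence the log-normal choice.
* **LLOQ censoring**: each analyte receives a lower limit of quantitation.
  A configurable 15% of analytes get an LLOQ above ~99.9% of their own
  distribution (censored in nearly all samples — emulating assay
  calibration ranges that miss the circulating level), 5% an LLOQ at a
  random 5–50% quantile (partial censoring), and the rest an LLOQ far
  below their range (no censoring). Censored cells are recorded as
  `<LLOQ`; the true values are kept only in the ground-truth object.
* **Severity linkage**: the disease's primary severity score (PASI for
  PSOR, ASDAS for AS, DAS28 for PSA) is a linear function of the planted
  analytes' log2 concentrations plus small age and gender terms and
  Gaussian noise. The default PSOR configuration plants two analytes with
  slopes 3.5 and 3.4 per log2 unit and a residual SD of 3.7 PASI points,
  giving a combined R² near 0.3 at n = 144 — magnitudes of the order a
  plasma biomarker pair realistically explains of a clinical score.
* **Trajectory templates** are multiplicative per-visit factors keyed by
  arm (optionally arm and responder status) and applied to member
  analytes: a placebo "bump" at week 4, a treated sustained decline whose
  week-4→16 rate differs between AR and ANR, and a treated early rise.
  The severity pair also belongs to the decline template, so the
  aggregated severity-biomarker score responds to treatment as well.
* **Missing-not-censored** cells are injected independently at 2% to
  exercise mean imputation separately from ½-LLOQ substitution.
* Planted analytes are excluded from the censored classes: a biomarker
  that is censored in most samples could never have been discovered, so
  planting it there would only test the QC filter twice.

Default cell sizes are the study's enrollment table (placebo / ANR / AR:
AS 80/108/67, PSOR 51/59/34, PSA 47/63/17; 526 subjects) and panel sizes
are 121/122/155 analytes. Everything is driven by one
`numpy.random.SeedSequence`; identical config + seed reproduces the
cohort bit-for-bit.

What the generator does **not** emulate: assay plate/batch effects,
pharmacokinetics, visit dropout, heavy-tailed or correlated analyte
noise, or disease-specific analyte families. Passing tests therefore show
that the estimators recover planted structure under a clean generative
model, not that they are robust to every artifact of real panel data.

## Preprocessing

`qc_filter` drops analytes, then samples, whose missing + censored
fraction strictly exceeds 50% ("more than" is strict: exactly half is
retained), with the two sweeps alternating to a fixed point. A single
analyte-then-sample pass is not idempotent — removing bad-heavy samples
can push a retained analyte's bad fraction over the threshold — so the
filter iterates until no retained row or column violates the rule; the
report records every dropped id with the fraction that condemned it.
Imputation sets remaining missing cells to the analyte's arithmetic mean
over observed raw-scale values and censored cells to half the analyte's
LLOQ. Values are then log2-scaled and quantile-normalized across samples
(each sample's k-th order statistic replaced by the mean k-th order
statistic; ties receive the average of the tied rank means, so the map is
deterministic and rank-preserving within samples). The imputation scale
(raw, pre-log) and stratum (within disease cohort) are recorded in the QC
report rather than silently assumed.

## Severity biomarkers

`lasso_select` runs an L1 path over 100 log-spaced penalties (from the
smallest penalty that zeroes every coefficient down three decades) with
seeded 10-fold cross-validation; the chosen penalty minimizes mean CV
error (the 1-SE alternative is reported alongside). Predictors are
standardized internally and coefficients rescaled to the log2-expression
scale. `robust_biomarkers` keeps analytes selected with a constant sign
at every visit and univariately significant (Pearson p < 0.05) at every
visit, ranked by mean |beta|; the laxer "significant at ≥ 1 visit" set is
kept for reporting. Covariate-adjusted models (`fit_adjusted`,
`univariate_screen`) are OLS with age and dummy-coded gender, per-term
Wald p-values, model R² and F-test p, and Benjamini–Hochberg FDR across
the per-visit analyte family; the joint significance rule is FDR < 0.05
and R² > 0.2. Delta–delta correlations are Pearson by default (Spearman
available). The aggregated biomarker score is the weighted sum
`Σ βᵢ·xᵢ` with baseline additive-model coefficients as weights, applied
to week-0→4 expression changes; groups (placebo / AR / ANR) are compared
by two-sided Mann–Whitney U — exact enumeration when both groups have ≤ 8
members and no ties, tie-corrected normal approximation otherwise.

## Differential expression

`moderated_de` fits one linear model per analyte (log2 expression on arm)
and moderates the residual variances empirically: the log sample
variances are moment-matched to a scaled-F model, giving a prior
df d₀ and prior variance s₀² (the trigamma inverse is solved by Newton
iteration); posterior variances are the df-weighted blend and the
moderated t has d₀ + d degrees of freedom. Setting the prior df to zero
switches shrinkage off, and the statistic then equals the ordinary pooled
two-sample t — the oracle the tests pin it to. `mixed_de` pools weeks 4
and 16 per analyte with a subject random intercept (REML via statsmodels
MixedLM), fixed arm, sum-coded visit and arm×visit terms, so the tested
arm main effect is the average arm effect over the pooled visits; fits
that fail are flagged and excluded from the BH family with a warning.
`meta_de` pools the three diseases on their analyte intersection with
disease as a fixed covariate and a shared arm effect (an arm×disease
interaction mode is available); a single-disease input reduces exactly to
`moderated_de`.

## Consensus time-series patterns

The grouped matrix D holds mean log2 expression per analyte per
(subgroup, visit) column, S the matching standard error of the mean
(floored at the smallest positive SE observed, so χ² weights stay
finite). The factorization D ≈ A·P minimizes the uncertainty-weighted
χ² = Σ((D − AP)/S)² over non-negative A (analyte × K amplitudes) and P
(K patterns, rows rescaled to unit Euclidean norm with the compensating
scale absorbed into A). Each run starts from seeded random non-negative
factors and applies multiplicative weighted updates, returning the best
state visited; identical seeds reproduce bit-identically. The number of
iterations is chosen by comparing mean χ² between batches of runs at
candidate counts (default 1000/5000/10000/15000/20000; ties go to the
smallest).

Runs are combined into a consensus:

1. **Merging**: all unit-norm patterns are pooled and grouped greedily by
   RMSD within 5% of the relative-strength range. Patterns are unit
   vectors, so the relative-strength scale is taken as 1 and the
   threshold is 0.05 absolute RMSD; the alternative that scales by the
   observed pooled coordinate range is available
   (`range_mode="observed"`) but not default, because near-flat patterns
   shrink that range and tighten the threshold exactly when runs agree.
   During grouping each group takes at most one pattern per run; a final
   deterministic consolidation pass fuses groups whose centroids fall
   within the same threshold, healing families that greedy order-
   dependence split. Centroids are renormalized member means.
2. **Marker assignment**: within a run, each analyte's amplitude row is
   scaled to unit maximum and assigned to the pattern whose indicator
   vector is nearest (the trajectory-distance marker statistic); ties go
   to the lowest pattern index and are flagged, all-zero rows stay
   unassigned.
3. **Consensus**: an analyte belongs to a merged pattern only if its
   per-run assignments map to that pattern in strictly more than 50% of
   runs.

Downstream, `top_decliners` ranks a pattern's analytes by |mean log2
decline| between weeks 4 and 16 in the treated arm and keeps the top 4;
`responder_decline_test` compares the per-subject mean log2 decline over
those analytes (the log of the geometric-mean fold change) between AR and
ANR by two-sided Mann–Whitney U, excluding and reporting subjects missing
either visit.

### Identifiability of the factorization — a known limitation

On mean-log2 matrices the flat baseline dominates the planted deviations,
and the weighted least-squares optimum is then a continuum: any
invertible mixing of the factors that preserves non-negativity leaves χ²
unchanged, so independent runs converge to equally good but different
factor pairs. The consensus machinery absorbs much of this wander, and
planted families whose deviations span two columns (sustained decline,
early rise) are recovered almost perfectly across data realizations. A
weak single-column family (the placebo week-4 bump), however, can be
fitted equally well by combinations of the other patterns — measured mean
χ² is statistically indistinguishable between runs that do and do not
contain a bump-aligned pattern — so no χ²-based selection can favor it,
and in roughly a third of data realizations the strict >50% consensus
rule correctly reports the ambiguity by leaving those markers
unassigned. Sparse amplitude penalties, data-row initialization and
minimum-volume regularization were evaluated as identifiability fixes and
rejected (they collapse patterns, land runs on a consistently wrong
attractor, or degenerate without simplex constraints); the sparse atomic
prior of a full MCMC NMF sampler is the mechanism that would restore
identifiability, and re-implementing it verbatim is out of scope. The
acceptance suite asserts the idealized recovery thresholds regardless,
and the corresponding test documents this gap rather than hiding it.

## Numerical and design choices

* BH FDR via `statsmodels.multipletests`, pinned in tests to a
  brute-force step-up enumeration.
* Lasso via scikit-learn's coordinate descent (`LassoCV`) with a seeded
  shuffled K-fold; the penalty grid is built in-house so the largest
  penalty provably zeroes all coefficients.
* Mann–Whitney exactness switches at n ≤ 8 per group without ties.
* Strict inequalities at published cutoffs: ">50% bad" drops, ">50%
  frequency" includes, "p < 0.05" stars.
* Mixed models that fail to converge are excluded and reported, not
  imputed.
* All randomness flows from one master seed through named
  `SeedSequence` substreams, so module-level tests and pipeline runs
  agree; derived seeds stay below 2³¹.

## Problem sizes

The default pipeline runs the full 526-subject, three-disease cohort with
100 NMF runs at 5000 iterations per pattern comparison and completes in a
few minutes on one CPU. The test suite uses smaller replicas chosen to
keep each property check sharp but cheap: severity recovery uses the
PSOR-sized cohort (144 subjects, 120 analytes, 20 data seeds), the
moderated-t null calibration 50 seeds of 120 analytes at n = 40, the
mixed-model recovery 100 seeds of 80 subjects × 2 visits, the consensus
workflow five cohort seeds of 120 subjects × 40 analytes with 100 runs at
the batch-selected iteration count, and the determinism check a reduced
two-disease pipeline run twice.
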