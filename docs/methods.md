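# Methods

## Model and assumptions

The package models paired tumor/normal expression cohorts in two levels.
Let Y_i ∈ {0,1} be tissue status of sample i (1 = tumor), and let mRNA and
miRNA values be TMM-normalized, log2-transformed expression.

1. **Mechanistic level.** For each disease-associated mRNA j,
   `mRNA_j = α₀ + Σ_m α_m miRNA_m + e_j`, fit by lasso over the full panel of
   disease-associated miRNAs.  The linear predictor η_j (intercept included)
   is the miRNA-explained component; e_j = mRNA_j − η_j is defined by
   subtraction, so the decomposition is exact to floating-point re-association
   (≤ 1 ulp).  p > n is expected and handled natively by the penalty.
2. **Clinical level.** Lasso-penalized logistic regression of Y on
   {η_j, e_j} for all mediated mRNAs plus one column per orphan mRNA/miRNA
   (log-scale values, the same scale as the mechanistic inputs).  All columns
   are standardized and share a single penalty; the intercept is unpenalized.
   Samples are treated as independent rather than pair-matched: the
   dependence diagnostic (per-feature Pearson correlation between the tumor
   and matched normal vectors across patients) typically shows ~85–90% of
   features with |r| < 0.3 on data of this design, so random patient effects
   are omitted.  Cross-validation folds are nevertheless assigned at the
   patient level so a patient's two samples never straddle a fold — a
   deliberate guard against leakage.
3. **Pair emission.** β_ηj ≠ 0 (exact zero test; lasso zeros are exact)
   emits (mRNA_j, m) for every m in the mechanistic support of j.  The rule
   is deliberately inclusive: some emitted miRNAs may be individually
   irrelevant.  β_ej ≠ 0 marks mRNA_j as residual-driven (no pairs).

## Upstream processing

- **TMM.**  Reference column: upper quartile of library-size-scaled counts
  closest to the mean upper quartile.  Per column: gene-wise
  M = log2 ratio and A = mean log2 abundance of proportions against the
  reference, genes with a zero in either column excluded, 30% two-sided trim
  on M and 5% on A (rank-based, intersection), inverse-asymptotic-variance
  weights, factors rescaled to geometric mean 1.  Verified in the test suite
  against an independently coded transcription (1e-8) and against the
  standard R implementation (edgeR `calcNormFactors`, 1e-8).
- **Log transform.**  value → log2(value + 1).  Base 2 and pseudocount 1 are
  conventional defaults; both are configurable.
- **Paired prefilter.**  Per feature, t = mean(d)/(sd(d)/√n) on within-
  patient differences d, two-sided p from t_{n−1}, BH step-up per feature
  kind (mRNAs and miRNAs adjusted separately, matching the convention of
  reporting the two selected-feature counts separately).  "FDR < 0.05" is a
  strict inequality.  The t-test runs on normalized log values; fold changes
  are median(raw tumor)/median(raw normal), with a signed infinity sentinel
  (never clipped) when the normal median is zero.  Zero-variance difference
  vectors are flagged degenerate, reported with p = 1 and never selected.
- **Missingness.**  Features missing in more than `max_missing_fraction` of
  samples are dropped whole; remaining missing cells are zero-filled only on
  explicit request, never silently.  Both NA tokens and empty cells count as
  missing at read time.

## Penalty selection

Lambda grids are geometric, 100 points from the smallest all-zero penalty
λ_max = max_j |x_jᵀ(y − ȳ)|/n down to 0.01·λ_max (60 points to 10⁻³·λ_max for
the logistic model).  CV criterion: validation MSE (gaussian) or binomial
deviance (logistic).  Fold assignment is patient-level and seeded per mRNA
from CRC32(mrna_id) XOR master seed, so mechanistic results are independent
of iteration order and parallelization; the clinical fit uses a distinct
stream derived from the master seed.

**Default rule: one-standard-error (`cv_1se`).**  The package's product is a
selected support, not a predictor.  The CV-error minimiser (`cv_min`,
available by config) is well known to over-select: on this package's own
canonical simulation it admits ~3–4 noise miRNAs per mRNA beyond the planted
regulators (behavior reproduced exactly by the reference R implementation,
cv.glmnet, on exported instances), and the inclusive pair-emission rule then
multiplies those extra support members into emitted false pairs.  The 1-SE
rule trades a small amount of within-support recall for markedly tighter
supports and is the appropriate default when the output is a pair list
handed to biological follow-up.  The acceptance script reports recovery
metrics under both rules.

Degenerate cases: fewer samples than 2×folds falls back to leave-one-out CV
(logged); zero-variance response yields an empty support with η ≡ mean(y);
λ = 0 is solved as ordinary least squares; near-separation in the logistic
fit (standardized coefficients beyond 50) walks the penalty back up the path
with a logged warning.

## Synthetic data

The generator emulates what the model assumes, with known truth:

- miRNA log2 abundance = baseline U(4,10) + N(0, σ²), with tumor-only shifts
  on disease miRNAs; mRNA log2 abundance = baseline U(4,12) + A·(centered
  miRNA) + N(0, σ²) + tumor-only residual-channel shifts.  A is sparse;
  regulatory coefficients are ±U(0.5, 1.0) (log-log regulatory slopes below
  1 in magnitude are the realistic regime).
- Disease effects are calibrated per affected molecule: a directly shifted
  miRNA moves by the effect size (log2 units); an η-channel mRNA receives
  the same total effect delivered through its regulators (Σ α_m δ_m =
  effect, split equally, shift signs aligned with coefficients); a
  residual-channel mRNA moves by the effect on its residual.  True pairs are
  the nonzero A entries of η-channel mRNAs.
- Log abundances are exponentiated, scaled by per-sample library sizes
  2^U(−1,1) (so TMM has something to correct; presets can switch to equal
  library sizes), and rounded to counts — overdispersed counts through the
  lognormal layer while keeping the log-scale linear model exactly correct.
  An explicit negative-binomial layer was deliberately not used for this
  reason.

Presets: `null` (all effects zero), `default` (30 patients, 200 mRNAs, 60
miRNAs, 5 η-channel mRNAs × 3 disjoint regulators = 15 true pairs, effect
1.5 log2 units, σ = 0.5), `easy` (effect 2.0, σ = 0.25), `hard` (effect
0.75, σ = 0.8).  All non-null presets also plant 20 background-regulated,
non-disease mRNAs whose regulators come only from non-disease miRNAs, so
truth labels stay unambiguous.  The residual and direct-miRNA disease
channels are first-class generator capabilities (exercised in the tests via
`make_truth` overrides) but are zero in the named presets.

**What the simulator does not emulate** — and hence what passing tests do not
show about real data: feature-level count dispersion heterogeneity, miRNAs
regulating hundreds of targets and overlapping regulator sets, batch and
composition effects beyond global library scaling, annotation errors, and
real panels 10–100× larger.  Recovery numbers on the presets are
scaled-down, best-case figures, not forecasts for cohort data.

## Known limitations

- With strong per-molecule effects the clinical design can be linearly
  separable; l1-penalized logistic regression then concentrates on a minimal
  separating subset of columns, which can drop some truly disease-mediated
  η's.  The path cap mitigates coefficient blow-up, not the selection
  behavior itself.
- Under `cv_min`, support over-selection combined with the inclusive
  emission rule bounds pair precision well below what `cv_1se` achieves;
  this is a property of the CV-minimising lasso shared by the reference
  implementation, not of this package.
- η and e of one mRNA are selected independently (no group structure), and
  all clinical columns share one penalty; both are the simplest faithful
  reading of the model and are stated assumptions, not estimated choices.
- The correlation comparator is plain pairwise Pearson screening, an
  approximation to component-based canonical-correlation comparators.
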