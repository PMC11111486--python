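# Methods

## Setting

`mrcausal` performs two-sample Mendelian randomization on GWAS summary
statistics: per-variant association estimates (β, SE, p, effect-allele
frequency, N) for an exposure and an outcome, measured in independent
samples. The package covers instrument screening, allele harmonization, five
causal estimators, sensitivity diagnostics, and a ground-truth simulator.
Effects for a binary exposure are log-odds per allele; the causal estimate
is therefore a log-odds slope and is reported alongside its exponential (an
odds ratio) with a 95% CI computed as exp(b ∓ 1.959964·se).

## Harmonization

Outcome records are aligned to the exposure effect allele. Identical or
strand-complement allele pairs pass through; swapped pairs (possibly after
complementing) negate the outcome beta and replace its EAF by 1−EAF. For
palindromic variants (A/T, G/C) the strand cannot be resolved from alleles,
so orientation is inferred from allele frequency: the variant is retained,
unflipped, only when both EAFs fall on the same side of 0.5 outside the
ambiguity window (default 0.42–0.58); anything else — mid-frequency,
opposite sides, or missing EAF — is dropped with a logged reason. A strict
mode drops all palindromic variants. The exposure orientation is never
altered, the operation is idempotent, and every input variant lands in
either the harmonized output or the exclusion log. Note that for palindromic
variants a relabelled (swapped-and-negated) outcome record is *not*
equivalent to the original: frequency inference deliberately ignores allele
labels, so relabelling moves the EAF to the other side and the variant is
dropped rather than silently flipped.

Only single-base A/C/G/T alleles are accepted at read time; palindromic
logic is undefined for indels. Missing EAF is tolerated on input but any
computation that needs it (palindromic inference, F-statistics, Steiger)
fails loudly rather than imputing.

## Instrument screening

Stage order: p < 5×10⁻⁸ on the exposure → MAF ≥ 0.01 → greedy LD clumping →
harmonization → per-variant F ≥ 10 → Steiger directionality. Clumping must
precede harmonization (it is an exposure-only operation); Steiger needs both
sides so it must follow. The audit trail records counts and removed IDs per
stage and telescopes exactly.

Clumping sorts by ascending p (ties: chromosome label, then position) and
repeatedly keeps the best remaining variant, removing variants that are both
within the distance window (default 10,000 kb) on the same chromosome and
correlated at r² ≥ 0.001. Distance alone never removes; correlation alone
never removes across the window. Without an LD matrix all r² are taken as 0
with a warning — clumping then degenerates to a p-ordering. Chromosomes are
opaque labels; positions are 1-based.

The F-statistic is computed per variant with that variant's N:
R² = 2·EAF·(1−EAF)·β², F = R²(N−2)/(1−R²). The Steiger filter applies the
same variance-explained approximation on both sides and keeps a variant only
when the exposure R² strictly exceeds the outcome R²; exact ties are dropped
as ambiguous. Using 2p(1−p)β² for a binary trait on the log-odds scale is an
approximation (a liability-scale R² would differ by a scale factor); a
user-supplied R² column can replace it by bypassing `steiger_filter` and
filtering externally.

## Estimators

All methods operate on the harmonized instruments. The first-order Wald
ratio SE, se_out/|β_exp|, ignores exposure-side noise — second-order terms
are negligible for genome-wide-significant instruments (F ≥ 10 bounds the
relative contribution).

- **IVW**: closed-form weighted least squares through the origin, weights
  1/se_out². Fixed SE = (Σ w β_x²)^(−1/2); multiplicative random-effects SE
  multiplies by √max(1, Q/(k−1)). The floor at 1 means random effects can
  never be anti-conservative and the two variants coincide when Q ≤ k−1.
  Default is multiplicative random effects; both are always reported.
- **MR-Egger**: instruments are first oriented to β_exp ≥ 0 by jointly
  negating both sides (the fit is invariant to this relabelling). Weighted
  regression with intercept; slope and intercept SEs scaled by
  √max(1, Q_egger/(k−2)); p-values from t with k−2 df (IVW, median and modes
  use the normal — the convention of the reference implementations). A
  degenerate exact fit (Q ≈ 0) is flagged rather than reported as a
  significant result.
- **Weighted median**: normalized inverse-variance weights
  w_j = β_xj²/se_yj² over ascending ratios, breakpoints
  s_j = cum(w′)_j − w′_j/2, linear interpolation at s = ½. SE from a
  parametric bootstrap (both sides' betas resampled from normals with their
  SEs, weights recomputed; default 1000 replicates). `n_boot = 0` skips the
  bootstrap for simulation loops that need only point estimates.
- **Modes**: normal-kernel density over the ratios, uniform (simple) or
  inverse-variance (weighted) weights. Bandwidth
  h = φ·0.9·min(SD, MAD/0.6745)·k^(−1/5); when MAD (or SD) is 0 the fallback
  is φ·range/100, and a zero range means all ratios coincide, so the mode is
  that value. The density is evaluated on a fixed 512-point grid over
  [min−3h, max+3h]; ties resolve to the smallest grid value, making the
  estimator fully deterministic. Bootstrap SE as for the median.

Minimum instrument counts are hard contracts: 2 for IVW, 3 for Egger, median
and modes; below them a typed error is raised, never a silent NA.
`run_all_methods` threads a single seed through the three bootstraps via a
`SeedSequence`, so one pipeline seed fixes every stochastic output.

Estimators follow the scikit-learn protocol (`fit`, trailing-underscore
fitted attributes, `get_params`/`set_params`) and accept either a harmonized
DataFrame or raw arrays.

## Sensitivity analyses

Cochran's Q uses the fixed-effect IVW line (df k−1) or the Egger line
(df k−2) with upper-tail chi-square p-values; adding the free intercept can
only decrease the weighted residual sum, so Q_egger ≤ Q_ivw always. The
Egger intercept test reports estimate, SE, t-based p and a verdict at the
configured α (default 0.05, no multiple-testing correction across stroke
types). Leave-one-out refits IVW k times plus an "All" row and flags whether
every refit keeps the pooled sign. The pipeline's headline IVW switches to
the random-effects SE exactly when the Q test rejects at α.

## Synthetic data generator

The generator emulates a two-sample design on the standardized scale: for
variant j, MAF p_j ~ U(0.05, 0.5); exposure effect magnitude
|γ_j| ~ U(0.05, 0.15); sampling SEs (2p(1−p)N)^(−1/2) with default
N_exposure = 40,585 and N_outcome = 175,226 (the sample sizes of the
motivating stroke-exposure / frailty-outcome design); observed betas drawn
independently in the two samples. A fraction `prop_invalid` of variants
carries a direct effect α_j ~ N(μ_α, σ_α²) on the outcome, *defined on the
exposure-increasing allele* — the frame in which directional pleiotropy is
meaningful and in which the Egger intercept is consistent for E[α] under
InSIDE. A random per-variant sign then flips both marginal effects together,
mimicking arbitrary allele labelling; harmonization and estimator
orientation undo it exactly. P-values are two-sided normal; alleles are
non-palindromic unless a palindromic fraction is requested.

The LD-block variant places each (size m, correlation r) block on its own
chromosome, 50 kb between members; the first member is the causal tag,
member i's true marginal effect is r^i times the tag's, and estimation
errors are drawn jointly with AR(1) correlation r^|i−j| (independently per
sample) — the behaviour of marginal statistics under LD. The emitted LD
matrix holds squared correlations.

What the generator does **not** model: liability-scale binary traits (the
binary exposure is mimicked only through effect scale), allele-frequency
spectra of real consortia, population stratification, sample overlap, or
winner's-curse-free replication. Passing recovery tests therefore validate
the estimators and pipeline logic under their own assumptions, not the
epidemiological conclusions of any particular application.

The default exposure-effect range keeps most instruments genome-wide
significant at the default sample size, but the selection pipeline is always
run — mild winner's curse from threshold selection is part of what the
recovery tests measure (the observed mean IVW bias at the default settings
is within 0.005 of zero at β = 0.1 over 500 replicates; the test suite
checks exactly this).

Replicate r of any Monte-Carlo suite uses seed + r; every stochastic test
states its seed and tolerance.

## Numerical choices

- z₀.₉₇₅ fixed at 1.959964; OR/CI computed from unrounded b and SE.
- Egger raises a collinearity error when the weighted variance of the
  oriented exposure effects is ≤ 10⁻¹⁰ of its scale.
- LD matrices must be symmetric within 10⁻¹², unit-diagonal, entries in
  [0, 1]; violations are rejected, not repaired (beyond clipping float dust).
- Sorting uses stable mergesort so clump output is deterministic for any
  input order.
- Monte-Carlo problem sizes in the test suite (500 recovery replicates at
  k = 50; 1000 calibration replicates at k = 20) were chosen as the smallest
  sizes at which the binomial/Monte-Carlo error bands in the assertions are
  meaningful.

## Known limitations

- The 2p(1−p)β² variance-explained formula is exact only for standardized
  continuous traits; for binary traits both the F and Steiger screens are
  approximations on the log-odds scale.
- First-order Wald SEs understate uncertainty for weak instruments; the
  screening F ≥ 10 floor is what justifies the default.
- No MR-PRESSO outlier removal, multivariable MR, or bidirectional analysis;
  LD is consumed as a user-supplied r² matrix, never computed from genotype
  panels.
- The packaged 18-variant instrument table stores run-together variant-ID
  labels exactly as published (the source typesets the ID and chromosome
  columns without a separator); they are treated as opaque unique keys, and
  no chromosome/position is attached.
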