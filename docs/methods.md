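# Methods

## Model and scope

The package implements two-sample summary-data Mendelian randomization: a
genetic variant j with per-allele effect β_xⱼ (SE_xⱼ) on an exposure and
β_yⱼ (SE_yⱼ) on an outcome, measured in non-overlapping samples, provides the
Wald ratio β_yⱼ/β_xⱼ as an estimate of the causal effect θ of the exposure on
the outcome (log-odds scale when the outcome is binary). Valid instruments
must be relevant (associated with the exposure), independent of confounders,
and exclusive (acting on the outcome only through the exposure); the screen's
sensitivity filters are tests of the third assumption's observable
consequences.

## Instrument selection

Candidates are variants with exposure p < 5×10⁻⁶ forward (5×10⁻⁸ in the
reverse direction). Clumping is greedy: sweep candidates by ascending
p-value (ties broken by chromosome, position, then id, so results are
reproducible and independent of input order) and keep a candidate only if no
already-kept variant on the same chromosome lies within the window
(default 10,000 kb) with r² above the cutoff (default 0.001). Cross-
chromosome pairs are never clumped. Strength uses R² = β²/(β² + SE²·N) —
the allele-frequency factor 2·EAF(1−EAF) appearing in the full variance
expression cancels exactly in this form — and F = [(N−K−1)/K]·R²/(1−R²) with
K = 1 per variant; variants with F < 10 are dropped after clumping, before
harmonization. An aggregate F over the retained set (K = set size, summed R²)
is reported alongside.

## Harmonization

Variants are matched between traits by identifier only; chromosome/position
disagreements are logged, not fatal, since consortia differ in genome build.
Outcome effects are reconciled to the exposure's effect allele: identical
pairs copy through, swapped effect/other alleles negate the outcome beta (and
reflect EAF), complementary alleles are treated as strand flips and then the
same rules apply. Palindromic variants (A/T, C/G) are removed
unconditionally, with no frequency-based rescue — their strand cannot be
resolved from the alleles alone; drops carry machine-readable reasons
(`palindromic`, `missing_in_outcome`, `allele_mismatch`), with the
palindrome check applied first. Outcome-side EAF is not required; only the
exposure EAF enters any downstream formula.

## Estimators

All five estimators consume the Wald ratios with first-order standard errors
SE_yⱼ/|β_xⱼ| (second-order terms are omitted; this matches the weighted-
regression identity used by IVW and common practice). Conventions that were
genuinely open and are fixed here:

* **IVW** `auto` model: fixed-effect unless Cochran's Q has p < 0.05, then
  multiplicative random effects — SE scaled by max(1, √(Q/(K−1))). The floor
  at 1 means homogeneous data are never deflated.
* **Egger**: rows are oriented so every β_x ≥ 0 before the weighted
  regression (weights 1/SE_y²); orientation is required for identifiability
  and leaves the slope and |intercept| invariant. Both coefficient SEs carry
  the analogous max(1, √(Q′/(K−2))) scaling, with Q′ the Rücker form
  (weighted residual sum of squares, K−2 df).
* **Weighted median**: the point where cumulative normalized weight reaches
  1/2, interpolating linearly between order statistics at midpoint cumulative
  weights; reduces to the sample median for equal weights and odd K.
* **Modes**: Gaussian-kernel density of the ratios on a 512-point grid
  spanning the ratios ± 3 bandwidths; bandwidth is a modified Silverman rule
  0.9·min(sd, IQR/1.34)·K^(−1/5) times a configurable factor (default 1).
  Degenerate inputs (all ratios equal) return that value. Bootstrap SEs for
  median/modes are parametric — resample each ratio from
  Normal(ratioⱼ, SEⱼ), recompute, take the SD over replicates (default 1000;
  the bandwidth is re-derived per replicate) — with an explicit seed; there
  is no hidden global randomness anywhere in the package.
* p-values are two-sided normal for all methods (a Student-t reference is
  available for Egger); 95% CIs are beta ± 1.96·SE; odds ratios are exp(beta).
* Method minimums: 2 instruments for IVW, 3 for the rest. A single variant's
  Wald ratio is never reported as IVW.

## The sequential screen

Rules are applied in a fixed order and the first failure decides the
exclusion reason: IVW significance (α = 0.05) → all five odds ratios strictly
on one side of 1 (an OR of exactly 1 fails) → heterogeneity (either the IVW Q
or the Egger Q′ below α = 0.05; configurable to IVW-only) → Egger intercept
(α = 0.05) → leave-one-out stability. Stability is operationalized — the
source procedure gives no numeric rule — as every K−1 subset IVW estimate
keeping both the sign and the nominal significance of the full estimate; the
significance half of the rule can be switched off. Exposures with fewer than
3 instruments after filters are recorded as excluded
(`too_few_instruments`), never raised, so batch runs always complete. No
multiple-testing correction is applied across exposures by default, matching
the raw p < 0.05 usage the pipeline models; a Benjamini-Hochberg option
exists. Per-exposure seeds derive from a stable hash of the exposure id, so
batch output is order-independent.

## Synthetic data generator

The generator works at summary-statistics level. For variant j:
EAFⱼ ~ U(0.05, 0.95); SE_xⱼ = 1/√(2·N_x·EAFⱼ(1−EAFⱼ)) (standardized-trait
form; the binary outcome is treated on the log-odds scale with the same
expression), with defaults N_x = 26,333 and N_y = 85,844 — the sample sizes
of the connectivity and Alzheimer GWAS the screening application uses.
Instruments receive γⱼ ~ N(gamma_mean, gamma_sd²); with the default
gamma_sd = 0.08 the per-SNP F of usable instruments spans roughly 20–200,
matching the instrument-strength range reported in the application. A
fraction `prop_invalid` of instruments gains a direct effect
αⱼ ~ N(alpha_mean, alpha_sd²) (balanced if alpha_mean = 0, directional
otherwise), drawn independently of γ so InSIDE holds by construction. True
outcome effects are θ·γⱼ + αⱼ; observed effects add Normal noise at the
stated SEs. LD is block-diagonal AR(1) (adjacent signed correlation
`ld_rho`); each instrument heads its own block, and LD partners inherit
proportionally attenuated effects plus correlated estimation noise, so
significance screening followed by clumping behaves as on real data.
Palindromic alleles and outcome-side allele-order swaps are injected with
configurable probabilities to exercise harmonization. Each instrument heads
its own block (`n_instruments ≤ n_blocks`), keeping instruments mutually
independent. The reverse direction reuses the same machinery with roles
swapped and `reverse_theta` as the causal parameter.

`simulate_cohort` extends this to a batch: many exposures share one variant
grid, one outcome GWAS, and one LD panel — as in a real screening study where
all traits are measured on the same genotyping panel — with disjoint
instrument blocks per exposure and the outcome aggregating all planted
effects.

What the generator does **not** emulate: realistic human LD maps and allele-
frequency spectra, case-control liability-scale conversions, sample overlap,
population stratification, and selection-induced winner's curse beyond what
the p-value screen itself produces. Tests passing on these simulations
therefore validate the estimators and screening logic under their stated
assumptions, not robustness to those additional real-data complications.

## Study-condition scenarios and problem sizes

Three shipped scenarios fix the Monte-Carlo conditions: `calibration_null`
(θ = 0, 30 valid independent instruments at the application's sample sizes),
`recovery_strong` (θ = 0.2 with a large exposure GWAS, N_x = 200,000, and
γ ~ N(0.1, 0.02²), so per-SNP F is in the hundreds and the no-measurement-
error assumption behind first-order Wald SEs effectively holds — coverage
then reflects estimator calibration rather than weak-instrument attenuation),
and `robustness_directional` (100 instruments, γ ~ N(0.1, 0.05²), 30%
invalid with α ~ N(0.05, 0.01²)). The validation suite uses 2000 replicates
for null calibration, 1000 for recovery, 250 for robustness, and a
206-exposure batch with 10 planted effects (θ = ±0.15, the typical magnitude
of the application's retained log-odds ratios; 10 instrument blocks per
exposure) — sizes chosen to keep each experiment at desk scale on one CPU
while leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* First-order Wald SEs understate uncertainty when θ·SE_x is not small
  against SE_y; with the application's sample-size ratio this costs IVW about
  one coverage point at θ = 0.2 and mildly inflates Q under strong effects.
* The sequential screen applies three ~5%-level sensitivity tests per
  exposure without multiplicity control — by design, mirroring the modeled
  procedure — so a planted-true exposure is falsely excluded in roughly one
  run in ten, and a batch of ten planted effects rarely survives intact.
  This is a property of the procedure, not of its implementation.
* MR-PRESSO, Steiger filtering, multivariable MR and other extensions are
  deliberately out of scope.
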