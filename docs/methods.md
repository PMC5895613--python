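# Methods

## Model and assumptions

The package performs two-sample summary-statistics Mendelian randomization.
The structural assumptions are the usual instrumental-variable triad: each
instrument is (i) associated with the exposure, (ii) independent of
exposure–outcome confounders, and (iii) affects the outcome only through
the exposure (no horizontal pleiotropy). Exposure and outcome effects are
taken from non-overlapping GWAS, so the sampling errors of
β̂<sub>X</sub> and β̂<sub>Y</sub> are independent.

All pooling estimators operate on the per-variant Wald ratios
θ̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub> with first-order weights
w<sub>j</sub> = β̂²<sub>Xj</sub>/σ²<sub>Yj</sub>, i.e. exposure-side
sampling error is ignored inside the weights (the NOME approximation,
standard in two-sample practice and accurate when instruments are strong;
exposure SEs are carried through for reporting and for the weighted-median
bootstrap). Consequences of this choice are discussed under *weak
instruments* below.

## Estimators

**IVW (fixed effects).** β̂ = Σ(β̂<sub>X</sub>β̂<sub>Y</sub>/σ²<sub>Y</sub>) /
Σ(β̂²<sub>X</sub>/σ²<sub>Y</sub>), SE = (Σβ̂²<sub>X</sub>/σ²<sub>Y</sub>)^(−1/2);
algebraically the weighted least-squares slope of β̂<sub>Y</sub> on
β̂<sub>X</sub> through the origin. Fixed-effects weighting is deliberate:
heterogeneity is surfaced by Cochran's Q rather than absorbed into the SE.
A single instrument degrades to the Wald ratio. P-values are two-sided
normal.

**MR-Egger.** Weighted least squares of β̂<sub>Y</sub> on β̂<sub>X</sub>
*with* intercept, after orienting every variant to β̂<sub>X</sub> ≥ 0
(the slope is invariant to joint sign flips; the intercept is only
meaningful in this orientation). The intercept estimates the average
directional pleiotropy; under the InSIDE assumption (pleiotropy
independent of instrument strength) the slope remains consistent for the
causal effect. The residual scale entering the coefficient SEs is
√max(RSS<sub>w</sub>/(J−2), 1): under-dispersion can never shrink the SEs
below their fixed-effect value, over-dispersion inflates them
(multiplicative random-effects correction). Coefficient p-values use
t with J−2 df; intercept p < 0.10 is reported as evidence of pleiotropy.

**Weighted median.** Sort θ̂ ascending and set p<sub>j</sub> =
(Σ<sub>k≤j</sub>w<sub>k</sub> − w<sub>j</sub>/2)/Σw; the estimate linearly
interpolates θ̂ across the p<sub>j</sub> bracketing 0.5. The SE comes from
a parametric bootstrap (β̂<sub>X</sub>, β̂<sub>Y</sub> resampled from
normal(β̂, SE), default 1,000 replicates, seed mandatory and recorded).
The estimator is consistent when at least half the total weight comes from
valid instruments — an asymptotic statement in instrument precision, not
in bootstrap or Monte-Carlo replicates. At finite GWAS precision with a
fraction q of the weight contaminated in one direction, the estimate sits
at the 0.5/(1−q) weighted quantile of the valid ratio distribution, a bias
of roughly z<sub>0.5/(1−q)</sub>·sd(θ̂<sub>valid</sub>) that shrinks only
as per-study SEs shrink. At the default simulation scale (q ≈ 0.3,
sd(θ̂) ≈ 0.07) this is ≈ +0.03 — an order of magnitude smaller than the
corresponding IVW bias, which is the estimator's actual selling point, but
decidedly nonzero. The test suite asserts both statements: the idealized
recovery check (which fails at this precision, and is kept as the record
of that gap) and the bias-dominance comparison against IVW (which passes).

## Harmonization rules

Outcome records are oriented to the exposure's effect allele. Effect/other
swaps and strand-complement-plus-swap negate β̂<sub>Y</sub> and mirror the
effect-allele frequency; pure strand complements change nothing but are
recorded. Palindromic variants (allele pair {A,T} or {C,G}) cannot be
strand-resolved from alleles; they are aligned by frequency concordance —
exposure and outcome effect-allele frequencies on opposite sides of 0.5
imply opposite orientations — and only when the minor-allele frequency is
≤ 0.42 on *both* sides. Nearer 0.5 the frequency carries no strand
information and the variant is excluded, as is any palindrome with a
missing frequency. The 0.42 bound is interpreted as a minor-allele
frequency bound (a literal effect-allele-frequency reading would
asymmetrically discard common, perfectly orientable variants). Both-sides
enforcement is the stricter of the defensible readings and is flagged in
the harmonization summary. Exclusion is monotone in the bound, and
harmonization is idempotent — both property-tested.

## Instrument selection

P-value filter (default 5×10⁻⁸) then greedy positional clumping: per
chromosome, retain the smallest-p variant (ties broken by lexicographic
variant id, making the result independent of row order) and discard
everything within the window (default 1 Mb, 1-based coordinates, |Δpos| ≤
window), repeating until exhausted. True linkage-disequilibrium clumping
needs a genotype reference panel; the distance window preserves the
one-signal-per-locus semantics without external data, and the default
mirrors the windows common in LD-clumping tools. The selection parameters
and counts are written to a JSON sidecar next to every instrument table.

## Sensitivity cascade

Cochran's Q = Σw<sub>j</sub>(θ̂<sub>j</sub> − β̂<sub>IVW</sub>)², referred
to χ²<sub>J−1</sub>; its per-variant decomposition is exported. Q's p <
0.05 triggers a rerun of all estimators after removing variants whose own
outcome association has p < 0.05 — a literal reading of
"individually associated with the outcome"; exclusion by Q contribution is
a noted alternative the reports do not implement. Note that under a real
causal effect, strong instruments are outcome-associated *through* the
exposure, so this rule removes signal as well as outliers and biases the
rerun toward the null; the rerun is reported alongside, never instead of,
the primary round. An empty remainder is reported as non-estimable, not
raised. The F-statistic uses the joint-instrument form
[R²(n−1−K)]/[(1−R²)K] with the R² explained by all K instruments together;
F ≤ 10 sets the weak-instrument flag.

## Power

mRnd-style normal approximation. Continuous outcomes: NCP = n·R²·β² with
standardized β; power = P(Z > z<sub>1−α/2</sub> − √NCP) +
P(Z < −z<sub>1−α/2</sub> − √NCP). Binary outcomes deflate by the case
fraction φ: NCP = n·R²·φ(1−φ)·log²OR. Minimum detectable effects invert
the monotone power curve by bracketed root-finding (relative tolerance
1e−10); OR and 1/OR are equivalent by construction and the value above 1
is returned. No exact logistic-likelihood power is attempted.

## Synthetic data generator

Emulates a two-sample study of a quantitative risk factor on a
quantitative ECG trait on standardized scales. Defaults are the study
conditions: 55 instruments, exposure GWAS n = 201,529 (blood-pressure
scale), outcome GWAS n = 73,518 (QRS-trait scale), allele frequencies
uniform on (0.05, 0.45). Per-study sampling SEs follow the GWAS
approximation 1/√(2p(1−p)n). True exposure effects are γ<sub>j</sub> =
z<sub>j</sub>·σ<sub>Xj</sub> with |z<sub>j</sub>| uniform on (8, 35) —
every instrument clears 5×10⁻⁸, spanning just-significant to strong loci
as in large blood-pressure GWAS — and all positive, matching the
instrument-list convention of orienting the effect allele to the
trait-increasing allele (this is what makes "directional" pleiotropy
directional on the ratio scale). Outcome expectation is
causal_effect·γ<sub>j</sub> + α<sub>j</sub> with pleiotropy α drawn per
mode (none / balanced / directional) on a configurable fraction of
variants; α is independent of γ, so InSIDE holds by construction.
Observed betas add independent normal noise at the nominal SEs, making the
IVW z-statistic and Cochran's Q exactly calibrated under the null — the
basis of the 2,000-rep calibration checks.

Allele corruption is applied post hoc and logged per variant:
effect/other swaps (beta negated, frequency mirrored — information
preserving), strand complements (values untouched), and palindrome
planting, which rewrites the allele pair on both tables (a variant cannot
be palindromic on one side only) at a configurable frequency; half the
planted palindromes are additionally strand-swapped, recoverable only via
the frequency rule. Round-tripping corrupted tables through the
harmonizer restores the original betas exactly and reproduces the planted
action per variant.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent; clumping is exercised with explicitly constructed
positional clusters in the tests), between-cohort frequency drift beyond
an optional jitter, sample overlap between the two GWAS, winner's-curse
selection of instruments, allele miscoding that destroys information, and
non-normal effect distributions. Passing simulation checks therefore
demonstrates correctness of the estimators and plumbing under the stated
model, not robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

- P-values are floored at the smallest positive float so they stay in
  (0, 1] even for |z| beyond ~38.
- Egger refuses < 3 variants; a constant-β̂<sub>X</sub> design is singular
  and reported as an estimator error, which the pipeline downgrades to
  "estimator skipped" rather than failing the pair.
- Weighted-median bootstrap draws hitting β̂<sub>X</sub> = 0 exactly are
  nudged to the smallest positive float to keep ratios defined.
- Clumping ties on p are broken by variant id; duplicated variant ids are
  rejected at selection time.
- Table round trips write floats with `repr`, so read(write(x)) is
  bit-identical.
- Non-estimable pairs (empty harmonized intersection, all variants
  excluded) are recorded and a study grid always completes.

## Multiplicity

The grid threshold is budget/(n<sub>exposures</sub>·n<sub>outcomes</sub>)
with the budget defaulting to 0.005 (0.005/52 = 9.62×10⁻⁵ for the 13 × 4
risk-factor × QRS-trait grid), a deliberately strict choice — 0.05 would
be the conventional budget for a 5% family-wise rate; the budget is
configurable and the default is surfaced in every report.

## Known limitations

- Distance-based clumping is a stand-in for LD clumping; correlation
  between variants further apart than the window (or across chromosomes)
  is not considered.
- The F-statistic takes R² as given; it does not estimate R² from the
  summary statistics.
- The reverse-direction analysis (ECG traits as exposure, mortality or
  longevity as outcome) is supported by the same `run_pair` machinery
  given a precomputed variant–outcome association table; generating that
  table from individual-level cohort data (per-variant Cox regressions) is
  out of scope.
- Monte-Carlo problem sizes in the tests and drivers (2,000 null
  replicates, 500 recovery replicates, 55 instruments) were chosen to give
  Monte-Carlo SEs well below the effect sizes being checked while keeping
  the suite quick to run.
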