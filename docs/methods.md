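# Methods

## Model and estimands

The package analyses two-sample summary-level MR data.  For instrument j,
the SNP-exposure association β_Xj (SE σ_Xj) and SNP-outcome association
β_Yj (SE σ_Yj) are estimated in non-overlapping samples.  Under the
instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction), each Wald ratio β_Yj/β_Xj estimates
the same causal effect θ; the estimators differ in how they pool the
ratios and in which violations they tolerate:

* **IVW** is the precision-weighted mean of the Wald ratios (equivalently
  a weighted regression of β_Y on β_X through the origin, weights
  1/σ_Yj²).  It is efficient when all instruments are valid and biased by
  any directional pleiotropy.
* **MR-Egger** adds an intercept: the slope is consistent under the
  InSIDE assumption even with directional pleiotropy, and the intercept
  estimates the average direct effect.  Rows are oriented to β_Xj ≥ 0
  before fitting (the fit is otherwise not invariant to the arbitrary
  choice of effect allele).
* **Weighted median** is consistent when instruments carrying ≥ 50% of
  the weight are valid; the estimate interpolates the ordered ratios at
  standardized cumulative weight 0.5.
* **Mode-based estimators** take the kernel-density mode of the ratio
  distribution (simple: equal weights; weighted: β_Xj²/σ_Yj²) and are
  consistent when the largest homogeneous cluster of instruments is
  valid.
* **Multivariable IVW** regresses β_Y jointly on several exposures'
  betas (no intercept), estimating each exposure's direct effect; it
  requires instruments specific to each exposure for identification.

Binary-outcome effects are log-odds throughout; odds ratios appear only
at reporting, as exp(β) with exp(β ± 1.96·SE) intervals.

## Inference conventions

* IVW default is **multiplicative random effects with a floor**: SE =
  SE_fixed · max(1, σ̂), σ̂² = Q/(J−1), Q the Cochran heterogeneity
  statistic.  The floor means the reported SE never undercuts the
  fixed-effect SE.  Under a homogeneous null this test is deliberately
  conservative (its rejections are a strict subset of the fixed-effect
  z-test's; analytically ≈ 3.9% at J = 13 for a nominal 5%), which is why
  the type-I-error check in the acceptance suite exercises
  `re_mode="fixed"` — the correctly specified, exactly calibrated variant
  — and separately asserts the subset property of the default.
* MR-Egger and multivariable IVW use the same max(1, σ̂) scale floor with
  t(J−2) / t(J−k) reference distributions; IVW, Wald, median and mode
  p-values are two-sided normal.
* Median/mode SEs come from a **parametric bootstrap** (β_X*, β_Y* drawn
  from their reported sampling distributions, default 1,000 replicates,
  explicit seed, bit-reproducible).  Mode bandwidth is the modified
  Silverman rule 0.9·φ·min(sd, 1.4826·MAD)·J^(−1/5) with φ = 1 by
  default; all-equal ratios give a degenerate bandwidth and the common
  ratio is returned.
* **MR-PRESSO** follows the published algorithm shape: leave-one-out IVW
  expected values, weighted residual sum of squares, parametric
  simulation of the no-pleiotropy model, empirical p-values via
  (1 + exceedances)/(n_sim + 1), Bonferroni-adjusted per-SNP outlier
  tests (default significance 0.05), and a distortion test comparing the
  raw-vs-corrected shift against random same-size removals.  Default
  n_sim = 1,000.
* **Mediation**: proportion = β1·β2/α with a first-order delta-method SE
  treating α, β1, β2 as independent.  That independence is approximate
  (α and β2 share the outcome sample); the point estimate is unaffected,
  and the interval is labelled accordingly.  The proportion
  is reported signed; it is flagged undefined when α is numerically zero.
* Per-taxon stochastic stages derive their seeds as
  blake2b(seed | taxon | stage) mod 2³¹, so panel results do not depend
  on processing order.

## Selection and harmonization rules

Instrument selection applies, in order: strict p < 1×10⁻⁵; greedy
clumping (lowest-p index SNP first, ties broken lexicographically by SNP
id; discard r² ≥ 0.001 within 10,000 kb; pairs absent from the sparse LD
table count as r² = 0; the window applies only when positions are
present); strict F > 10; exclusion list.  Counts are logged per step.
PhenoScanner-style confounder lookup is deliberately not performed — it
is a non-reproducible web service — and is replaced by the exclusion
file.

Harmonization keys the outcome (and mediator) to the exposure's effect
allele: identical alleles kept, swapped alleles negated, strand
complements resolved before declaring incompatibility, indels dropped.
Palindromic SNPs are dropped when either allele frequency is missing or
inside (0.42, 0.58); outside the band the strand is inferred from
whether the frequencies lie on the same side of 0.5.  The band and rule
are configurable; dropping ambiguous palindromes is the conservative
default.

The panel screen uses raw IVW p < 0.05 with no multiplicity correction,
matching the study design this package mirrors; a Benjamini–Hochberg
switch (`use_fdr`) is provided and recommended for new analyses.
Replication re-estimates significant taxa against a second outcome GWAS
with the same instruments (re-estimation, not re-selection).

## Synthetic-data generator

`simulate_pair` draws γ_j ~ N(γ̄, σ_γ²), observes β_Xj ~ N(γ_j, σ_X²)
and β_Yj ~ N(θγ_j + α_j, σ_Y²), where α_j is zero for valid instruments
and N(μ_α, σ_α²) for an invalid fraction, plus optional additive shifts
for outlier injection.  Defaults encode the study conditions the package
is organised around: J = 13 instruments with per-SNP F ≈ 20 (matching
the ≈ 21 reported for microbiome-taxa instruments from an 18k-sample 16S
GWAS), outcome SEs of 0.15 (log-odds scale of a ~2k-case/300k-control
GWAS), and θ = ln 0.61 ≈ −0.494, the headline protective effect.
Frequencies are uniform on (0.05, 0.5); alleles are non-palindromic
unless requested; p-values are two-sided normal.

`simulate_mediation_triple` chains exposure → mediator → outcome with
β1, β2 and a direct effect θ_d (truth: total = θ_d + β1β2, proportion =
β1β2/total).  The mediator carries **its own instrument block** (effects
δ_j, transmitted to the outcome as β2δ_j) in addition to the β1γ_j it
inherits through the exposure instruments.  This is a deliberate design
point: without mediator-specific instruments the multivariable design
matrix is collinear up to measurement noise and β2 is unidentified —
the same reason real two-step analyses build the MVMR on the union of
both traits' instruments.

The directional-pleiotropy robustness scenario (J = 50, 30% invalid,
γ ~ N(0.15, 0.06), σ_X = 0.005, σ_Y = 0.02, α ~ N(0.20, 0.02)) was fixed
by an a-priori power design before any test was written.  Two findings
from that design are worth recording because they bound what the test
suite can show: (i) the max(1, σ̂)-scaled Egger intercept test absorbs
the valid/invalid mixture variance into its residual scale, capping its
power near 30% at J = 50 regardless of pleiotropy magnitude (power
reaches ~57% at J = 100 and ~84% at J = 200); (ii) removing a flagged
8-SE outlier from J = 20 instruments shifts the IVW estimate by only
about 1.7 SEs of the corrected estimate's own noise, so outlier
correction improves the point estimate in ~85% of replicates, not
essentially always.  Both are properties of the estimators at those
instrument counts, not implementation artifacts, and the corresponding
acceptance checks are left asserting the stronger bounds they were
specified with.

What the generator does **not** emulate: sample overlap between exposure
and outcome GWAS, LD between generated instruments (LD enters only
through the separate block-structured r² fixture used to exercise
clumping), allele-frequency-dependent effect sizes, winner's-curse
selection of instruments, and population stratification.  Passing tests
therefore demonstrate correctness of the estimators and pipeline under
the summary-level MR model, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

Input rows violating per-SNP invariants are dropped and counted, except
p = 0, which is clamped to the smallest positive float (downstream −log
transforms).  Delimiters are sniffed among tab/comma/semicolon.  Result
tables carry 12 significant digits so round-trips preserve estimates to
better than 1e-10.  Estimators raise typed errors below their instrument
minima (Wald 1, IVW 2, Egger/median/modes 3, MR-PRESSO 4, MVMR k+2) and
on rank-deficient MVMR designs, naming the offending columns.  Exact
boundary cases in selection are strict: p < threshold, r² ≥ threshold
discarded, F > threshold.  Identical ratios give Q = 0, an IVW SE at the
fixed-effect floor, and degenerate-bandwidth modes returning the common
ratio.  Output files are byte-reproducible for a fixed configuration (no
timestamps; fixed column orders and float formats).

## Problem sizes used in the test and acceptance runs

Simulation-based checks use 200–2,000 replicates per property (500 for
estimator recovery/coverage, 2,000 for type-I error, 300 for the
pleiotropy robustness ordering, 200 + 100 for MR-PRESSO calibration and
outlier handling, 200 for mediation recovery), with J between 13 and
200 instruments — sizes chosen so each Monte-Carlo standard error is
small relative to the tolerance being asserted while the whole suite
runs in a few minutes on one CPU.

## Known limitations

* No proxy-SNP lookup for instruments missing in the outcome; no
  GWAS-VCF parsing, liftover, or rsID/position resolution; no reverse-
  direction MR.
* LD clumping consumes a precomputed pairwise-r² table; the package does
  not compute LD from genotype reference panels.
* The delta-method mediation interval ignores the α/β2 outcome-sample
  correlation (see above).
* The mode estimators evaluate the kernel density on the ratio grid
  itself rather than a fine mesh; with very few instruments the mode is
  correspondingly coarse.
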