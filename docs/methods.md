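# Methods

## Mortality model

The package models mortality with the Gompertz law: hazard
h(t) = exp(μ₀ + μ₁ t), survival S(t) = exp(−(e^{μ₀+μ₁t} − e^{μ₀})/μ₁).
Although curves of this family are often labelled "Gompertz–Makeham", no
age-independent Makeham term is included: the reference analysis uses the
pure Gompertz form, and adding a constant hazard would change every derived
quantity.  Time is months everywhere; the reference regime is μ₀ = −11.4
(log baseline hazard per month) and μ₁ = 0.7 /month, under which about 56%
of the population is alive at 15 months and 10% at ~17.0 months.

Two normalizations of S are exposed.  `proper` (default) is the exact
survival function above, with S(0) = 1 identically.  `paper_literal` keeps
the bare exponential shape exp(−e^{μ₀+μ₁t}/μ₁) that printed versions of the
formula reduce to when their normalization prefactor is taken at face value;
the printed prefactor N₀ = 100%·exp(−e^{μ₀}/μ₁) does not actually make
S(0) = 100%, so the package treats N₀ as the 100% unit itself.  The two
normalizations differ by exactly e^{μ₀}/μ₁ in log-survival — about 1.6×10⁻⁵
in the reference regime — so every cohort-level quantity agrees to far
better than measurement precision; `paper_literal` exists only for exact
comparability with printed curves.  Sampling always inverts the proper form,
which is a true probability distribution.

## Empirical survival and the inclusion policy

The empirical curve is the classical step estimator: each death drops the
fraction surviving by 1/n (ties drop k/n).  `alive` records are
right-censored — they contribute to n but never drop the curve.  This is
deliberately simpler than Kaplan–Meier reweighting and coincides with it
whenever no animal is censored before the last death (the reference study
had no surviving animals at study end); with heavy interior censoring the
tail of the step curve is biased low, a documented limitation.  With no
censoring the curve is identical to the Kaplan–Meier estimate, which the
test suite checks against lifelines.

The inclusion policy is exactly two rules, applied before any statistics:
sacrificed animals are removed from everything; embolic (injection-table)
deaths are relabelled natural at the injection-day age.  The policy is
idempotent and non-mutating.

## Least-squares fitting

The Gompertz parameters are fitted by minimizing the squared deviation
between the model survival fraction and the empirical fraction immediately
after each distinct death age (the step's lower value, i.e. the recorded
loss of animals).  The evaluation-point rule is a genuine free choice — a
monthly grid or the pre-drop values would be equally defensible — but at
zero noise all choices recover the generating parameters exactly, and at
n = 10⁴ the slope is recovered to ±0.01, so the choice is immaterial at the
scales that matter.  The optimizer is a deterministic multistart: a fixed
5×5 grid over μ₀ ∈ [−20, −5] and μ₁ ∈ [0.1, 2] (geometric in μ₁), each
start refined by bounded trust-region least squares with tolerances 10⁻¹⁴;
the lowest-cost optimum wins.  No maximum-likelihood or interval-censored
variant is provided.

## MLS estimators

* **Direct**: mean of the top k = max(1, ⌊fraction·n⌋) death ages, fraction
  0.1 by default.  This k-rule reproduces both reference cases (n=20 → k=2,
  n=51 → k=5).  A cohort below 10 animals triggers a warning rather than an
  error.  Its half-width is the Student-t interval of the k tail ages.
* **Model tail**: conditional mean of the fitted curve over [t₁₀, ∞) with
  the survival function as weight, evaluated by adaptive quadrature
  (relative tolerance 10⁻⁸, upper truncation where S < 10⁻¹²) and
  cross-checked in the tests against a 10⁻⁴-month trapezoid sum.  The
  survival-function weight (not the death density) is the reading used
  throughout; the density-weighted alternative gives a value ~0.08 month
  higher in the reference regime.
* **Combined**: (Δ₂·v₁ + Δ₁·v₂)/(Δ₁+Δ₂), a convex combination.  No
  published rule exists for the combined half-width, so it is propagated as
  min(Δ₁, Δ₂) and explicitly flagged `heuristic`.

### Recorded versus computed uncertainties

The published half-widths for the reference estimates (±2.6, ±0.6, ±0.8,
±0.5 months; ±5%; ±0.3-fold) are not reproducible from the standard
Student-t formula: that computation gives ±10.8 months for the two-animal
control tail and ±1.56 for the five-animal experimental tail.  The package
therefore stores the published values verbatim as recorded constants
(`maxlifespan.reference`) tagged `printed`, computes its own Student
intervals tagged `student`, and never substitutes one for the other.

### The 17.2-month model-tail value

Re-evaluating the tail integral at the published rounded parameters
(−11.4, 0.7) gives 17.35 months, 0.15 above the published 17.2.  The
integral is sensitive at this level to rounding μ₁ to one decimal (μ₁ ≈ 0.71
reproduces 17.2), so the published value was evidently computed from the
authors' unrounded fit, which is not recoverable without the raw death ages.
The reproduction report shows this row as informational rather than
pass/fail; downstream worked arithmetic (the weighted combination, extension
and fold) uses the published 17.2 as input, exactly as the published
calculation does.

## Chimerism

Per-image GFP⁺/total counts are reduced to an observed fraction either as
the unweighted mean of per-image fractions (default, matching
instrument-software practice of averaging per-image percentages) or by
pooling counts; the two coincide when images have equal cell counts.  The
corrected chimerism is observed/donor-positive-fraction, optionally after
subtracting a measured autofluorescence background (default 0).  Values
above the donor ceiling by more than 10⁻⁹ are rejected as inconsistent
input.  On binomial synthetic counts with per-cell probability c·d the
pipeline recovers c within ±0.02 at 20 images × 1000 cells.

## The synthetic-study generator

`StudyDesign` defaults encode the reference study: 20 control and 56
experimental animals; control mortality (−11.4, 0.7); intervention at 15
months; 6 injections, the first at T0 and the rest at uniform 10–20-day
gaps (30.44 days/month); embolic risk 0.06 per injection for every animal
alive on the injection day (9 deaths per ~150 injections); 5 sacrifices at
21 months — six months after the first injection, the age at which
chimerism was assayed; true chimerism 0.28 read through a 0.25
donor-positive fraction over 15 images of 1000 nucleated cells (image
counts are not published; 10–20 images per preparation with ~10³ nucleated
cells in frame is typical for automated slide scans).

The treatment effect is modelled as a parameter change after T0: treated
survivors follow (−15.3, 0.7) conditional on having reached T0
(piecewise-hazard construction by conditional inverse-CDF).  The μ₀ shift of
−3.9 was chosen once so the model tail mean moves by about the observed
+5.6 months; it is a minimal forward model for testing the pipeline, not an
inference about mechanism.  An optional age-weighted embolism mode (off by
default) doubles the risk for the frailest animals and tapers it to zero
for the most robust, for sensitivity analyses of the possibility that the
injections killed preferentially senile animals.

All randomness flows from one `numpy` Generator seeded by the design's
single seed; a fixed seed gives byte-identical output CSVs.

What the generator does *not* emulate: litter or cage effects, seasonal
husbandry variation, measurement error in death ages (real records have
~0.1-month resolution), engraftment kinetics, or any correlation between
embolic risk and injection number.  Tests passing on this generator
therefore validate the estimators under the stated statistical model, not
robustness to those real-data features.

## Numerical choices and problem sizes

Quadrature: `scipy.integrate.quad`, relative tolerance 10⁻⁸ with explicit
residual checks.  Quantiles: closed form, verified against bisection to
10⁻⁹.  Tie-break in sacrifice selection: uniform random among animals alive
at the scheduled age.  Degenerate inputs (empty cohorts, no deaths,
single-observation CIs, zero donor fraction, both-zero weights) raise
`ValueError` with specific messages rather than returning sentinels.

Validation experiments run at n = 10⁴ lifespans for parameter recovery
(20 seeds for the median-error summary), n = 10⁵ for distributional checks
(Kolmogorov–Smirnov < 0.01, direct-vs-model-tail agreement within 0.3
month), and n = 10⁴ for the Glivenko–Cantelli gap (< 0.03).  These sizes
put Monte-Carlo noise well below every asserted tolerance while keeping the
full suite around ten seconds.
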