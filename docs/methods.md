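# Methods

## Model

Plasma input functions are bi-exponential,
`AC_p(t) = A·e^{a·t} + B·e^{b·t}` with `A, B ≥ 0` (%IA/L) and `a, b < 0`
(h⁻¹, stored signed-negative so the model reads exactly as written). The
exact cumulated concentration is
`AUC_p(t) = A(e^{a·t}−1)/a + B(e^{b·t}−1)/b`.

Tissue curves follow the linearized irreversible two-tissue model,
`AC_t(t) = Ki·AUC_p(t) + VT·AC_p(t)`. Curves generated this way are in
plasma–tissue equilibrium from t = 0 by construction, so the estimator is
applied without an equilibration cutoff; on real data the standard ≥ 24 h
onset guidance applies externally.

The estimator mimics clinical sparse sampling: the plasma curve is known at
0 h plus the three imaging times only, AUC_p comes from the composite
trapezoidal rule over those four points, and (Ki, VT) are the unweighted OLS
slope/intercept of `AC_t/AC_p` on `AUC_p/AC_p` over the three imaging
points. The t = 0 sample feeds only the AUC, never the regression. No sign
constraints are imposed on the estimates — clamping would distort the bias
and variability being studied. For a convex, decreasing plasma curve the
trapezoid overestimates AUC_p at every imaging time, stretching the Patlak
x-coordinates while the y-coordinates are unchanged; the fitted slope is
therefore biased low in every noise-free condition. Because the noise is
mean-zero and the OLS estimator is linear in the tissue values, the
Monte-Carlo mean estimate equals the noise-free estimate in expectation, so
this deterministic trapezoid bias *is* the bias of the method.

## Noise

Tissue noise is derived from counting statistics: detected counts are
Poisson, relative error ∝ 1/√N, and N is proportional to the
*non-decay-corrected* activity concentration `ncAC_t(t) = AC_t(t)·2^{−t/T½}`
with T½ = 78.41 h for ⁸⁹Zr (the physical constant; configurable). Anchoring
the fractional SD at injection gives

    %SD(t) = noise0 · √( ncAC_t(0) / ncAC_t(t) ),   ncAC_t(0) = VT·(A+B).

Noise is applied multiplicatively and independently per imaging point:
`AC_t,noise = AC_t·(1 + %SD(t)·z)`, `z ~ N(0,1)`, one deviate per point per
repetition, no temporal correlation and no second-level randomization of the
SD itself. Negative noisy values are retained. Plasma samples are noise-free
(well-counter errors of 0.2–0.4% are negligible against 5–15% tissue noise).

Two deliberate readings where the source material is ambiguous:

- The SD propagation is implemented with the count ratio *inside* the square
  root as written above, i.e. SD grows as counts die away. The alternative
  algebraic arrangement (dividing by the ratio) would make noise shrink over
  time, contradicting both Poisson statistics and the qualitative behaviour
  the model is meant to capture.
- "SD at t = 0" is a *fractional* SD of the tissue value (5/10/15% noise
  levels), not an absolute concentration.

One consequence worth knowing: %SD(t) is monotone increasing only where the
non-decay-corrected TAC decreases. For high-uptake tissue (Ki = 20·10⁻³ h⁻¹)
accumulation can transiently outpace physical decay between 24 h and 48 h,
producing a slight early dip. The tests assert the conditional property
(SD rises wherever counts fall) and unconditional monotonicity at low
uptake.

Conditions with VT = 0 and noise > 0 are rejected: the noise anchor
ncAC_t(0) = VT·(A+B) vanishes and the SD ratio is undefined. The study grid
(VT ≥ 0.1) never hits this.

## Study grid and summaries

Default axes: 3 input functions × all C(5,3) = 10 three-point schedules from
{24, 48, 96, 144, 192} h × rKi {1, 5, 20}·10⁻³ h⁻¹ × rVT {0.1, 0.2, 0.5} ×
noise {5, 10, 15}% — 810 conditions, 1000 repetitions each by default.
Accuracy is `bias% = 100·(mean − ref)/ref`; precision is
`variability% = 100·SD/ref` with SD the spread (ddof = 1) of the estimate
distribution across repetitions — the uncertainty of a *single* simulated
study, which is the quantity schedules should be judged by. Normalizing by
the reference (rather than the mean) is a declared convention; the package's
comparative conclusions (signs, ratios, orderings) are invariant to it.
Repetitions yielding non-finite estimates would be excluded and counted
(`n_failed`); on the default grid none occur.

Seeding: a master seed spawns one independent substream per condition by
SHA-256-hashing the condition descriptor (fixture, schedule, rKi, rVT,
noise) together with the master seed. Adding grid cells therefore never
perturbs existing cells, and identical seeds give bit-identical tables.
`run_condition` evaluates all repetitions with a closed-form batched OLS;
`run_repetition` composes the public single-study operations and is tested
to agree with the batched path deviate-for-deviate.

## Bundled input functions

The three bundled profiles emulate published ⁸⁹Zr-mAb serum clearances with
three distinct clearance rates. Their fitted coefficients are not publicly
tabulated, so the bundled parameters are synthetic: chosen once under
realistic constraints (t = 0 concentration ≈ injected activity in ~2.5 L
plasma, i.e. 40–44 %IA/L; distribution half-life ≈ 10–12 h; terminal
half-life ≈ 58 / 92 / 154 h) and calibrated so the plasma-exposure ordering
(huJ591-like < trastuzumab-like < pertuzumab-like at 192 h) and the
magnitude of the deterministic sparse-sampling Ki bias match the published
behaviour of the real curves (worst with-24 h bias ≈ −16% / −10% / −5%
respectively). Provenance notes live in `src/patlaksim/data/fixtures.json`.
Because these are emulations, per-schedule *magnitudes* of bias and
variability are indicative; the package's robust outputs are the signs,
ratios and orderings, which are insensitive to the exact coefficients.
The one magnitude treated as meaningful is the with-24 h worst-case Ki bias
bound (≤ 16% at 5% noise), which the calibration targets. The smallest
|Ki bias| on this grid (~1.3%) is somewhat larger than the smallest
published value (−0.5%), a residual of emulated coefficients.

The random generator (`synthetic` module) draws half-lives, t = 0
concentration and fast-phase fraction uniformly from ranges bracketing the
five published curves (fast t½ 4–24 h, slow t½ 40–240 h, C0 20–60 %IA/L,
fast fraction 0.2–0.6). It emulates shape and scale only — no
target-mediated (nonlinear) clearance, no inter-patient covariance between
clearance and uptake — so passing tests demonstrate estimator properties
for this model class, not clinical performance.

## Numerical choices

- Bi-exponential fitting: trust-region nonlinear least squares on
  untransformed concentrations, initialized by log-linear curve peeling,
  bounds `amp ≥ 0`, `rate ≤ −1e−12`; phases re-ordered post-fit so
  `rate_fast < rate_slow`. Needs ≥ 4 positive samples.
- OLS: `scipy.stats.linregress` for single fits (cross-checked against
  `numpy.polyfit` in tests); closed-form centered formula for the batched
  Monte-Carlo path. ≥ 2 distinct x required; degenerate input is an error,
  recorded as a failed repetition by the engine.
- Trapezoid: `numpy.trapezoid` over the sampled points; the upper limit must
  be an exact sample time (no interpolation).
- Statistical test bounds: fixed-seed Monte-Carlo checks use 4 SE bands
  (family-wise calibrated where hundreds of conditions are checked at once);
  the grid-wide sign check relies on the exact noise-free estimate plus a
  2 SE one-sided criterion.

## Problem sizes in the checks

The full-grid sign check runs all 810 conditions at 200 repetitions; the
with-24 h bias bound uses 20 000 repetitions so the Monte-Carlo mean
resolves the deterministic bias to ~0.2% even in low-Ki cells with ~30%
single-study spread; the noise-scaling ratio uses 1000–5000 repetitions.
These sizes are the package's own precision choices for each statistic.

## Limitations

- Image-domain effects (reconstruction, resolution, partial volume) and
  scan-duration optimization are out of scope; noise enters only as the
  count-statistics model above.
- The forward model enforces equilibrium from t = 0; real tissue needs ~24 h
  to equilibrate, which is exactly why the earliest candidate time is 24 h.
- Plasma noise, target-mediated clearance and receptor-occupancy dynamics
  are not modelled.
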