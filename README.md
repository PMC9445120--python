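# patlaksim

Accuracy and precision of sparse-sampled Patlak linearization for
⁸⁹Zr-immuno-PET, by simulation.

## The problem

Zirconium-89-labelled monoclonal antibodies (⁸⁹Zr-mAbs) are imaged with PET
over about a week. Because ⁸⁹Zr residualizes in tissue after the antibody is
catabolized or irreversibly bound, tracer kinetics follow an irreversible
two-tissue compartment model, and Patlak graphical analysis applies: after
plasma–tissue equilibrium,

    AC_t(t) / AC_p(t) = Ki · ( ∫₀ᵗ AC_p dx / AC_p(t) ) + VT

is a straight line whose slope **Ki** (h⁻¹) is the net irreversible uptake
rate and whose intercept **VT** (unitless) is the reversible distribution
volume. In patients only a handful of blood samples and PET scans can be
obtained — typically a blood sample at injection plus three imaging days —
so the plasma integral AUC_p must be computed by the trapezoidal rule over
four samples, and the regression uses only three points. `patlaksim`
quantifies what that sparse sampling does to the accuracy (bias) and
precision (variability) of Ki and VT, as a function of the imaging schedule,
the plasma clearance of the antibody, the noise level, and the reference
kinetics.

The pieces:

- **Input functions** — bi-exponential plasma models
  `AC_p(t) = A·e^{a·t} + B·e^{b·t}` (%IA/L, rates negative), with exact
  closed-form AUC, nonlinear refitting from sampled curves, and three
  bundled profiles emulating literature ⁸⁹Zr-mAb clearances
  (`huJ591-like` fastest, `trastuzumab-like`, `pertuzumab-like` slowest).
- **Forward model** — noise-free tissue curves
  `AC_t = Ki·AUC_p + VT·AC_p`, plus counting-statistics noise whose
  fractional SD grows as counts decay:
  `%SD(t) = noise0 · √(ncAC_t(0)/ncAC_t(t))`, with ncAC the
  non-decay-corrected concentration (⁸⁹Zr half-life 78.41 h).
- **Estimator** — four-point trapezoidal AUC, Patlak coordinates,
  unweighted OLS for (Ki, VT).
- **Experiment engine** — seeded Monte-Carlo over the full condition grid
  (3 input functions × 10 schedules from {24, 48, 96, 144, 192} h ×
  rKi {1, 5, 20}·10⁻³ h⁻¹ × rVT {0.1, 0.2, 0.5} × noise {5, 10, 15}%),
  summarizing percent bias and percent variability per condition.

## Worked example

```python
import numpy as np
import patlaksim as ps

ifn = ps.fixture_library("pertuzumab-like")
ref = ps.KineticParameters(ki=1e-3, vt=0.2)
schedule = ps.SamplingSchedule.from_imaging_times([24, 48, 96])

scen = ps.make_scenario(ifn, ref, schedule, noise0=0.05, seed=42)
x, y = ps.patlak_coordinates(scen.plasma, scen.tissue_noisy, schedule)
fit = ps.fit_patlak(x, y)
print(fit.ki_hat, fit.vt_hat)
```

prints `Ki = 1.222e-03 /h` and `VT = 0.184` for this noise realization,
against references 1.0e-03 and 0.2. The *noise-free* estimate for the same
condition is `Ki = 9.854e-04 /h`, i.e. a deterministic −1.5% bias: the
trapezoid overestimates the AUC of a convex decaying plasma curve, which
stretches the Patlak x-axis and tips the slope down. Ki is underestimated in
**every** condition of the default grid for this reason.

Monte-Carlo summaries come from the experiment engine
(`examples/03_monte_carlo_condition.py`):

```
noise    5%:  Ki bias   -9.0%  Ki variability  25.9%   VT bias   +0.7%  VT variability  20.4%
noise   15%:  Ki bias   -8.5%  Ki variability  77.8%   VT bias   +1.2%  VT variability  61.1%
```

— tripling the noise triples the variability and leaves the bias unchanged.
`examples/04_schedule_grid.py` shows the headline schedule effect: schedules
containing the 24 h sample cut the mean |VT bias| from ~16–22% to ~1–4% and
roughly halve the VT variability, because the early sample pins down the
most curved part of the plasma curve.

A thin CLI wraps the same library:

```bash
patlaksim schedules                      # the 10 imaging-time combinations
patlaksim simulate --fixture pertuzumab-like --out scenario.csv
patlaksim fit scenario.csv               # Patlak fit of a sampled study
patlaksim grid --reps 200 --seed 7 --out summary.csv
```

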