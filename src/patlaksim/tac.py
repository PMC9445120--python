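"""Forward simulation of tissue activity curves (TACs) and counting-statistics noise.

Under the irreversible two-tissue compartment model in its linearized
(Patlak) form, the decay-corrected tissue activity concentration is

    AC_t(t) = Ki·AUC_p(t) + VT·AC_p(t),

where Ki (h⁻¹) is the net irreversible uptake rate and VT (unitless) the
tissue-to-plasma ratio of the reversible compartment at equilibrium.  A
tissue curve generated this way is in equilibrium from t = 0 by
construction.

Noise on the tissue values is derived from counting statistics: the number
of detected counts is Poisson, so the relative uncertainty scales as 1/√N,
and N is proportional to the *non-decay-corrected* activity concentration.
Anchoring the fractional standard deviation at injection time gives

    %SD(t) = noise0 · √( ncAC_t(0) / ncAC_t(t) ),

which grows over time as counts die away with isotope decay and tracer
washout.  Gaussian noise with this fractional SD is applied multiplicatively
to the decay-corrected tissue values; plasma samples are treated as
noise-free (well-counter counting errors are negligible by comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .input_function import InputFunction, analytic_auc, evaluate

__all__ = [
    "ZR89_HALF_LIFE_H",
    "KineticParameters",
    "NoiseModel",
    "simulate_tac",
    "non_decay_corrected",
    "percent_sd",
    "add_noise",
]

#: Physical half-life of zirconium-89 in hours.
ZR89_HALF_LIFE_H = 78.41


@dataclass(frozen=True)
class KineticParameters:
    """Reference kinetic parameters (rKi, rVT) of the irreversible model.

    ``ki`` is the net irreversible uptake rate in h⁻¹ and ``vt`` the
    unitless reversible distribution volume.  Both must be non-negative;
    *estimates* coming out of the Patlak regression are plain floats and
    may legitimately be negative under noise.
    """

    ki: float
    vt: float

    def __post_init__(self) -> None:
        if self.ki < 0:
            raise ValueError("reference ki must be >= 0")
        if self.vt < 0:
            raise ValueError("reference vt must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Counting-statistics noise description.

    ``noise0`` is the fractional SD of the tissue concentration at t = 0
    (0.05 means 5% noise); ``isotope_half_life`` is the physical half-life
    in hours used to un-decay-correct concentrations when propagating the
    count ratio.
    """

    noise0: float
    isotope_half_life: float = ZR89_HALF_LIFE_H

    def __post_init__(self) -> None:
        if not 0 <= self.noise0 < 1:
            raise ValueError("noise0 must lie in [0, 1)")
        if self.isotope_half_life <= 0:
            raise ValueError("isotope_half_life must be positive")


def simulate_tac(ifn: InputFunction, params: KineticParameters, t):
    """Noise-free tissue activity concentration at ``t`` hours (%IA/L).

    Linear in its components: ``ki * analytic_auc + vt * evaluate``.  At
    t = 0 this equals ``vt * (A + B)``.
    """
    return params.ki * analytic_auc(ifn, t) + params.vt * evaluate(ifn, t)


def non_decay_corrected(conc, t, noise: NoiseModel):
    """Remove the decay correction: multiply by 2^(−t / half-life)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.asarray(conc, dtype=float) * 2.0 ** (-t / noise.isotope_half_life)
    return out if out.ndim else float(out)


def percent_sd(tac0, tac_t, t, noise: NoiseModel):
    """Fractional SD of the tissue value at time ``t``.

    ``tac0`` is the noise-free tissue concentration at t = 0 (the anchor,
    decay factor 1) and ``tac_t`` the noise-free value at ``t``.  Returns
    ``noise0 * sqrt(ncAC_t(0) / ncAC_t(t))``, which equals ``noise0`` at
    t = 0 and grows whenever the non-decay-corrected TAC falls.
    """
    tac0 = np.asarray(tac0, dtype=float)
    tac_t = np.asarray(tac_t, dtype=float)
    if np.any(tac0 <= 0) or np.any(tac_t <= 0):
        raise ValueError("tissue concentrations must be positive for noise scaling")
    nc_t = non_decay_corrected(tac_t, t, noise)
    out = noise.noise0 * np.sqrt(tac0 / nc_t)
    return out if np.asarray(out).ndim else float(out)


def add_noise(conc, frac_sd, z):
    """Apply multiplicative Gaussian noise: ``conc * (1 + frac_sd * z)``.

    ``z`` is a standard-normal deviate (caller-supplied, so all randomness
    stays in the caller's seeded generator).  The expectation over ``z`` is
    ``conc`` and the SD is ``conc * frac_sd``; negative outputs are possible
    and deliberately retained — truncation would bias the estimator.
    """
    conc = np.asarray(conc, dtype=float)
    frac_sd = np.asarray(frac_sd, dtype=float)
    if np.any(conc < 0):
        raise ValueError("noise-free concentration must be non-negative")
    if np.any(frac_sd < 0):
        raise ValueError("fractional SD must be non-negative")
    out = conc + conc * frac_sd * np.asarray(z, dtype=float)
    return out if out.ndim else float(out)
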