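"""Sparse-sampling Patlak estimation: trapezoidal AUC, coordinates, regression.

Dividing the operational equation of the irreversible compartment model by
the plasma concentration gives the Patlak plot,

    AC_t/AC_p  =  Ki · (AUC_p / AC_p)  +  VT,

a straight line in the "normalized time" coordinate x = AUC_p/AC_p with
slope Ki and intercept VT.  In sparse ⁸⁹Zr-immuno-PET protocols the plasma
curve is known at only four time points (0 h plus three imaging days), so
AUC_p must be computed by the trapezoidal rule over those samples.  Because
the plasma curve is convex and decreasing, the trapezoid *over*estimates the
true AUC, inflating x and deterministically biasing the fitted slope (Ki)
downward — the central systematic effect this package quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .input_function import SampledCurve

__all__ = ["SamplingSchedule", "PatlakFit", "trapezoid_auc", "patlak_coordinates", "fit_patlak"]


@dataclass(frozen=True)
class SamplingSchedule:
    """Blood-sampling / imaging schedule.

    ``plasma_times`` always start at 0 h (blood sample at injection, used
    only for the AUC); ``imaging_times`` are the later time points at which
    tissue is imaged and which enter the Patlak regression.
    """

    plasma_times: tuple
    imaging_times: tuple

    def __post_init__(self) -> None:
        pt = tuple(float(t) for t in self.plasma_times)
        it = tuple(float(t) for t in self.imaging_times)
        object.__setattr__(self, "plasma_times", pt)
        object.__setattr__(self, "imaging_times", it)
        if not pt or pt[0] != 0.0:
            raise ValueError("plasma_times must start at 0 h")
        if any(b <= a for a, b in zip(pt, pt[1:])):
            raise ValueError("plasma_times must be strictly increasing")
        if it != pt[1:]:
            raise ValueError("imaging_times must equal plasma_times after 0 h")
        if len(it) < 1:
            raise ValueError("at least one imaging time required")

    @classmethod
    def from_imaging_times(cls, imaging_times: Sequence[float]) -> "SamplingSchedule":
        it = tuple(sorted(float(t) for t in imaging_times))
        return cls(plasma_times=(0.0,) + it, imaging_times=it)

    def __str__(self) -> str:
        return "/".join(f"{t:g}" for t in self.imaging_times)


@dataclass(frozen=True)
class PatlakFit:
    """Result of a Patlak linear regression.

    ``ki_hat`` (h⁻¹) and ``vt_hat`` (unitless) are the ordinary
    least-squares slope and intercept of ``patlak_y`` on ``patlak_x``.
    """

    ki_hat: float
    vt_hat: float
    patlak_x: np.ndarray
    patlak_y: np.ndarray


def trapezoid_auc(plasma: SampledCurve, upto: float) -> float:
    """Composite trapezoidal AUC of the sampled plasma curve from 0 to ``upto``.

    ``upto`` must be one of the sample times (no interpolation is done) and
    the curve must include the t = 0 sample.  For a convex decreasing plasma
    curve this is an overestimate of the analytic AUC.
    """
    if plasma.times[0] != 0.0:
        raise ValueError("plasma curve must include a sample at t = 0")
    idx = np.flatnonzero(np.isclose(plasma.times, upto))
    if idx.size == 0:
        raise ValueError(f"upto={upto} is not a plasma sample time")
    k = int(idx[0])
    return float(np.trapezoid(plasma.values[: k + 1], plasma.times[: k + 1]))


def patlak_coordinates(
    plasma: SampledCurve, tissue: SampledCurve, schedule: SamplingSchedule
):
    """Patlak plot coordinates for each imaging time of ``schedule``.

    x = trapezoid_auc(plasma, t) / plasma(t)   (normalized time, h)
    y = tissue(t) / plasma(t)                  (unitless)

    The 0 h plasma sample contributes only to the AUC, never as a
    regression point.  Returns ``(x, y)`` arrays ordered by imaging time.
    """
    xs, ys = [], []
    for t in schedule.imaging_times:
        cp = plasma.value_at(t)
        if cp <= 0:
            raise ValueError(f"plasma concentration must be positive at t={t}")
        xs.append(trapezoid_auc(plasma, t) / cp)
        ys.append(tissue.value_at(t) / cp)
    return np.asarray(xs), np.asarray(ys)


def fit_patlak(x, y) -> PatlakFit:
    """Unweighted OLS line through the Patlak coordinates.

    Exact on collinear input; requires at least two points with distinct x.
    No sign constraint is applied to slope or intercept, so noisy estimates
    may be negative — clamping them would distort bias studies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 points with distinct x for the Patlak fit")
    res = stats.linregress(x, y)
    return PatlakFit(float(res.slope), float(res.intercept), x, y)
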