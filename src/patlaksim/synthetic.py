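"""Generators for plausible mAb-like input functions and end-to-end scenarios.

Used by the test-suite and by users who want stress inputs beyond the three
bundled literature-emulating profiles.  Half-life ranges default to a spread
bracketing published ⁸⁹Zr-mAb serum curves: distribution half-lives of a few
hours to a day, terminal half-lives of roughly two to ten days, and t = 0
concentrations around the value implied by injecting into a 2–3 L plasma
volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .input_function import InputFunction, SampledCurve, evaluate
from .patlak import SamplingSchedule
from .tac import KineticParameters, NoiseModel, add_noise, percent_sd, simulate_tac

__all__ = ["IFGeneratorSpec", "random_input_function", "Scenario", "make_scenario"]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class IFGeneratorSpec:
    """Sampling ranges for random bi-exponential input functions.

    Half-lives in hours (slow strictly above fast), total t = 0
    concentration in %IA/L, and the fraction of it carried by the fast
    phase.  Degenerate (single-point) ranges give deterministic output.
    """

    fast_half_life_range: tuple = (4.0, 24.0)
    slow_half_life_range: tuple = (40.0, 240.0)
    c0_range: tuple = (20.0, 60.0)
    fast_fraction_range: tuple = (0.2, 0.6)

    def __post_init__(self) -> None:
        for name in ("fast_half_life_range", "slow_half_life_range", "c0_range",
                     "fast_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: need 0 < low <= high")
        if self.slow_half_life_range[0] <= self.fast_half_life_range[1]:
            raise ValueError("slow half-life range must lie above the fast range")
        if self.fast_fraction_range[1] >= 1.0:
            raise ValueError("fast fraction must stay below 1")


def random_input_function(
    spec: IFGeneratorSpec = IFGeneratorSpec(), rng=None, label: str = "random"
) -> InputFunction:
    """Draw one valid :class:`InputFunction` uniformly from the spec's ranges."""
    rng = np.random.default_rng(rng)
    t_fast = rng.uniform(*spec.fast_half_life_range)
    t_slow = rng.uniform(*spec.slow_half_life_range)
    c0 = rng.uniform(*spec.c0_range)
    frac = rng.uniform(*spec.fast_fraction_range)
    return InputFunction(
        amp_fast=c0 * frac,
        rate_fast=-_LN2 / t_fast,
        amp_slow=c0 * (1.0 - frac),
        rate_slow=-_LN2 / t_slow,
        label=label,
    )


@dataclass(frozen=True)
class Scenario:
    """Bundled inputs for one simulated study, as the estimator consumes them."""

    ifn: InputFunction
    ref: KineticParameters
    schedule: SamplingSchedule
    plasma: SampledCurve
    tissue_noise_free: SampledCurve
    tissue_noisy: SampledCurve

    def to_csv(self, path) -> None:
        """Write the `fit` CSV dialect: time_h, plasma_pia_per_l, tissue_pia_per_l.

        The t = 0 row has a blank tissue value (plasma-only sample); the
        tissue column holds the *noisy* values the estimator would see.
        """
        lines = ["time_h,plasma_pia_per_l,tissue_pia_per_l"]
        noisy = dict(zip(self.tissue_noisy.times, self.tissue_noisy.values))
        for t, cp in zip(self.plasma.times, self.plasma.values):
            ct = f"{noisy[t]:.10g}" if t in noisy else ""
            lines.append(f"{t:g},{cp:.10g},{ct}")
        Path(path).write_text("\n".join(lines) + "\n")


def make_scenario(
    ifn: InputFunction,
    ref: KineticParameters,
    schedule: SamplingSchedule,
    noise0: float,
    seed: int = 0,
) -> Scenario:
    """Simulate one study's plasma and tissue samples (noise-free + noisy)."""
    t_plasma = np.asarray(schedule.plasma_times)
    t_img = np.asarray(schedule.imaging_times)
    plasma = SampledCurve(t_plasma, evaluate(ifn, t_plasma))
    tac = simulate_tac(ifn, ref, t_img)
    if noise0 > 0:
        noise = NoiseModel(noise0)
        frac_sd = percent_sd(simulate_tac(ifn, ref, 0.0), tac, t_img, noise)
        z = np.random.default_rng(seed).standard_normal(t_img.size)
        noisy = add_noise(tac, frac_sd, z)
    else:
        noisy = tac.copy()
    return Scenario(
        ifn=ifn,
        ref=ref,
        schedule=schedule,
        plasma=plasma,
        tissue_noise_free=SampledCurve(t_img, tac),
        tissue_noisy=SampledCurve(t_img, noisy),
    )
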