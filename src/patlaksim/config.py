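"""Experiment configuration: validated grid axes with study defaults.

An empty config file expands to the full default study grid: the three
bundled input functions × all 10 three-point schedules from
{24, 48, 96, 144, 192} h × rKi {1, 5, 20}·10⁻³ h⁻¹ × rVT {0.1, 0.2, 0.5} ×
noise {5, 10, 15}% — 810 conditions at 1000 repetitions each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .input_function import available_fixtures

__all__ = ["ExperimentConfig", "load_config", "save_config"]

_DEFAULTS = dict(
    fixtures=["huJ591-like", "trastuzumab-like", "pertuzumab-like"],
    candidate_times=[24.0, 48.0, 96.0, 144.0, 192.0],
    schedule_size=3,
    require_time=None,
    rki_values=[1e-3, 5e-3, 20e-3],
    rvt_values=[0.1, 0.2, 0.5],
    noise_levels=[0.05, 0.10, 0.15],
    n_reps=1000,
    seed=0,
)


@dataclass
class ExperimentConfig:
    """Validated axes of a Monte-Carlo grid experiment."""

    fixtures: list = field(default_factory=lambda: list(_DEFAULTS["fixtures"]))
    candidate_times: list = field(
        default_factory=lambda: list(_DEFAULTS["candidate_times"])
    )
    schedule_size: int = 3
    require_time: float | None = None
    rki_values: list = field(default_factory=lambda: list(_DEFAULTS["rki_values"]))
    rvt_values: list = field(default_factory=lambda: list(_DEFAULTS["rvt_values"]))
    noise_levels: list = field(
        default_factory=lambda: list(_DEFAULTS["noise_levels"])
    )
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        known = available_fixtures()
        for name in self.fixtures:
            if isinstance(name, str) and name not in known:
                raise ValueError(
                    f"fixtures: unknown fixture {name!r}; available: {', '.join(known)}"
                )
        if not self.candidate_times or any(t <= 0 for t in self.candidate_times):
            raise ValueError("candidate_times: must be positive hours")
        if len(set(self.candidate_times)) != len(self.candidate_times):
            raise ValueError("candidate_times: duplicates not allowed")
        if not 1 <= self.schedule_size <= len(self.candidate_times):
            raise ValueError("schedule_size: must be between 1 and |candidate_times|")
        if self.require_time is not None and float(self.require_time) not in [
            float(t) for t in self.candidate_times
        ]:
            raise ValueError("require_time: must be one of candidate_times")
        if any(k < 0 for k in self.rki_values) or not self.rki_values:
            raise ValueError("rki_values: must be non-empty, all >= 0 (h^-1)")
        if any(v <= 0 for v in self.rvt_values) or not self.rvt_values:
            raise ValueError("rvt_values: must be non-empty, all > 0")
        if any(not 0 <= n < 1 for n in self.noise_levels) or not self.noise_levels:
            raise ValueError("noise_levels: fractional SDs in [0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps: must be >= 1")

    @property
    def n_conditions(self) -> int:
        from math import comb

        n_sched = comb(len(self.candidate_times), self.schedule_size)
        if self.require_time is not None:
            n_sched = comb(len(self.candidate_times) - 1, self.schedule_size - 1)
        return (
            len(self.fixtures)
            * n_sched
            * len(self.rki_values)
            * len(self.rvt_values)
            * len(self.noise_levels)
        )


def load_config(path) -> ExperimentConfig:
    """Load a YAML/JSON experiment config; missing fields take study defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(
            f"{path}: unknown config fields {sorted(unknown)}; "
            f"expected a subset of {sorted(_DEFAULTS)}"
        )
    try:
        return ExperimentConfig(**raw)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def save_config(config: ExperimentConfig, path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
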