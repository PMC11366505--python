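"""Lifetime phosphorus-excretion projection for a market pig.

Drives the Gompertz growth curve and a pair of excretion models (fecal
and urinary) over a phase-feeding schedule: one prediction per integer
day of age, phase means, a lifetime mean, and annualized totals.

Conventions (they matter for reproducing published budgets):

* the daily grid is integer ages, inclusive at both ends — the default
  27..180-day schedule gives 154 days, each weighted equally;
* BW is evaluated at the integer age itself;
* the "total" stream is the per-day sum of the fecal and urinary
  predictions, not a separately fitted total model;
* annualization is mean daily excretion (g/d) x 365 / 1000 (kg/yr);
* rounding to the 2 decimals used in reporting happens only at the
  presentation layer — all stored values are full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .excretion_models import (
    ExcretionModel,
    evaluate,
    load_published_models,
    within_fitted_domain,
)
from .growth import DEFAULT_GOMPERTZ, GompertzParams, gompertz_bw

__all__ = [
    "Phase",
    "PhaseSchedule",
    "ProjectionResult",
    "default_schedule",
    "project_daily",
    "annualize",
    "herd_adjust",
]

STREAMS = ("fecal", "urinary", "total")


class ScheduleError(ValueError):
    """Phase schedule has a gap, an overlap, or an inverted interval."""


class UnsupportedModelError(ValueError):
    """Model cannot be projected (needs a feed-intake trajectory)."""


@dataclass(frozen=True)
class Phase:
    """One feeding phase: an inclusive integer age interval and its diet P."""

    label: str
    age_start_d: int
    age_end_d: int
    diet_p_pct: float
    bw_range_kg: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.age_start_d > self.age_end_d:
            raise ScheduleError(
                f"phase {self.label!r}: age_start_d {self.age_start_d} > age_end_d {self.age_end_d}"
            )
        if not np.isfinite(self.diet_p_pct) or self.diet_p_pct < 0:
            raise ValueError(f"phase {self.label!r}: diet_p_pct must be finite and >= 0")

    @property
    def n_days(self) -> int:
        return self.age_end_d - self.age_start_d + 1


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous, non-overlapping feeding phases.

    Phases are sorted by starting age on construction, so two schedules
    with the same phases in different order are the same schedule.
    """

    phases: tuple[Phase, ...]

    def __init__(self, phases: Sequence[Phase]):
        ordered = tuple(sorted(phases, key=lambda p: p.age_start_d))
        if not ordered:
            raise ScheduleError("schedule must contain at least one phase")
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.age_start_d != prev.age_end_d + 1:
                kind = "overlap" if nxt.age_start_d <= prev.age_end_d else "gap"
                raise ScheduleError(
                    f"{kind} between phases {prev.label!r} (ends {prev.age_end_d}) "
                    f"and {nxt.label!r} (starts {nxt.age_start_d})"
                )
        object.__setattr__(self, "phases", ordered)

    @property
    def age_start_d(self) -> int:
        return self.phases[0].age_start_d

    @property
    def age_end_d(self) -> int:
        return self.phases[-1].age_end_d

    @property
    def n_days(self) -> int:
        return self.age_end_d - self.age_start_d + 1

    def phase_of(self, age_d: int) -> Phase:
        for ph in self.phases:
            if ph.age_start_d <= age_d <= ph.age_end_d:
                return ph
        raise ScheduleError(f"age {age_d} outside schedule span {self.age_start_d}..{self.age_end_d}")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PhaseSchedule":
        phases = []
        for rec in data["phases"]:
            bw_range = None
            if "bw_low" in rec and "bw_high" in rec:
                bw_range = (float(rec["bw_low"]), float(rec["bw_high"]))
            phases.append(
                Phase(
                    label=str(rec["label"]),
                    age_start_d=int(rec["age_start"]),
                    age_end_d=int(rec["age_end"]),
                    diet_p_pct=float(rec["diet_p_pct"]),
                    bw_range_kg=bw_range,
                )
            )
        return cls(phases)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PhaseSchedule":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))

    def to_mapping(self) -> dict:
        out = []
        for ph in self.phases:
            rec = {
                "label": ph.label,
                "age_start": ph.age_start_d,
                "age_end": ph.age_end_d,
                "diet_p_pct": ph.diet_p_pct,
            }
            if ph.bw_range_kg is not None:
                rec["bw_low"], rec["bw_high"] = ph.bw_range_kg
            out.append(rec)
        return {"phases": out}


def default_schedule() -> PhaseSchedule:
    """The six-phase schedule: ages 27-180 d, diet P 0.64% down to 0.40%."""
    text = resources.files("pigpex.data").joinpath("default_schedule.yaml").read_text()
    return PhaseSchedule.from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class ProjectionResult:
    """Daily series plus phase/lifetime/annual summaries.

    ``daily`` has one row per integer age with columns age_d, bw_kg,
    diet_p_pct, phase, fecal_g_d, urinary_g_d, total_g_d, in_domain.
    ``phase_means`` is indexed by phase label with one column per
    stream (g/d); ``lifetime_mean_g_d`` and ``annual_kg_yr`` map stream
    name to value.
    """

    daily: pd.DataFrame
    phase_means: pd.DataFrame
    lifetime_mean_g_d: Mapping[str, float]
    annual_kg_yr: Mapping[str, float]

    def rounded_summary(self, ndigits: int = 2) -> dict:
        """Presentation copy: half-up rounding at the reported precision."""

        def _round(x: float) -> float:
            q = 10.0**ndigits
            return float(np.floor(x * q + 0.5) / q)

        return {
            "phase_means_g_d": {
                s: {lab: _round(v) for lab, v in self.phase_means[s].items()} for s in STREAMS
            },
            "lifetime_mean_g_d": {s: _round(self.lifetime_mean_g_d[s]) for s in STREAMS},
            "annual_kg_yr": {s: _round(self.annual_kg_yr[s]) for s in STREAMS},
        }


def annualize(mean_g_d: float) -> float:
    """Convert a mean daily excretion (g/d) to an annual total (kg/yr)."""
    if not np.isfinite(mean_g_d):
        raise ValueError("mean_g_d must be finite")
    return mean_g_d * 365.0 / 1000.0


def herd_adjust(
    pig_annual_kg_yr: float, sow_multiplier: float = 2.0, sow_fraction: float = 0.10
) -> float:
    """Herd-level annual excretion per head, counting the sow population.

    Sows excrete ``sow_multiplier`` times as much P as a market pig and
    make up ``sow_fraction`` of the herd; the per-head average is
    (1 - f) * pig + f * multiplier * pig.
    """
    if not (0.0 <= sow_fraction <= 1.0):
        raise ValueError(f"sow_fraction must lie in [0, 1], got {sow_fraction!r}")
    if sow_multiplier <= 0:
        raise ValueError("sow_multiplier must be positive")
    return (1.0 - sow_fraction) * pig_annual_kg_yr + sow_fraction * sow_multiplier * pig_annual_kg_yr


def project_daily(
    growth: GompertzParams = DEFAULT_GOMPERTZ,
    fecal_model: ExcretionModel | None = None,
    urinary_model: ExcretionModel | None = None,
    schedule: PhaseSchedule | None = None,
) -> ProjectionResult:
    """Project daily P excretion over the schedule's age span.

    ``fecal_model`` and ``urinary_model`` default to the published BW-
    and-diet-P equations.  Models with feed-intake terms are rejected:
    the projection defines no FI trajectory.
    """
    if schedule is None:
        schedule = default_schedule()
    if fecal_model is None or urinary_model is None:
        published = load_published_models()
        fecal_model = fecal_model or published["Eq1"]
        urinary_model = urinary_model or published["Eq2"]
    for model in (fecal_model, urinary_model):
        if model.requires_fi():
            raise UnsupportedModelError(
                f"model {model.name!r} uses feed-intake terms; the projection "
                "defines no daily FI trajectory"
            )

    ages = np.arange(schedule.age_start_d, schedule.age_end_d + 1)
    bw = gompertz_bw(growth, ages)
    labels = np.empty(ages.shape, dtype=object)
    dietp = np.empty(ages.shape, dtype=float)
    for i, a in enumerate(ages):
        ph = schedule.phase_of(int(a))
        labels[i] = ph.label
        dietp[i] = ph.diet_p_pct

    fecal = evaluate(fecal_model, bw_kg=bw, diet_p_pct=dietp)
    urinary = evaluate(urinary_model, bw_kg=bw, diet_p_pct=dietp)
    daily = pd.DataFrame(
        {
            "age_d": ages,
            "bw_kg": bw,
            "diet_p_pct": dietp,
            "phase": labels,
            "fecal_g_d": fecal,
            "urinary_g_d": urinary,
            "total_g_d": fecal + urinary,
            "in_domain": within_fitted_domain(bw_kg=bw, diet_p_pct=dietp),
        }
    )

    stream_cols = {"fecal": "fecal_g_d", "urinary": "urinary_g_d", "total": "total_g_d"}
    order = [ph.label for ph in schedule.phases]
    grouped = daily.groupby("phase", sort=False)[list(stream_cols.values())].mean().loc[order]
    phase_means = grouped.rename(columns={v: k for k, v in stream_cols.items()})
    lifetime = {s: float(daily[c].mean()) for s, c in stream_cols.items()}
    annual = {s: annualize(v) for s, v in lifetime.items()}
    return ProjectionResult(
        daily=daily,
        phase_means=phase_means,
        lifetime_mean_g_d=lifetime,
        annual_kg_yr=annual,
    )
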