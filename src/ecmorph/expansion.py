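"""Tissue-expansion kinetics: theoretical vs empirical expansion index.

A subcutaneous expander inflated with saline is modelled as a hemisphere,
volume V = (2/3)*pi*r^3 and dome surface area A = 2*pi*r^2, so the area
available to the overlying skin scales as V^(2/3).  The *theoretical*
expansion index is the injected volume to the 2/3 power normalized to a
reference day; the *empirical* index uses hair-follicle density: follicles
neither form nor vanish during expansion, so 1/alpha (alpha = follicles
per mm^2) is proportional to skin area, and its value normalized to the
reference day tracks realized area growth.

While regeneration keeps pace, the two curves coincide.  Regenerative
exhaustion appears as a persistent shortfall of the empirical curve below
the theoretical one; :func:`detect_decoupling` reports the first day from
which the shortfall persists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InjectionSchedule",
    "FollicleCounts",
    "IndexSeries",
    "DecouplingReport",
    "DEFAULT_SCHEDULE",
    "cumulative_volume",
    "theoretical_index",
    "empirical_index",
    "build_index_series",
    "detect_decoupling",
]


@dataclass(frozen=True)
class InjectionSchedule:
    """Expander inflation protocol: initial fill plus timed additions."""

    initial_volume_ml: float
    additions: tuple[tuple[float, float], ...]  # (day, added mL)
    cap_ml: float | None = None

    def __post_init__(self) -> None:
        if self.initial_volume_ml <= 0:
            raise ValueError("initial volume must be > 0")
        days = [d for d, _ in self.additions]
        if any(v <= 0 for _, v in self.additions):
            raise ValueError("added volumes must be > 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("addition days must be strictly increasing")
        if self.cap_ml is not None and self.cap_ml < self.initial_volume_ml:
            raise ValueError("cap must be at least the initial volume")


def _default_schedule() -> InjectionSchedule:
    # 0.6 mL at implantation, 0.3 mL every 4 days, to a 3.0 mL total
    return InjectionSchedule(
        initial_volume_ml=0.6,
        additions=tuple((float(d), 0.3) for d in range(4, 41, 4)),
        cap_ml=3.0,
    )


DEFAULT_SCHEDULE = _default_schedule()


@dataclass(frozen=True)
class FollicleCounts:
    """Hair-follicle density (per mm^2) measured on given days."""

    observations: tuple[tuple[float, float], ...]  # (day, density per mm^2)

    def __post_init__(self) -> None:
        if any(d < 0 for d, _ in self.observations):
            raise ValueError("days must be non-negative")
        if any(a <= 0 for _, a in self.observations):
            raise ValueError("densities must be > 0")

    def density(self, day: float) -> float:
        for d, a in self.observations:
            if d == day:
                return a
        raise KeyError(f"no follicle density recorded for day {day}")

    @property
    def days(self) -> list[float]:
        return [d for d, _ in self.observations]


@dataclass
class DecouplingReport:
    decoupling_day: float | None
    tolerance: float
    shortfall: dict[float, float]  # day -> 1 - E/T


@dataclass
class IndexSeries:
    """Aligned theoretical and empirical index curves."""

    days: list[float]
    theoretical: list[float]
    empirical: list[float]
    reference_day: float = 4.0


def cumulative_volume(schedule: InjectionSchedule, day: float) -> float:
    """Total injected volume (mL) on a given day, cap applied."""
    if day < 0:
        raise ValueError("day must be >= 0")
    vol = schedule.initial_volume_ml + sum(
        v for d, v in schedule.additions if d <= day
    )
    if schedule.cap_ml is not None:
        vol = min(vol, schedule.cap_ml)
    return vol


def theoretical_index(
    schedule: InjectionSchedule, days, reference_day: float = 4.0
) -> np.ndarray:
    """T(d) = (V(d) / V(ref))^(2/3), the hemisphere area-growth ratio."""
    v_ref = cumulative_volume(schedule, reference_day)
    if v_ref <= 0:
        raise ValueError("cumulative volume at the reference day must be > 0")
    vols = np.array([cumulative_volume(schedule, d) for d in days], dtype=float)
    return (vols / v_ref) ** (2.0 / 3.0)


def empirical_index(
    counts: FollicleCounts, days=None, reference_day: float = 4.0
) -> np.ndarray:
    """E(d) = alpha(ref) / alpha(d): reciprocal-density area ratio."""
    try:
        a_ref = counts.density(reference_day)
    except KeyError:
        raise ValueError(
            f"reference day {reference_day} missing from the follicle series"
        ) from None
    if days is None:
        days = counts.days
    return np.array([a_ref / counts.density(d) for d in days], dtype=float)


def build_index_series(
    schedule: InjectionSchedule,
    counts: FollicleCounts,
    reference_day: float = 4.0,
) -> IndexSeries:
    """Evaluate both curves on the follicle-observation days."""
    days = counts.days
    t = theoretical_index(schedule, days, reference_day)
    e = empirical_index(counts, days, reference_day)
    return IndexSeries(
        days=list(days), theoretical=list(t), empirical=list(e),
        reference_day=reference_day,
    )


def detect_decoupling(series: IndexSeries, tolerance: float = 0.10) -> DecouplingReport:
    """First day from which E persistently falls below (1 - tol) * T.

    The decoupling day is the smallest observed day d* such that
    E(d) < (1 - tolerance) * T(d) on d* and on every later observed day;
    ``None`` when no such day exists.  The per-day shortfall 1 - E/T is
    reported for all days.
    """
    days = series.days
    t = np.asarray(series.theoretical, dtype=float)
    e = np.asarray(series.empirical, dtype=float)
    below = e < (1.0 - tolerance) * t
    shortfall = {d: float(1.0 - ei / ti) for d, ti, ei in zip(days, t, e)}
    day_star = None
    # scan from the end: the suffix where `below` holds throughout
    for i in range(len(days) - 1, -1, -1):
        if not below[i]:
            break
        day_star = days[i]
    return DecouplingReport(
        decoupling_day=day_star, tolerance=tolerance, shortfall=shortfall
    )
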