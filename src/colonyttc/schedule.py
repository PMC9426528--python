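"""Piecewise-constant light/temperature regimes for cycling experiments.

A colony biofilm experiment alternates illumination (and, optionally, a
small temperature change) with a fixed period, e.g. 12 h of white light at
25 degC followed by 12 h of darkness at 23 degC, repeated for six days.
The schedule is the single source of truth for "what condition was the
incubator in at time t"; both the synthetic movie generator and the
cohort-labelling step consult it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import pandas as pd

LIGHT = "light"
DARK = "dark"


@dataclass(frozen=True)
class Interval:
    """One contiguous stretch of constant conditions, half-open [start_h, end_h)."""

    start_h: float
    end_h: float
    light: bool
    temp_C: float

    def __post_init__(self) -> None:
        if not self.start_h < self.end_h:
            raise ValueError(
                f"interval start_h ({self.start_h}) must be < end_h ({self.end_h})"
            )

    @property
    def label(self) -> str:
        return LIGHT if self.light else DARK

    def contains(self, t_h: float) -> bool:
        return self.start_h <= t_h < self.end_h


@dataclass(frozen=True)
class ConditionSchedule:
    """An ordered, contiguous cover of [0, total_h) by condition intervals."""

    intervals: tuple[Interval, ...]
    total_h: float

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule needs at least one interval")
        if self.intervals[0].start_h != 0:
            raise ValueError("first interval must start at 0 h")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.end_h != b.start_h:
                raise ValueError(
                    f"intervals must be contiguous: gap/overlap at {a.end_h} vs {b.start_h}"
                )
        if self.intervals[-1].end_h != self.total_h:
            raise ValueError("last interval must end at total_h")

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def interval_at(self, t_h: float) -> Interval:
        """The interval containing time ``t_h`` (half-open containment)."""
        if not 0 <= t_h < self.total_h:
            raise ValueError(
                f"time {t_h} h is outside the schedule span [0, {self.total_h}) h"
            )
        for iv in self.intervals:
            if iv.contains(t_h):
                return iv
        raise AssertionError("contiguous schedule must contain t_h")  # pragma: no cover

    def label_at(self, t_h: float) -> str:
        return self.interval_at(t_h).label

    def temp_at(self, t_h: float) -> float:
        return self.interval_at(t_h).temp_C

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_h": [iv.start_h for iv in self.intervals],
                "end_h": [iv.end_h for iv in self.intervals],
                "light": [iv.light for iv in self.intervals],
                "temp_C": [iv.temp_C for iv in self.intervals],
            }
        )


def make_schedule(
    period_h: float,
    light_fraction: float,
    total_h: float,
    temp_light: float,
    temp_dark: float,
    phase_offset_h: float = 0.0,
) -> ConditionSchedule:
    """Build an alternating light/dark schedule starting with light at t = 0.

    Parameters
    ----------
    period_h
        Length of one full light+dark cycle in hours (e.g. 24 for the
        standard 12 h light / 12 h dark regime).
    light_fraction
        Fraction of each period spent in the light, in (0, 1).
    total_h
        Experiment duration; the last interval is truncated here.
    temp_light, temp_dark
        Incubator temperature during light and dark intervals (degC).
        Pass equal values for light-only cycling.
    phase_offset_h
        Shifts the cycle so that t = 0 falls ``phase_offset_h`` hours into
        it; 0 starts exactly at lights-on.
    """
    if period_h <= 0:
        raise ValueError(f"period_h must be positive, got {period_h}")
    if total_h < period_h:
        raise ValueError(
            f"total_h ({total_h}) must be at least one period ({period_h})"
        )
    if not 0 < light_fraction < 1:
        raise ValueError(f"light_fraction must be in (0, 1), got {light_fraction}")

    light_h = period_h * light_fraction
    # Walk cycle boundaries from (possibly negative) phase-shifted origin.
    edges: list[tuple[float, bool]] = []  # (start of segment, is_light)
    t0 = -(phase_offset_h % period_h)
    t = t0
    while t < total_h:
        edges.append((t, True))
        edges.append((t + light_h, False))
        t += period_h

    intervals: list[Interval] = []
    for (start, is_light), (end, _) in zip(edges, edges[1:] + [(total_h + period_h, True)]):
        start_c = max(start, 0.0) + 0.0  # +0.0 normalizes -0.0
        end_c = min(end, total_h)
        if start_c < end_c:
            intervals.append(
                Interval(start_c, end_c, is_light, temp_light if is_light else temp_dark)
            )
    return ConditionSchedule(tuple(intervals), total_h)


def schedule_to_csv(schedule: ConditionSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def schedule_from_csv(path) -> ConditionSchedule:
    df = pd.read_csv(path)
    intervals = tuple(
        Interval(float(r.start_h), float(r.end_h), bool(r.light), float(r.temp_C))
        for r in df.itertuples()
    )
    return ConditionSchedule(intervals, intervals[-1].end_h)
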