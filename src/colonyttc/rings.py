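"""Ring-cohort dynamics: the figure-level quantities of colony movies.

Because the colony expands radially, distance from the center encodes age:
pixels that first crossed the colony threshold within one time window form
a "ring of growth" (cohort). This module derives the quantities used to
characterize entrenched ring physiology:

* cohort traces — mean signal vs time since birth for each ring;
* the lagged edge trace — for each cohort of newly detected edge pixels,
  the mean intensity a fixed lag (default 12 h) after first detection; the
  primary oscillation readout;
* reduction rates — smoothed time derivatives of cohort traces;
* radial profiles and kymographs;
* cohort condition labels from the light/dark schedule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundary import BirthTimeMap, _ray_radii_and_pixels
from .schedule import ConditionSchedule
from .stack import FrameStack

log = logging.getLogger(__name__)


@dataclass
class RingCohort:
    """Pixels born within one half-open window [t0_h, t1_h), with condition label."""

    birth_window: tuple[float, float]
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    label: str = ""
    label_temp_C: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.pixel_rows) != len(self.pixel_cols):
            raise ValueError("pixel row/col arrays must have equal length")
        if len(self.pixel_rows) == 0:
            raise ValueError("cohort must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_rows)


@dataclass
class CohortTrace:
    """Mean cohort signal re-indexed to time since the cohort's birth."""

    time_since_birth_h: np.ndarray
    mean_intensity: np.ndarray
    birth_h: float
    label: str = ""
    rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_since_birth_h = np.asarray(self.time_since_birth_h, dtype=np.float64)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=np.float64)
        if len(self.time_since_birth_h) != len(self.mean_intensity):
            raise ValueError("trace grids must have equal length")
        if len(self.time_since_birth_h) and self.time_since_birth_h[0] != 0:
            raise ValueError("time_since_birth_h must start at 0")

    @property
    def final_value(self) -> float:
        return float(self.mean_intensity[-1])


@dataclass
class RadialProfile:
    distance_px: np.ndarray
    intensity: np.ndarray


@dataclass
class Kymograph:
    radial_positions_px: np.ndarray
    timestamps_h: np.ndarray
    values: np.ndarray  # (radius, time)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.radial_positions_px), len(self.timestamps_h)):
            raise ValueError("kymograph grid does not match its axes")


def cohort_pixels(birth_map: BirthTimeMap, window: tuple[float, float]):
    """(rows, cols) of pixels with t0 <= birth_h < t1; may be empty."""
    t0, t1 = window
    if not t0 < t1:
        raise ValueError(f"birth window must satisfy t0 < t1, got {window}")
    mask = (birth_map.birth_h >= t0) & (birth_map.birth_h < t1)
    return np.nonzero(mask)


def make_cohorts(
    birth_map: BirthTimeMap,
    window_h: float,
    schedule: ConditionSchedule | None = None,
) -> list[RingCohort]:
    """Partition colonized pixels into consecutive birth windows of width ``window_h``.

    Windows start at the earliest birth time; empty windows are dropped.
    With a schedule, each cohort is labelled by the condition at its window
    start.
    """
    births = birth_map.birth_h[birth_map.colonized]
    if births.size == 0:
        return []
    t_min, t_max = births.min(), births.max()
    cohorts = []
    t0 = t_min
    while t0 <= t_max:
        rows, cols = cohort_pixels(birth_map, (t0, t0 + window_h))
        if len(rows):
            label, temp = "", float("nan")
            if schedule is not None and 0 <= t0 < schedule.total_h:
                iv = schedule.interval_at(t0)
                label, temp = iv.label, iv.temp_C
            cohorts.append(RingCohort((t0, t0 + window_h), rows, cols, label, temp))
        t0 += window_h
    return cohorts


def interval_cohorts(
    birth_map: BirthTimeMap, schedule: ConditionSchedule
) -> list[RingCohort]:
    """One cohort per schedule interval (ring formed in one light or dark phase)."""
    cohorts = []
    for iv in schedule:
        rows, cols = cohort_pixels(birth_map, (iv.start_h, iv.end_h))
        if len(rows):
            cohorts.append(
                RingCohort((iv.start_h, iv.end_h), rows, cols, iv.label, iv.temp_C)
            )
    return cohorts


def cohort_trace(stack: FrameStack, cohort: RingCohort) -> CohortTrace:
    """Mean working-channel value over cohort pixels vs time since birth.

    Frames at or after the cohort's earliest member birth are kept and the
    time axis re-zeroed at that first frame.
    """
    h, w = stack.shape
    if (
        (cohort.pixel_rows < 0).any() or (cohort.pixel_rows >= h).any()
        or (cohort.pixel_cols < 0).any() or (cohort.pixel_cols >= w).any()
    ):
        raise ValueError("cohort contains pixels outside the image")
    series = stack.frames[:, cohort.pixel_rows, cohort.pixel_cols].mean(axis=1)
    start = int(np.searchsorted(stack.timestamps_h, cohort.birth_window[0]))
    if start >= stack.n_frames:
        raise ValueError("cohort is born after the last frame")
    t = stack.timestamps_h[start:] - stack.timestamps_h[start]
    return CohortTrace(t, series[start:], birth_h=float(stack.timestamps_h[start]),
                       label=cohort.label)


def edge_trace_lagged(
    stack: FrameStack, birth_map: BirthTimeMap, lag_h: float = 12.0
) -> pd.DataFrame:
    """Mean intensity of each detection cohort, ``lag_h`` hours after detection.

    For every distinct birth time t with at least one pixel, reports the
    mean working-channel value of those pixels at the frame nearest
    t + lag_h. Birth times whose lagged readout falls beyond the last frame
    are omitted. Returns a DataFrame with columns birth_h, mean_intensity,
    n_pixels.
    """
    if lag_h < 0:
        raise ValueError(f"lag_h must be non-negative, got {lag_h}")
    births = birth_map.birth_h
    distinct = np.unique(births[~np.isnan(births)])
    rows = []
    t_end = stack.timestamps_h[-1]
    for t in distinct:
        if t + lag_h > t_end + 1e-9:
            continue
        rr, cc = np.nonzero(births == t)
        j = stack.nearest_frame_index(t + lag_h)
        rows.append(
            {
                "birth_h": float(t),
                "mean_intensity": float(stack.frames[j, rr, cc].mean()),
                "n_pixels": int(len(rr)),
            }
        )
    if not rows:
        log.warning("lagged edge trace is empty (lag %.1f h beyond movie end?)", lag_h)
        return pd.DataFrame(columns=["birth_h", "mean_intensity", "n_pixels"])
    return pd.DataFrame(rows)


def reduction_rate(
    trace: CohortTrace, smooth_window_h: float = 1.5
) -> np.ndarray:
    """Time derivative of the (optionally smoothed) cohort trace.

    The trace is smoothed over ``smooth_window_h`` (an odd number of
    frames; a sliding mean in the interior, degree-1 fits at the ends so
    linear traces pass through unchanged) and differentiated with centered
    finite differences; the endpoints use one-sided differences. Pass
    ``smooth_window_h=0`` for no smoothing.
    """
    from scipy.signal import savgol_filter

    y = trace.mean_intensity
    t = trace.time_since_birth_h
    if len(y) < 3:
        raise ValueError("rate needs a trace of at least 3 points")
    dt = float(np.median(np.diff(t)))
    n_win = max(int(round(smooth_window_h / dt)), 1) if smooth_window_h > 0 else 1
    if n_win % 2 == 0:
        n_win += 1
    if n_win > 1 and n_win <= len(y):
        y = savgol_filter(y, n_win, 1)
    rate = np.gradient(y, t)
    trace.rate = rate
    return rate


def radial_profile(
    frame: np.ndarray,
    center: tuple[float, float],
    n_angles: int = 1,
    max_radius: float | None = None,
) -> RadialProfile:
    """Mean working-channel value at each integer radius over ``n_angles`` rays.

    ``n_angles=1`` reproduces single-radius quantification along angle 0;
    larger values average equally spaced rays. The profile extends to the
    largest radius that stays inside the image for every ray.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"center {center} lies outside the {frame.shape} frame")
    if n_angles < 1:
        raise ValueError("n_angles must be at least 1")
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    per_ray = []
    for angle in angles:
        radii, rows, cols = _ray_radii_and_pixels(frame.shape, center, angle, max_radius)
        per_ray.append((radii, frame[rows, cols]))
    r_max = min(len(radii) for radii, _ in per_ray)
    values = np.stack([v[:r_max] for _, v in per_ray])
    return RadialProfile(np.arange(r_max), values.mean(axis=0))


def kymograph(
    stack: FrameStack,
    center: tuple[float, float],
    angle: float = 0.0,
    max_radius_px: int | None = None,
) -> Kymograph:
    """Intensity along one radius vs time, nearest-pixel sampled.

    ``values[r, t]`` is the working-channel value at integer radius ``r``
    along ``angle`` in frame ``t``.
    """
    h, w = stack.shape
    radii, rows, cols = _ray_radii_and_pixels((h, w), center, angle, None)
    if max_radius_px is not None:
        if max_radius_px > radii[-1]:
            raise ValueError(
                f"max_radius_px={max_radius_px} leaves the image (ray ends at {radii[-1]})"
            )
        radii, rows, cols = radii[: max_radius_px + 1], rows[: max_radius_px + 1], cols[: max_radius_px + 1]
    values = stack.frames[:, rows, cols].T  # (radius, time)
    return Kymograph(radii, stack.timestamps_h.copy(), np.asarray(values, dtype=np.float64))


def classify_cohort(birth_h: float, schedule: ConditionSchedule) -> tuple[str, float]:
    """(label, temperature) of the schedule interval containing ``birth_h``.

    Containment is half-open, so a birth exactly on an interval boundary
    belongs to the later interval.
    """
    iv = schedule.interval_at(birth_h)
    return iv.label, iv.temp_C


def classify_birth_map(
    birth_map: BirthTimeMap, schedule: ConditionSchedule
) -> np.ndarray:
    """Pixelwise light/dark labels (codes 0 agar, 1 light, 2 dark) from birth times."""
    from .synthetic import LABEL_AGAR, LABEL_DARK, LABEL_LIGHT

    births = birth_map.birth_h
    starts = np.array([iv.start_h for iv in schedule.intervals])
    is_light = np.array([iv.light for iv in schedule.intervals])
    valid = ~np.isnan(births) & (births >= 0) & (births < schedule.total_h)
    idx = np.clip(
        np.searchsorted(starts, np.nan_to_num(births), side="right") - 1,
        0,
        len(starts) - 1,
    )
    labels = np.where(valid, np.where(is_light[idx], LABEL_LIGHT, LABEL_DARK), LABEL_AGAR)
    return labels.astype(np.uint8)


# ---------------------------------------------------------------------------
# CSV writers (long format, one row per observation).

def cohort_traces_to_frame(traces: list[CohortTrace]) -> pd.DataFrame:
    frames = []
    for i, tr in enumerate(traces):
        df = pd.DataFrame(
            {
                "cohort_id": i,
                "birth_h": tr.birth_h,
                "label": tr.label,
                "t_since_birth_h": tr.time_since_birth_h,
                "mean_intensity": tr.mean_intensity,
            }
        )
        df["rate"] = tr.rate if tr.rate is not None else np.nan
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cohort_id", "birth_h", "label", "t_since_birth_h", "mean_intensity", "rate"]
    )


def radial_profile_to_frame(profile: RadialProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {"distance_px": profile.distance_px, "intensity": profile.intensity}
    )


def kymograph_to_frame(kymo: Kymograph) -> pd.DataFrame:
    rr, tt = np.meshgrid(kymo.radial_positions_px, kymo.timestamps_h, indexing="ij")
    return pd.DataFrame(
        {"r_px": rr.ravel(), "t_h": tt.ravel(), "value": kymo.values.ravel()}
    )
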