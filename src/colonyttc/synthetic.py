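"""Synthetic colony-movie generator with known ground truth.

The generator embodies the "entrenchment" picture of ring formation in
expanding colony biofilms: the colony edge advances at a constant radial
speed, and the environmental condition (light/dark, temperature) at the
moment a zone of biomass forms sets that zone's TTC-reduction capacity,
which then stays fixed while conditions keep cycling. Each pixel therefore
accumulates red (reduced-TTC) signal after its birth time with saturating
kinetics

    I(t) = A_label * (1 - exp(-(t - t_birth) / tau)),   t >= t_birth,

where ``A_label`` depends only on the schedule condition at ``t_birth``.
Biomass born in the dark has the larger saturating amplitude, which is the
direction of effect observed experimentally, and the time constant ``tau``
puts the rapid accumulation phase in the first 10-15 h after a zone forms.

The reduced-TTC signal is encoded as intensity ABOVE the agar background
mean; darkening of raw images is the channel transform's business, not the
generator's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import DARK, LIGHT, ConditionSchedule, make_schedule
from .stack import FrameStack

log = logging.getLogger(__name__)

# Codes in the integer label map.
LABEL_AGAR = 0
LABEL_LIGHT = 1
LABEL_DARK = 2
LABEL_NAMES = {LABEL_AGAR: "agar", LABEL_LIGHT: LIGHT, LABEL_DARK: DARK}


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs; defaults are the standard six-day cycling scenario.

    image_size : (H, W) pixels.
    center : (row, col) of the inoculation point; defaults to the image middle.
    radial_speed : colony expansion speed, px/h.
    frame_interval_h : time between frames (0.5 h = one frame every 30 min).
    agar_mean, agar_sd : background intensity and its Gaussian noise SD.
    amp_light, amp_dark : saturating amplitude of reduced-TTC signal for
        biomass born in light vs dark intervals (amp_dark >= amp_light).
    tau_h : accumulation time constant, hours.
    noise_sd : per-pixel per-frame Gaussian noise inside the colony.
    seed : single integer controlling all randomness.
    """

    image_size: tuple[int, int] = (881, 881)
    center: tuple[float, float] | None = None
    radial_speed: float = 3.0
    frame_interval_h: float = 0.5
    agar_mean: float = 20.0
    agar_sd: float = 1.0
    amp_light: float = 50.0
    amp_dark: float = 100.0
    tau_h: float = 5.0
    noise_sd: float = 5.0
    seed: int = 0

    # Defaults place the colony at ~10 um/px stereomicroscope scale: the edge
    # advances 1.5 px per 30-min frame, so birth times are frame-resolved.

    def __post_init__(self) -> None:
        if self.radial_speed <= 0:
            raise ValueError(f"radial_speed must be positive, got {self.radial_speed}")
        if self.tau_h <= 0:
            raise ValueError(f"tau_h must be positive, got {self.tau_h}")
        if self.frame_interval_h <= 0:
            raise ValueError(f"frame_interval_h must be positive, got {self.frame_interval_h}")
        if not 0 <= self.amp_light <= self.amp_dark:
            raise ValueError(
                f"need 0 <= amp_light <= amp_dark, got {self.amp_light}, {self.amp_dark}"
            )
        if self.noise_sd < 0 or self.agar_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.image_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated movie.

    true_birth_map holds the geometric birth time distance/speed in hours
    (NaN on pixels the colony never reaches); true_label_map holds the
    schedule condition at birth as integer codes (0 agar, 1 light, 2 dark).
    """

    true_birth_map: np.ndarray
    true_label_map: np.ndarray
    params: SimulationParams
    schedule: ConditionSchedule


def intensity_kinetics(t, t_birth, amplitude, tau_h):
    """Saturating signal accumulation after birth; 0 before birth.

    Vectorized over any broadcastable combination of arguments.
    """
    if np.any(np.asarray(tau_h) <= 0):
        raise ValueError("tau_h must be positive")
    age = np.asarray(t, dtype=np.float64) - np.asarray(t_birth, dtype=np.float64)
    out = amplitude * -np.expm1(-np.maximum(age, 0.0) / tau_h)
    return out if out.ndim else float(out)


def simulate_movie(
    params: SimulationParams, schedule: ConditionSchedule
) -> tuple[FrameStack, SyntheticTruth]:
    """Render a colony time-lapse movie plus its ground truth.

    Frames are taken at t = 0, dt, ..., up to (but excluding) total_h, so a
    144-h experiment at 0.5-h frames yields 288 frames. The colony radius at
    the final frame must fit inside the image.
    """
    h, w = params.image_size
    cy, cx = params.resolved_center()
    timestamps = np.arange(0.0, schedule.total_h - 1e-9, params.frame_interval_h)
    final_radius = params.radial_speed * timestamps[-1]
    margin = min(cy, cx, (h - 1) - cy, (w - 1) - cx)
    if final_radius > margin:
        raise ValueError(
            f"colony radius at final frame ({final_radius:.1f} px) exceeds the "
            f"distance from center to the nearest image edge ({margin:.1f} px); "
            "enlarge image_size or slow radial_speed"
        )

    yy, xx = np.indices((h, w))
    dist = np.hypot(yy - cy, xx - cx)
    birth = dist / params.radial_speed
    reached = birth <= timestamps[-1]

    true_birth = np.where(reached, birth, np.nan)
    # Interval containing each birth time, via searchsorted on interval starts.
    starts = np.array([iv.start_h for iv in schedule.intervals])
    is_light_iv = np.array([iv.light for iv in schedule.intervals])
    idx = np.clip(np.searchsorted(starts, birth, side="right") - 1, 0, len(starts) - 1)
    born_light = is_light_iv[idx]
    labels = np.where(
        reached, np.where(born_light, LABEL_LIGHT, LABEL_DARK), LABEL_AGAR
    ).astype(np.uint8)
    amp = np.where(born_light, params.amp_light, params.amp_dark) * reached

    rng = np.random.default_rng(params.seed)
    frames = np.empty((len(timestamps), h, w), dtype=np.float32)
    for i, t in enumerate(timestamps):
        inside = birth <= t
        signal = np.where(
            inside, amp * -np.expm1(-np.maximum(t - birth, 0.0) / params.tau_h), 0.0
        )
        noise_sd = np.where(inside, params.noise_sd, params.agar_sd)
        noise = rng.standard_normal((h, w)) * noise_sd if noise_sd.any() else 0.0
        frames[i] = params.agar_mean + signal + noise

    stack = FrameStack(frames, timestamps, channel_transform_id="identity")
    truth = SyntheticTruth(true_birth, labels, params, schedule)
    return stack, truth


# ---------------------------------------------------------------------------
# Named scenarios: the study conditions used throughout tests and analyses.

def standard_scenario(seed: int = 0, noise_sd: float | None = None):
    """Six days of 12 h light / 12 h dark cycling with 2 degC temperature swing.

    amp_dark = 2 * amp_light; noise_sd defaults to 5% of amp_dark.
    """
    params = SimulationParams(seed=seed, **({} if noise_sd is None else {"noise_sd": noise_sd}))
    schedule = make_schedule(24.0, 0.5, 144.0, temp_light=25.0, temp_dark=23.0)
    return params, schedule


def short_cycle_scenario(seed: int = 0):
    """Shortened cycle: 6 h light / 6 h dark (12-h period) over six days."""
    params = SimulationParams(seed=seed)
    schedule = make_schedule(12.0, 0.5, 144.0, temp_light=25.0, temp_dark=23.0)
    return params, schedule


def long_cycle_scenario(seed: int = 0):
    """Prolonged cycle: 24 h light / 24 h dark (48-h period) over 312 h.

    Rendered at lower magnification (1 px/h) so the much larger final
    colony still fits a practical frame.
    """
    params = SimulationParams(image_size=(645, 645), radial_speed=1.0, seed=seed)
    schedule = make_schedule(48.0, 0.5, 312.0, temp_light=25.0, temp_dark=23.0)
    return params, schedule


def light_only_scenario(seed: int = 0):
    """Light cycling without the temperature swing: half the amplitude contrast.

    Constant 25 degC; amp_dark - amp_light = 25 instead of the standard 50.
    """
    params = SimulationParams(amp_dark=75.0, seed=seed)
    schedule = make_schedule(24.0, 0.5, 144.0, temp_light=25.0, temp_dark=25.0)
    return params, schedule


# ---------------------------------------------------------------------------
# On-disk formats for ground truth.

def write_truth_csv(truth: SyntheticTruth, path) -> None:
    """Long-format CSV of colony pixels: row, col, birth_h, label."""
    rr, cc = np.nonzero(truth.true_label_map != LABEL_AGAR)
    pd.DataFrame(
        {
            "row": rr,
            "col": cc,
            "birth_h": truth.true_birth_map[rr, cc],
            "label": [LABEL_NAMES[k] for k in truth.true_label_map[rr, cc]],
        }
    ).to_csv(path, index=False)


def write_params_txt(params: SimulationParams, path) -> None:
    """Key=value text dump of the simulation parameters."""
    with open(path, "w") as fh:
        for key, value in asdict(params).items():
            fh.write(f"{key}={value}\n")
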