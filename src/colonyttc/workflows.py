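"""High-level workflows composing simulation, segmentation, and rhythm steps.

These are the entry points the analysis drivers and the reproduction
script call: each one runs the complete pipeline on a named synthetic
scenario and returns the scientific quantity of interest.
"""

from __future__ import annotations

import logging

import numpy as np

from . import boundary, rhythm, rings
from .schedule import ConditionSchedule, make_schedule
from .stack import FrameStack
from .synthetic import SimulationParams, simulate_movie

log = logging.getLogger(__name__)


def lagged_edge_rhythm(
    stack: FrameStack, birth_map: boundary.BirthTimeMap, lag_h: float = 12.0
):
    """Lagged edge trace plus its trim/detrend/period summary."""
    edge = rings.edge_trace_lagged(stack, birth_map, lag_h)
    if len(edge) < 5:
        raise ValueError("lagged edge trace too short for rhythm analysis")
    result = rhythm.analyze_series(
        edge["birth_h"].to_numpy(), edge["mean_intensity"].to_numpy()
    )
    return edge, result


def recover_forcing_period(
    interval_h: float,
    total_h: float,
    seed: int = 0,
    lag_h: float = 12.0,
    radial_speed: float = 3.0,
) -> float | None:
    """Recover the light/dark forcing period from a synthetic movie.

    Simulates a colony movie under alternating light/dark intervals of
    ``interval_h`` hours (so the forcing period is ``2 * interval_h``),
    segments it with the 3-SD threshold pipeline, builds the 12-h lagged
    edge trace, trims and detrends it, and returns the dominant period in
    hours (None if no significant periodicity is found). The frame is
    sized to just fit the final colony with margin; pass a smaller
    ``radial_speed`` (lower magnification) for long experiments.
    """
    radius = radial_speed * (total_h - 0.5)
    half = int(np.ceil(radius)) + 10
    image_size = (2 * half + 1, 2 * half + 1)
    params = SimulationParams(image_size=image_size, radial_speed=radial_speed, seed=seed)
    schedule = make_schedule(
        2 * interval_h, 0.5, total_h, temp_light=25.0, temp_dark=23.0
    )
    stack, _ = simulate_movie(params, schedule)
    birth_map, _ = boundary.segment_movie(stack)
    _, result = lagged_edge_rhythm(stack, birth_map, lag_h)
    log.info(
        "interval %.1f h: recovered period %s h (amplitude %.2f)",
        interval_h, result.period_h, result.amplitude,
    )
    return result.period_h


def classification_accuracy(
    params: SimulationParams,
    schedule: ConditionSchedule,
    exclude_within_h: float = 0.0,
) -> float:
    """Pixelwise light/dark recovery accuracy on a synthetic movie.

    Runs the full segmentation pipeline, labels every colonized pixel by
    the schedule condition at its measured birth time, and compares with
    the generator's ground-truth labels. Pixels whose true birth falls
    within ``exclude_within_h`` of a schedule interval boundary are
    excluded (their detection-time jitter makes the label genuinely
    ambiguous).
    """
    stack, truth = simulate_movie(params, schedule)
    birth_map, _ = boundary.segment_movie(stack)
    predicted = rings.classify_birth_map(birth_map, schedule)

    true_labels = truth.true_label_map
    evaluable = (true_labels != 0) & (predicted != 0)
    if exclude_within_h > 0:
        edges = np.array([iv.start_h for iv in schedule.intervals][1:])
        births = truth.true_birth_map
        dist_to_edge = np.min(
            np.abs(births[..., None] - edges[None, None, :]), axis=-1
        )
        evaluable &= ~(dist_to_edge < exclude_within_h)
    if evaluable.sum() == 0:
        raise ValueError("no evaluable pixels")
    return float((predicted[evaluable] == true_labels[evaluable]).mean())
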