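"""Cohorts, traces, lagged edge series, rates, profiles, kymographs."""

import numpy as np
import pandas as pd
import pytest

from colonyttc.boundary import BirthTimeMap, segment_movie
from colonyttc.rings import (
    RingCohort,
    classify_birth_map,
    classify_cohort,
    cohort_pixels,
    cohort_trace,
    edge_trace_lagged,
    interval_cohorts,
    kymograph,
    make_cohorts,
    radial_profile,
    reduction_rate,
)
from colonyttc.schedule import make_schedule
from colonyttc.stack import FrameStack
from colonyttc.synthetic import SimulationParams, simulate_movie


def _birth_map(grid, threshold=5.0):
    return BirthTimeMap(np.asarray(grid, dtype=float), threshold, (0.0, 0.0))


class TestCohortPixels:
    def test_half_open_window(self):
        bm = _birth_map([[1.0, 1.5, 2.0]])
        rows, cols = cohort_pixels(bm, (1.0, 2.0))
        assert set(zip(rows, cols)) == {(0, 0), (0, 1)}

    def test_window_covering_everything(self):
        bm = _birth_map([[1.0, np.nan], [0.0, 3.0]])
        rows, cols = cohort_pixels(bm, (0.0, 10.0))
        assert len(rows) == 3  # sentinel pixel excluded

    def test_bad_window_rejected(self):
        bm = _birth_map([[1.0]])
        with pytest.raises(ValueError, match="t0 < t1"):
            cohort_pixels(bm, (2.0, 2.0))

    def test_cohorts_partition_colonized_pixels(self, tiny_noise_free):
        _, _, stack, _ = tiny_noise_free
        bm, _ = segment_movie(stack)
        cohorts = make_cohorts(bm, 0.5)
        total = sum(c.n_pixels for c in cohorts)
        assert total == int(bm.colonized.sum())
        seen = set()
        for c in cohorts:
            pix = set(zip(c.pixel_rows.tolist(), c.pixel_cols.tolist()))
            assert not (pix & seen), "no pixel may fall in two cohorts"
            seen |= pix

    def test_cohort_sets_are_annuli_of_expected_width(self, tiny_noise_free):
        params, _, _, truth = tiny_noise_free
        bm = BirthTimeMap(truth.true_birth_map, 0.0, params.resolved_center())
        rows, cols = cohort_pixels(bm, (6.0, 12.0))  # one 6-h interval
        cy, cx = params.resolved_center()
        dist = np.hypot(rows - cy, cols - cx)
        width = dist.max() - dist.min()
        assert width == pytest.approx(params.radial_speed * 6.0, abs=1.5)


class TestCohortTrace:
    def test_single_pixel_cohort_equals_pixel_series(self, tiny_noisy):
        _, _, stack, _ = tiny_noisy
        cohort = RingCohort((0.0, 0.5), np.array([117]), np.array([117]))
        trace = cohort_trace(stack, cohort)
        assert np.allclose(trace.mean_intensity, stack.frames[:, 117, 117])
        assert trace.time_since_birth_h[0] == 0.0

    def test_mean_consistency_with_per_pixel_series(self, tiny_noisy):
        _, _, stack, _ = tiny_noisy
        rows = np.array([100, 101, 102, 117])
        cols = np.array([117, 117, 118, 100])
        cohort = RingCohort((2.0, 2.5), rows, cols)
        trace = cohort_trace(stack, cohort)
        start = np.searchsorted(stack.timestamps_h, 2.0)
        manual = np.mean(
            [stack.frames[start:, r, c] for r, c in zip(rows, cols)], axis=0
        )
        assert np.allclose(trace.mean_intensity, manual, rtol=1e-9)

    def test_noise_free_trace_nondecreasing(self, tiny_noise_free):
        _, schedule, stack, truth = tiny_noise_free
        bm = BirthTimeMap(truth.true_birth_map, 0.0, (117.0, 117.0))
        for cohort in interval_cohorts(bm, schedule)[:3]:
            trace = cohort_trace(stack, cohort)
            assert np.all(np.diff(trace.mean_intensity) >= -1e-3)

    def test_dark_cohorts_end_higher_than_light(self, tiny_noise_free):
        """Rings formed in the dark accumulate more signal (entrenched amplitude).

        The youngest ring is still in its rapid accumulation phase at the
        end of this short movie, so it is excluded; the six-day acceptance
        scenario includes every cohort.
        """
        _, schedule, stack, truth = tiny_noise_free
        bm = BirthTimeMap(truth.true_birth_map, 0.0, (117.0, 117.0))
        finals = {}
        for cohort in interval_cohorts(bm, schedule)[:-1]:
            finals.setdefault(cohort.label, []).append(
                cohort_trace(stack, cohort).final_value
            )
        assert min(finals["dark"]) > max(finals["light"])

    def test_pixels_outside_image_rejected(self, tiny_noisy):
        _, _, stack, _ = tiny_noisy
        cohort = RingCohort((0.0, 1.0), np.array([0]), np.array([999]))
        with pytest.raises(ValueError, match="outside"):
            cohort_trace(stack, cohort)


class TestEdgeTraceLagged:
    def test_zero_lag_reads_near_threshold(self, tiny_noise_free):
        _, _, stack, _ = tiny_noise_free
        bm, _ = segment_movie(stack)
        trace = edge_trace_lagged(stack, bm, lag_h=0.0)
        # at detection each pixel has just reached the threshold
        mid = trace.iloc[2:-2]
        assert np.all(mid["mean_intensity"] >= bm.threshold - 0.5)
        # one frame of dark-ring growth above threshold at most
        assert np.all(mid["mean_intensity"] <= bm.threshold + 13.0)

    def test_alternates_with_forcing_period(self, tiny_noise_free):
        """12-h lag readout alternates high (dark-born) / low (light-born)."""
        _, schedule, stack, truth = tiny_noise_free
        bm = BirthTimeMap(truth.true_birth_map, 0.0, (117.0, 117.0))
        # quantize truth births to the frame grid for cohort grouping
        q = np.round(truth.true_birth_map * 2) / 2
        bm = BirthTimeMap(q, 0.0, (117.0, 117.0))
        trace = edge_trace_lagged(stack, bm, lag_h=12.0)
        labels = np.array(
            [schedule.label_at(t) for t in trace["birth_h"]]
        )
        dark_mean = trace["mean_intensity"][labels == "dark"].mean()
        light_mean = trace["mean_intensity"][labels == "light"].mean()
        assert dark_mean > light_mean + 20

    def test_lag_beyond_movie_end_yields_empty(self, tiny_noisy):
        _, _, stack, _ = tiny_noisy
        bm = _birth_map(np.full((235, 235), 30.0))
        trace = edge_trace_lagged(stack, bm, lag_h=100.0)
        assert trace.empty

    def test_negative_lag_rejected(self, tiny_noisy):
        _, _, stack, _ = tiny_noisy
        with pytest.raises(ValueError, match="lag"):
            edge_trace_lagged(stack, _birth_map(np.zeros((235, 235))), lag_h=-1)


class TestReductionRate:
    def _trace(self, t, y):
        from colonyttc.rings import CohortTrace

        return CohortTrace(t, y, birth_h=0.0)

    def test_linear_trace_constant_rate(self):
        t = np.arange(0, 10, 0.5)
        trace = self._trace(t, 3.0 * t + 2.0)
        rate = reduction_rate(trace, smooth_window_h=1.5)
        assert np.allclose(rate, 3.0)

    def test_constant_trace_zero_rate(self):
        t = np.arange(0, 5, 0.5)
        rate = reduction_rate(self._trace(t, np.full_like(t, 7.0)), 1.5)
        assert np.allclose(rate, 0.0)

    def test_saturating_trace_rate_positive_and_decreasing(self):
        t = np.arange(0, 30, 0.5)
        y = 100 * (1 - np.exp(-t / 5.0))
        rate = reduction_rate(self._trace(t, y), smooth_window_h=0)
        assert np.all(rate > 0)
        assert np.all(np.diff(rate[1:-1]) < 0)  # interior: strictly slowing

    def test_rate_of_cumsum_recovers_increments(self):
        rng = np.random.default_rng(3)
        inc = rng.uniform(0.5, 2.0, 40)
        t = np.arange(40) * 0.5
        y = np.cumsum(inc)
        rate = reduction_rate(self._trace(t, y), smooth_window_h=0)
        # centered differences average adjacent increments
        expected = (inc[2:] + inc[1:-1]) / (2 * 0.5)
        assert np.allclose(rate[1:-1], expected)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            reduction_rate(self._trace(np.array([0.0, 0.5]), np.array([1.0, 2.0])), 0)


class TestRadialProfile:
    def test_constant_image(self):
        profile = radial_profile(np.full((41, 41), 5.0), (20, 20), n_angles=8)
        assert np.allclose(profile.intensity, 5.0)

    def test_matches_generating_radial_function(self):
        h = w = 101
        yy, xx = np.indices((h, w))
        dist = np.hypot(yy - 50, xx - 50)
        img = 100.0 / (1.0 + dist / 10.0)
        profile = radial_profile(img, (50, 50), n_angles=32)
        expected = 100.0 / (1.0 + profile.distance_px / 10.0)
        assert np.max(np.abs(profile.intensity - expected)) < 2.0  # pixel rounding

    def test_alternating_annuli_repeat_with_cycle_width(self, tiny_noise_free):
        """Light-to-dark jumps in the final profile recur every cycle width.

        Moving outward, signal drops with age within a ring but jumps up
        where a dark-born annulus begins; those jumps are one forcing
        period of growth apart: radial_speed x 12 h = 36 px here.
        """
        params, _, stack, _ = tiny_noise_free
        cy, cx = params.resolved_center()
        profile = radial_profile(stack.final_frame, (cy, cx), n_angles=16)
        interior = profile.intensity[: int(params.radial_speed * 30)]
        jumps = np.nonzero(np.diff(interior) > 5.0)[0]
        spacing = np.diff(jumps)
        spacing = spacing[spacing > 2]  # merge adjacent samples of one jump
        assert np.allclose(spacing, params.radial_speed * 12.0, atol=4)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError, match="center"):
            radial_profile(np.zeros((10, 10)), (20, 5), n_angles=1)


class TestKymograph:
    def test_time_constant_stack_has_identical_columns(self):
        frame = np.random.default_rng(1).uniform(0, 9, (21, 21))
        stack = FrameStack(np.stack([frame] * 4), np.arange(4) * 0.5)
        k = kymograph(stack, (10, 10), angle=0.0)
        assert np.allclose(k.values, k.values[:, :1])

    def test_row_equals_pixel_series_exactly(self, tiny_noisy):
        _, _, stack, _ = tiny_noisy
        k = kymograph(stack, (117, 117), angle=0.0)
        r = 40
        assert np.array_equal(k.values[r], stack.frames[:, 117, 117 + r])

    def test_threshold_crossing_traces_growth_line(self, tiny_noise_free):
        params, _, stack, _ = tiny_noise_free
        bm, _ = segment_movie(stack)
        k = kymograph(stack, (117, 117), angle=0.0)
        first_cross = []
        for i, r in enumerate(k.radial_positions_px):
            above = k.values[i] >= bm.threshold
            if above.any():
                first_cross.append((r, k.timestamps_h[np.argmax(above)]))
        first_cross = np.asarray(first_cross)
        # time of first crossing grows linearly with radius at 1/radial_speed
        slope = np.polyfit(first_cross[5:, 0], first_cross[5:, 1], 1)[0]
        assert slope == pytest.approx(1.0 / params.radial_speed, rel=0.05)

    def test_max_radius_beyond_image_rejected(self, tiny_noisy):
        _, _, stack, _ = tiny_noisy
        with pytest.raises(ValueError, match="max_radius"):
            kymograph(stack, (117, 117), angle=0.0, max_radius_px=500)


class TestClassifyCohort:
    def test_examples(self):
        sched = make_schedule(24.0, 0.5, 144.0, 25.0, 23.0)
        assert classify_cohort(6.0, sched) == ("light", 25.0)
        assert classify_cohort(12.0, sched) == ("dark", 23.0)  # boundary -> later
        with pytest.raises(ValueError, match="outside"):
            classify_cohort(144.0, sched)

    def test_noise_free_pipeline_labels_match_truth(self, tiny_noise_free):
        """Away from interval boundaries, recovered labels are perfect.

        Distances are measured on the frame grid, where the generator
        quantizes pixel birth.
        """
        params, schedule, stack, truth = tiny_noise_free
        bm, _ = segment_movie(stack)
        predicted = classify_birth_map(bm, schedule)
        dt = params.frame_interval_h
        grid_birth = np.ceil(truth.true_birth_map / dt) * dt
        edges = np.array([iv.start_h for iv in schedule.intervals][1:])
        dist = np.min(np.abs(grid_birth[..., None] - edges[None, None, :]), axis=-1)
        sel = (truth.true_label_map != 0) & (predicted != 0) & (dist > dt)
        assert np.all(predicted[sel] == truth.true_label_map[sel])

    def test_final_value_cohort_classification_under_noise(self):
        """Interval-cohort final values separate light from dark at 10% noise.

        Six days of 12 h / 12 h cycling (rendered at 1 px/h magnification
        to keep the frame small); a single intensity cut on the final
        values must classify >= 95% of the ring cohorts correctly.
        """
        params = SimulationParams(
            image_size=(311, 311), radial_speed=1.0, noise_sd=10.0, seed=21
        )
        schedule = make_schedule(24.0, 0.5, 144.0, 25.0, 23.0)
        stack, truth = simulate_movie(params, schedule)
        bm, _ = segment_movie(stack)
        cohorts = interval_cohorts(bm, schedule)
        values = np.array([cohort_trace(stack, c).final_value for c in cohorts])
        labels = np.array([c.label for c in cohorts])
        best = 0.0
        for cut in np.sort(values):  # best single-threshold classifier
            acc = np.mean(np.where(values >= cut, "dark", "light") == labels)
            best = max(best, acc)
        assert best >= 0.95
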