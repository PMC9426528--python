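"""End-to-end pipeline runs: simulate and analyze, with manifests.

Everything written to disk is plain text or standard image formats
(CSV / TIFF / PNG); each run ends by writing ``manifest.csv`` listing every
artifact with its SHA-256 checksum so reruns can be compared file by file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boundary, rings, rhythm
from .schedule import ConditionSchedule, schedule_from_csv, schedule_to_csv
from .stack import FrameStack, read_movie, write_movie_tiff
from .synthetic import (
    SimulationParams,
    simulate_movie,
    write_params_txt,
    write_truth_csv,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis settings; the defaults reproduce the standard movie protocol.

    k_sd = 3 (boundary rule), lag_h = 12 (lagged edge trace), cohort
    windows of one frame interval, 3-frame rate smoothing at 0.5-h frames.
    """

    input_path: str | Path | None = None
    schedule_path: str | Path | None = None
    out_dir: str | Path = "results"
    channel_transform_id: str = "identity"
    center: tuple[float, float] | None = None
    k_sd: float = 3.0
    lag_h: float = 12.0
    n_boundary_angles: int = 64
    cohort_window_h: float | None = None  # None: one frame interval
    smooth_window_h: float = 1.5
    kymo_angle_rad: float = 0.0
    radial_n_angles: int = 1
    frame_interval_h: float = 0.5  # fallback timing for movies without timestamps
    seed: int = 0

    @classmethod
    def from_key_value_file(cls, path) -> "RunConfig":
        """Parse a simple ``key=value`` text config (one pair per line)."""
        fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = _parse_value(raw.strip())
        return cls(**kwargs)


def _parse_value(raw: str):
    if raw.lower() in ("none", ""):
        return None
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    if "," in raw:
        return tuple(_parse_value(p.strip()) for p in raw.split(","))
    try:
        f = float(raw)
        return int(f) if f.is_integer() and "." not in raw and "e" not in raw.lower() else f
    except ValueError:
        return raw


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, files: list[Path]) -> Path:
    rows = [
        {"filename": str(p.relative_to(out_dir)), "sha256": _sha256(p)} for p in files
    ]
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def run_simulate(
    params: SimulationParams,
    schedule: ConditionSchedule,
    out_dir,
    write_png: bool = False,
) -> dict:
    """Simulate a movie and write it plus its ground truth under ``out_dir``."""
    out_dir = Path(out_dir)
    if not out_dir.exists():
        log.info("creating output directory %s", out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, truth = simulate_movie(params, schedule)

    files = []
    movie_path = out_dir / "movie.tiff"
    write_movie_tiff(stack, movie_path)
    files.append(movie_path)
    if write_png:
        from .stack import write_movie_png_dir

        write_movie_png_dir(stack, out_dir / "frames")
        files.extend(sorted((out_dir / "frames").iterdir()))
    truth_path = out_dir / "truth.csv"
    write_truth_csv(truth, truth_path)
    files.append(truth_path)
    params_path = out_dir / "params.txt"
    write_params_txt(params, params_path)
    files.append(params_path)
    schedule_path = out_dir / "schedule.csv"
    schedule_to_csv(schedule, schedule_path)
    files.append(schedule_path)
    write_manifest(out_dir, files)
    return {"stack": stack, "truth": truth, "out_dir": out_dir}


def run_analyze(config: RunConfig, stack: FrameStack | None = None,
                schedule: ConditionSchedule | None = None) -> dict:
    """Full analysis: segmentation, cohorts, traces, profiles, rhythm summary.

    Either pass the stack/schedule in memory or point ``config`` at files.
    Writes every artifact as CSV/TIFF under ``config.out_dir`` plus a
    checksum manifest, and returns the in-memory results.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stack is None:
        if config.input_path is None:
            raise ValueError("run_analyze needs a stack or config.input_path")
        kwargs = (
            {"frame_interval_h": config.frame_interval_h}
            if not Path(config.input_path).is_dir()
            else {}
        )
        stack = read_movie(config.input_path, **kwargs)
    if schedule is None and config.schedule_path is not None:
        schedule = schedule_from_csv(config.schedule_path)

    birth_map, agar_stats = boundary.segment_movie(
        stack,
        center=config.center,
        k=config.k_sd,
        n_angles=config.n_boundary_angles,
    )
    files = []
    birth_csv = out_dir / "birth_map.csv"
    boundary.write_birth_map_csv(birth_map, birth_csv)
    files.append(birth_csv)
    birth_tiff = out_dir / "birth_map.tiff"
    boundary.write_birth_map_tiff(birth_map, birth_tiff)
    files.append(birth_tiff)

    # Cohort traces: per-frame cohorts by default, plus one per schedule interval.
    dt = float(np.median(np.diff(stack.timestamps_h)))
    window = config.cohort_window_h if config.cohort_window_h else dt
    cohorts = rings.make_cohorts(birth_map, window, schedule)
    traces = [rings.cohort_trace(stack, c) for c in cohorts]
    for tr in traces:
        if len(tr.mean_intensity) >= 3:
            rings.reduction_rate(tr, config.smooth_window_h)
    traces_csv = out_dir / "cohort_traces.csv"
    rings.cohort_traces_to_frame(traces).to_csv(traces_csv, index=False)
    files.append(traces_csv)

    interval_traces = []
    if schedule is not None:
        interval_traces = [
            rings.cohort_trace(stack, c)
            for c in rings.interval_cohorts(birth_map, schedule)
        ]
        for tr in interval_traces:
            if len(tr.mean_intensity) >= 3:
                rings.reduction_rate(tr, config.smooth_window_h)
        iv_csv = out_dir / "interval_cohort_traces.csv"
        rings.cohort_traces_to_frame(interval_traces).to_csv(iv_csv, index=False)
        files.append(iv_csv)

    edge = rings.edge_trace_lagged(stack, birth_map, config.lag_h)
    edge_csv = out_dir / "edge_trace_lagged.csv"
    edge.to_csv(edge_csv, index=False)
    files.append(edge_csv)

    profile = rings.radial_profile(
        stack.final_frame, birth_map.center, n_angles=config.radial_n_angles
    )
    profile_csv = out_dir / "radial_profile.csv"
    rings.radial_profile_to_frame(profile).to_csv(profile_csv, index=False)
    files.append(profile_csv)

    kymo = rings.kymograph(stack, birth_map.center, config.kymo_angle_rad)
    kymo_csv = out_dir / "kymograph.csv"
    rings.kymograph_to_frame(kymo).to_csv(kymo_csv, index=False)
    files.append(kymo_csv)

    rhythm_result = None
    if len(edge) >= 5:
        try:
            rhythm_result = rhythm.analyze_series(
                edge["birth_h"].to_numpy(), edge["mean_intensity"].to_numpy()
            )
        except ValueError as exc:
            log.warning("rhythm analysis skipped: %s", exc)
        else:
            rhythm_path = out_dir / "rhythm_summary.json"
            rhythm_path.write_text(json.dumps(rhythm_result.summary(), indent=1))
            files.append(rhythm_path)

    write_manifest(out_dir, files)
    log.info("analysis complete: %d artifacts in %s", len(files), out_dir)
    return {
        "birth_map": birth_map,
        "agar_stats": agar_stats,
        "cohorts": cohorts,
        "traces": traces,
        "interval_traces": interval_traces,
        "edge_trace": edge,
        "radial_profile": profile,
        "kymograph": kymo,
        "rhythm": rhythm_result,
        "out_dir": out_dir,
    }
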