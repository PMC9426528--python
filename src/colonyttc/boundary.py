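"""Agar statistics, 3-SD boundary detection, and per-pixel birth times.

The segmentation follows the thresholding scheme used for colony time-lapse
movies: the final frame gives the background statistics of the agar area;
rays scanned from the agar toward the colony locate the agar/colony
boundary as the first pixel deviating from the agar mean by more than
``k`` standard deviations (k = 3); the intensity at that boundary in the
final frame becomes the threshold applied to every frame; and each pixel's
birth time is the timestamp of the first frame in which it reached the
threshold.

The deviation test is two-sided (absolute deviation) by default — whether
the original rule was one-sided is not documented, so the direction is a
parameter rather than an assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .stack import FrameStack

log = logging.getLogger(__name__)

NEVER = np.nan  # sentinel birth time for pixels that never cross the threshold


class NoBoundaryFoundError(RuntimeError):
    """No pixel along the scanned ray left the agar intensity band."""


@dataclass(frozen=True)
class AgarStats:
    """Background intensity statistics over a stated agar region."""

    mean: float
    sd: float
    n_pixels: int
    region_descriptor: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_pixels < 2:
            raise ValueError("agar statistics need at least 2 pixels")


@dataclass
class BirthTimeMap:
    """Per-pixel time of first threshold crossing (NaN = never)."""

    birth_h: np.ndarray
    threshold: float
    center: tuple[float, float]

    @property
    def colonized(self) -> np.ndarray:
        """Boolean mask of pixels that crossed the threshold at some frame."""
        return ~np.isnan(self.birth_h)


def compute_agar_stats(frame: np.ndarray, agar_region) -> AgarStats:
    """Mean and population SD of intensity over the agar region.

    ``agar_region`` is either a boolean mask of the frame or an (N, 2)
    array of (row, col) coordinates. The population convention (divide by
    n) is used for the SD.
    """
    frame = np.asarray(frame, dtype=np.float64)
    region = np.asarray(agar_region)
    if region.dtype == bool:
        if region.shape != frame.shape:
            raise ValueError("boolean agar mask must match the frame shape")
        values = frame[region]
        descriptor = f"mask of {int(region.sum())} px"
    else:
        coords = region.reshape(-1, 2)
        if (
            (coords < 0).any()
            or (coords[:, 0] >= frame.shape[0]).any()
            or (coords[:, 1] >= frame.shape[1]).any()
        ):
            raise ValueError("agar region contains out-of-bounds coordinates")
        values = frame[coords[:, 0], coords[:, 1]]
        descriptor = f"{len(coords)} listed px"
    if values.size < 2:
        raise ValueError("agar region must contain at least 2 pixels")
    return AgarStats(
        mean=float(values.mean()),
        sd=float(values.std()),  # population (ddof=0)
        n_pixels=int(values.size),
        region_descriptor=descriptor,
    )


def _ray_radii_and_pixels(
    frame_shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    max_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer radii along a ray and their nearest-pixel coordinates."""
    cy, cx = center
    dy, dx = np.sin(angle), np.cos(angle)
    if max_radius is None:
        # Largest radius staying inside the image along this ray.
        h, w = frame_shape
        r = 0
        while True:
            row = int(round(cy + (r + 1) * dy))
            col = int(round(cx + (r + 1) * dx))
            if not (0 <= row < h and 0 <= col < w):
                break
            r += 1
        max_radius = r
    radii = np.arange(int(max_radius) + 1)
    rows = np.rint(cy + radii * dy).astype(int)
    cols = np.rint(cx + radii * dx).astype(int)
    return radii, rows, cols


def scan_boundary(
    frame: np.ndarray,
    center: tuple[float, float],
    angle: float,
    stats: AgarStats,
    k: float = 3.0,
    two_sided: bool = True,
    max_radius: float | None = None,
) -> int:
    """Radius of the agar/colony boundary along one ray.

    Scans inward from the agar side (largest radius first) and returns the
    radius of the first pixel whose intensity deviates from ``stats.mean``
    by more than ``k * stats.sd`` (absolute deviation if ``two_sided``,
    else positive excess only).

    Raises :class:`NoBoundaryFoundError` if no pixel leaves the band.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"center {center} lies outside the {frame.shape} frame")
    radii, rows, cols = _ray_radii_and_pixels(frame.shape, center, angle, max_radius)
    values = frame[rows, cols]
    dev = values - stats.mean
    exceeds = np.abs(dev) > k * stats.sd if two_sided else dev > k * stats.sd
    # Inward scan: check the outermost radius first.
    for i in range(len(radii) - 1, -1, -1):
        if exceeds[i]:
            return int(radii[i])
    raise NoBoundaryFoundError(
        f"no pixel along angle {angle:.3f} rad deviates by more than "
        f"{k} x {stats.sd:.4g} from the agar mean {stats.mean:.4g}"
    )


def determine_threshold(final_frame: np.ndarray, boundary_pixels) -> float:
    """Scalar threshold: median final-frame intensity of the boundary pixels."""
    final_frame = np.asarray(final_frame, dtype=np.float64)
    coords = np.asarray(boundary_pixels).reshape(-1, 2)
    if coords.size == 0:
        raise ValueError("boundary pixel set is empty")
    return float(np.median(final_frame[coords[:, 0], coords[:, 1]]))


def compute_birth_times(
    stack: FrameStack, threshold: float, center: tuple[float, float] | None = None
) -> BirthTimeMap:
    """Timestamp of the first frame in which each pixel reached ``threshold``.

    First crossing is final: pixels that later drop below the threshold keep
    their original birth time. Pixels that never reach it get NaN.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    if stack.n_frames == 0:
        raise ValueError("frame stack is empty")
    above = stack.frames >= threshold  # (T, H, W)
    ever = above.any(axis=0)
    first = above.argmax(axis=0)
    birth = np.where(ever, stack.timestamps_h[first], NEVER)
    if center is None:
        center = mask_centroid(ever)
    return BirthTimeMap(birth_h=birth, threshold=float(threshold), center=center)


def estimate_agar_region(
    final_frame: np.ndarray,
    dilate_px: int | None = None,
    border_frac: float = 0.02,
) -> np.ndarray:
    """Approximate agar mask of the final frame.

    A first guess at the background comes from the image border (which
    must be agar, since the colony has to fit inside the frame); pixels
    deviating from the border statistics by more than 3 SD are called
    colony. The colony mask is then dilated so that the dim rising ramp
    at the colony edge does not contaminate the background statistics:
    with ``dilate_px=None`` the dilation grows adaptively until the agar
    SD stops shrinking (the ramp has been excluded); pass an integer for
    a fixed dilation.
    """
    final_frame = np.asarray(final_frame, dtype=np.float64)
    h, w = final_frame.shape
    m = max(3, int(round(border_frac * min(h, w))))
    border = np.zeros((h, w), dtype=bool)
    border[:m], border[-m:], border[:, :m], border[:, -m:] = True, True, True, True
    b_mean = final_frame[border].mean()
    b_sd = final_frame[border].std()
    if b_sd > 0:
        colony = np.abs(final_frame - b_mean) > 3 * b_sd
    else:
        colony = final_frame != b_mean
    colony = ndimage.binary_fill_holes(colony)
    if dilate_px is not None:
        if dilate_px > 0:
            colony = ndimage.binary_dilation(colony, iterations=dilate_px)
        agar = ~colony
    else:
        agar = ~colony
        sd = final_frame[agar].std()
        if sd == 0:
            return agar  # already a perfectly uniform background
        for _ in range(50):
            grown = ndimage.binary_dilation(colony, iterations=2)
            candidate = ~grown
            if candidate.sum() < max(100, 0.05 * final_frame.size):
                break
            new_sd = final_frame[candidate].std()
            colony, agar = grown, candidate
            if new_sd > 0.98 * sd:  # no longer improving: ramp excluded
                sd = new_sd
                break
            sd = new_sd
    if agar.sum() < 2:
        raise ValueError("agar region estimate is degenerate (colony fills the frame)")
    return agar


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """(row, col) centroid of a boolean mask."""
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    return float(rr.mean()), float(cc.mean())


def detect_boundary_and_threshold(
    final_frame: np.ndarray,
    center: tuple[float, float],
    stats: AgarStats,
    k: float = 3.0,
    n_angles: int = 64,
    two_sided: bool = True,
) -> tuple[np.ndarray, float]:
    """Boundary pixels over ``n_angles`` rays plus the resulting threshold.

    Rays along which no boundary is found are skipped with a log message;
    if every ray fails, :class:`NoBoundaryFoundError` propagates.
    """
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    cy, cx = center
    pixels = []
    failures = 0
    for angle in angles:
        try:
            radius = scan_boundary(final_frame, center, angle, stats, k=k, two_sided=two_sided)
        except NoBoundaryFoundError:
            failures += 1
            continue
        row = int(round(cy + radius * np.sin(angle)))
        col = int(round(cx + radius * np.cos(angle)))
        pixels.append((row, col))
    if failures:
        log.warning("no boundary found along %d of %d rays", failures, len(angles))
    if not pixels:
        raise NoBoundaryFoundError(
            f"no boundary found along any of {len(angles)} rays (k={k})"
        )
    boundary = np.asarray(pixels)
    return boundary, determine_threshold(final_frame, boundary)


def segment_movie(
    stack: FrameStack,
    center: tuple[float, float] | None = None,
    k: float = 3.0,
    n_angles: int = 64,
    agar_region: np.ndarray | None = None,
    two_sided: bool = True,
) -> tuple[BirthTimeMap, AgarStats]:
    """Full segmentation: agar stats -> boundary -> threshold -> birth times.

    The center defaults to the centroid of the final frame's above-Otsu
    mask; the agar region defaults to the Otsu-based estimate.
    """
    final = stack.final_frame
    if agar_region is None:
        agar_region = estimate_agar_region(final)
    stats = compute_agar_stats(final, agar_region)
    if (~agar_region).sum() == 0:
        raise NoBoundaryFoundError(
            "frame contains no pixels distinguishable from the agar background"
        )
    if center is None:
        center = mask_centroid(~agar_region)
        log.info("using centroid center (%.1f, %.1f)", *center)
    _, threshold = detect_boundary_and_threshold(
        final, center, stats, k=k, n_angles=n_angles, two_sided=two_sided
    )
    log.info(
        "agar mean=%.3f sd=%.3f (n=%d); threshold=%.3f",
        stats.mean, stats.sd, stats.n_pixels, threshold,
    )
    birth = compute_birth_times(stack, threshold, center=center)
    return birth, stats


# ---------------------------------------------------------------------------
# On-disk formats.

def write_birth_map_csv(birth_map: BirthTimeMap, path) -> None:
    """CSV of (row, col, birth_h) for pixels that crossed the threshold."""
    rr, cc = np.nonzero(birth_map.colonized)
    pd.DataFrame(
        {"row": rr, "col": cc, "birth_h": birth_map.birth_h[rr, cc]}
    ).to_csv(path, index=False)


def write_birth_map_tiff(birth_map: BirthTimeMap, path) -> None:
    """Single-page float32 TIFF of birth hours (NaN where never colonized)."""
    tifffile.imwrite(Path(path), birth_map.birth_h.astype(np.float32))
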