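"""Frame stacks: the in-memory movie container and its file formats.

A movie is an ordered set of 2-D working-channel images with one timestamp
per frame. Raw RGB microscope frames are reduced to a single channel before
analysis: standard luminance grayscale by default, or a "redness" channel
(red minus the mean of green and blue) that isolates the red formazan
precipitate of reduced TTC in endpoint images.

On disk a stack is either a multi-page TIFF (float32, lossless) or a
directory of numbered PNGs plus an index CSV of (filename, time_h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def luminance(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an (..., 3) RGB image."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114


def redness(rgb: np.ndarray) -> np.ndarray:
    """Red channel minus the mean of green and blue; isolates red TTC signal."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return rgb[..., 0] - (rgb[..., 1] + rgb[..., 2]) / 2.0


def identity(gray: np.ndarray) -> np.ndarray:
    return np.asarray(gray, dtype=np.float64)


CHANNEL_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "luminance": luminance,
    "redness": redness,
    "identity": identity,
}


@dataclass
class FrameStack:
    """Ordered grayscale frames with strictly increasing timestamps (hours)."""

    frames: np.ndarray  # (T, H, W) float
    timestamps_h: np.ndarray  # (T,)
    channel_transform_id: str = "identity"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if len(self.timestamps_h) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.timestamps_h)} timestamps"
            )
        if len(self.timestamps_h) > 1 and not np.all(np.diff(self.timestamps_h) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.channel_transform_id not in CHANNEL_TRANSFORMS:
            raise ValueError(
                f"unknown channel transform {self.channel_transform_id!r}; "
                f"known: {sorted(CHANNEL_TRANSFORMS)}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def final_frame(self) -> np.ndarray:
        return self.frames[-1]

    def nearest_frame_index(self, t_h: float) -> int:
        """Index of the frame whose timestamp is nearest ``t_h`` (earlier wins ties)."""
        return int(np.argmin(np.abs(self.timestamps_h - t_h)))

    @classmethod
    def from_rgb(
        cls, rgb_frames: np.ndarray, timestamps_h, transform: str = "luminance"
    ) -> "FrameStack":
        fn = CHANNEL_TRANSFORMS[transform]
        frames = np.stack([fn(f) for f in np.asarray(rgb_frames)])
        return cls(frames, timestamps_h, channel_transform_id=transform)


def write_movie_tiff(stack: FrameStack, path) -> None:
    """Multi-page float32 TIFF; timestamps go in the image description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    desc = "timestamps_h=" + ",".join(f"{t:g}" for t in stack.timestamps_h)
    tifffile.imwrite(
        path, stack.frames.astype(np.float32), description=desc,
        photometric="minisblack",
    )


def read_movie_tiff(path, timestamps_h=None, frame_interval_h: float | None = None) -> FrameStack:
    """Read a multi-page TIFF movie.

    Timestamps are recovered, in order of preference, from the explicit
    ``timestamps_h`` argument, the TIFF description written by
    :func:`write_movie_tiff`, or a constant ``frame_interval_h``.
    """
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].description or ""
    if frames.ndim == 2:
        frames = frames[None]
    if timestamps_h is None and desc.startswith("timestamps_h="):
        timestamps_h = [float(x) for x in desc.removeprefix("timestamps_h=").split(",")]
    if timestamps_h is None:
        if frame_interval_h is None:
            raise ValueError("need timestamps_h or frame_interval_h to time the frames")
        timestamps_h = np.arange(len(frames)) * frame_interval_h
    return FrameStack(np.asarray(frames, dtype=np.float64), timestamps_h)


def write_movie_png_dir(stack: FrameStack, directory) -> None:
    """Numbered 16-bit PNGs plus an index CSV of (filename, time_h).

    PNG requires integers, so intensities are rounded to uint16; values
    outside [0, 65535] are clipped. Use TIFF for lossless storage.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (frame, t) in enumerate(zip(stack.frames, stack.timestamps_h)):
        name = f"frame_{i:04d}.png"
        img = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)
        iio.imwrite(directory / name, img)
        rows.append({"filename": name, "time_h": t})
    pd.DataFrame(rows).to_csv(directory / "index.csv", index=False)


def read_movie_png_dir(directory) -> FrameStack:
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv")
    frames = np.stack(
        [np.asarray(iio.imread(directory / name), dtype=np.float64) for name in index["filename"]]
    )
    if frames.ndim == 4:  # RGB PNGs: default to luminance
        return FrameStack.from_rgb(frames, index["time_h"].to_numpy(), "luminance")
    return FrameStack(frames, index["time_h"].to_numpy())


def read_movie(path, **kwargs) -> FrameStack:
    """Dispatch on path type: a directory of PNGs or a multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        return read_movie_png_dir(path)
    return read_movie_tiff(path, **kwargs)
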