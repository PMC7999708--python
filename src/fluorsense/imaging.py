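"""ROI quantification of 8-bit time-lapse fluorescence image stacks.

Replicates the by-hand Fiji measurement as code: load the ordered frames,
place a square region of interest (default 50 x 50 px) as close as possible
to the spot where the fluorometer and reflectometer read, and track the mean
(and sample standard deviation) pixel intensity over time.  Statistics are
computed in floating point; only the stored frames are 8-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "ROI",
    "read_stack",
    "write_stack",
    "roi_mean_intensity",
    "intensity_timecourse",
]

_INDEX_NAME = "frame_index.csv"


@dataclass(frozen=True)
class ImageStack:
    """Time-ordered grayscale frames on the 0-255 grey scale."""

    frames: np.ndarray  # (n_frames, rows, cols) uint8
    times: np.ndarray   # minutes per frame, strictly increasing

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, rows, cols), got {frames.ndim}-D")
        if frames.dtype != np.uint8:
            raise ValueError(f"frames must be 8-bit (uint8), got {frames.dtype}")
        if frames.shape[0] != times.size:
            raise ValueError(
                f"{frames.shape[0]} frames but {times.size} timestamps"
            )
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ROI:
    """Square/rectangular region: top-left (row0, col0), half-open extent."""

    row0: int
    col0: int
    height: int = 50
    width: int = 50

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"ROI origin ({self.row0}, {self.col0}) must be >= 0")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def check_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.row0 + self.height > rows or self.col0 + self.width > cols:
            raise ValueError(
                f"ROI rows [{self.row0}, {self.row0 + self.height}) x "
                f"cols [{self.col0}, {self.col0 + self.width}) exceeds "
                f"frame shape {shape}"
            )


def roi_mean_intensity(frame: np.ndarray, roi: ROI) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of the ROI pixel values."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D intensity array")
    roi.check_within(frame.shape)
    patch = frame[roi.slices()].astype(float)
    mean = float(patch.mean())
    std = float(patch.std(ddof=1)) if patch.size > 1 else 0.0
    return mean, std


def intensity_timecourse(stack: ImageStack, roi: ROI) -> pd.DataFrame:
    """Per-frame ROI statistics, in frame order."""
    rows = [roi_mean_intensity(stack.frames[k], roi) for k in range(len(stack))]
    return pd.DataFrame(
        {
            "time_min": stack.times,
            "mean_intensity": [r[0] for r in rows],
            "sd_intensity": [r[1] for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# I/O: numbered 8-bit frames + index CSV
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, out_dir: str | Path, fmt: str = "tiff") -> Path:
    """Write numbered single-channel frames plus ``frame_index.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "png": "png"}.get(fmt)
    if ext is None:
        raise ValueError(f"unsupported frame format {fmt!r} (tiff or png)")
    names = []
    for k in range(len(stack)):
        name = f"frame_{k:04d}.{ext}"
        path = out / name
        if ext == "tif":
            tifffile.imwrite(path, stack.frames[k])
        else:
            iio.imwrite(path, stack.frames[k])
        names.append(name)
    pd.DataFrame(
        {"frame": np.arange(len(stack)), "time_min": stack.times, "file": names}
    ).to_csv(out / _INDEX_NAME, index=False)
    return out / _INDEX_NAME


def read_stack(frames_dir: str | Path) -> ImageStack:
    """Load a frame directory written by :func:`write_stack`.

    Validates that every indexed file exists, is single-channel 8-bit, and
    matches the first frame's shape.
    """
    frames_dir = Path(frames_dir)
    index_path = frames_dir / _INDEX_NAME
    if not index_path.exists():
        raise FileNotFoundError(f"missing frame index {index_path}")
    index = pd.read_csv(index_path)
    for col in ("frame", "time_min", "file"):
        if col not in index.columns:
            raise ValueError(f"{index_path}: missing column {col!r}")
    index = index.sort_values("time_min")

    frames = []
    shape: tuple[int, int] | None = None
    for _, row in index.iterrows():
        path = frames_dir / str(row["file"])
        if not path.exists():
            raise FileNotFoundError(f"indexed frame missing: {path}")
        arr = (
            tifffile.imread(path) if path.suffix in (".tif", ".tiff")
            else iio.imread(path)
        )
        arr = np.asarray(arr)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel image")
        if arr.dtype != np.uint8:
            raise ValueError(f"{path}: expected 8-bit data, got {arr.dtype}")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"{path}: frame shape {arr.shape} differs from {shape}"
            )
        frames.append(arr)
    return ImageStack(
        frames=np.stack(frames), times=index["time_min"].to_numpy(dtype=float)
    )
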