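"""Movie-to-kymograph processing.

Per frame: sum intensity perpendicular to the strand axis within a
user-supplied ROI, subtract a running-median background baseline
estimated outside the strand support, and stack the profiles into a
time x position kymograph with anchor calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "Kymograph",
    "project_frame",
    "subtract_background",
    "build_kymograph",
]


@dataclass
class MovieStack:
    """A stack of 2-D frames of one tethered strand.

    ``strand_roi`` is ``((row0, row1), (col0, col1))``, half-open, a band
    containing the (horizontal) strand.
    """

    frames: np.ndarray  # (t, h, w)
    pixel_size_um: float
    frame_interval_s: float
    strand_roi: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (t, h, w) array with >= 1 frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_tiff(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "strand_roi": [list(self.strand_roi[0]), list(self.strand_roi[1])],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tiff(cls, path, strand_roi=None) -> "MovieStack":
        path = Path(path)
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        if strand_roi is None:
            roi = meta.get("strand_roi")
            if roi is None:
                roi = ((0, frames.shape[1]), (0, frames.shape[2]))
            else:
                roi = (tuple(roi[0]), tuple(roi[1]))
        else:
            roi = strand_roi
        return cls(
            frames=frames,
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
            strand_roi=roi,
        )


@dataclass
class Kymograph:
    """Time x position intensity raster with calibration.

    Rows are frames, columns are pixels along the strand axis.
    ``anchor_px`` are the (left, right) strand end columns.
    """

    data: np.ndarray  # (t, x)
    pixel_size_um: float
    frame_interval_s: float
    anchor_px: tuple[int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (time x position)")
        a, b = self.anchor_px
        if not a < b:
            raise ValueError("anchor_left must be < anchor_right")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def end_to_end_um(self) -> float:
        return (self.anchor_px[1] - self.anchor_px[0]) * self.pixel_size_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def to_tiff(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "anchor_px": list(self.anchor_px),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tiff(cls, path) -> "Kymograph":
        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            pixel_size_um=float(meta["pixel_size_um"]),
            frame_interval_s=float(meta["frame_interval_s"]),
            anchor_px=tuple(int(a) for a in meta["anchor_px"]),
        )


def project_frame(frame: np.ndarray, strand_roi) -> np.ndarray:
    """Sum a frame perpendicular to the strand within the ROI band.

    Returns a 1-D profile of length ``col1 - col0``.
    """
    frame = np.asarray(frame, dtype=float)
    (r0, r1), (c0, c1) = strand_roi
    if not (0 <= r0 < r1 <= frame.shape[0] and 0 <= c0 < c1 <= frame.shape[1]):
        raise ValueError(f"ROI {strand_roi} outside frame bounds {frame.shape} or empty")
    return frame[r0:r1, c0:c1].sum(axis=0)


def subtract_background(profile: np.ndarray, kernel_px: int = 51) -> np.ndarray:
    """Subtract a running-median background baseline from a profile.

    The baseline is estimated from pixels *outside* the strand support
    (so a wide kernel cannot eat the strand itself): support pixels are
    masked out, a centered running median of width ``kernel_px`` is taken
    over the remainder, and the gap under the strand is bridged by linear
    interpolation.  Negative residues are clamped to zero.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1:
        raise ValueError("profile must be 1-D")
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be odd and >= 3")
    if kernel_px > p.size:
        raise ValueError(f"kernel ({kernel_px}) larger than profile ({p.size})")

    # support threshold from the 90th percentile, not the max: a bright
    # diffraction-limited spot must not mask the dimmer strand line
    lo, hi = np.percentile(p, [10, 90])
    support = p > lo + 0.25 * (hi - lo)
    masked = pd.Series(np.where(support, np.nan, p))
    baseline = masked.rolling(kernel_px, center=True, min_periods=1).median()
    baseline = baseline.interpolate(limit_direction="both")
    if baseline.isna().all():  # strand fills the whole profile
        baseline = pd.Series(np.full(p.size, p.min()))
    return np.clip(p - baseline.to_numpy(), 0.0, None)


def _locate_anchors(mean_profile: np.ndarray, frac: float = 0.2) -> tuple[int, int]:
    """Outermost columns whose time-averaged intensity exceeds ``frac`` of
    the strand median."""
    m = mean_profile
    peak = m.max()
    if peak <= 0:
        raise ValueError("strand not detected: empty time-averaged profile")
    coarse = m > frac * peak
    strand_median = np.median(m[coarse])
    cols = np.flatnonzero(m > frac * strand_median)
    if cols.size < 3:
        raise ValueError(f"strand not detected: support {cols.size} px < 3 px")
    return int(cols[0]), int(cols[-1])


def build_kymograph(movie: MovieStack, kernel_px: int = 51) -> Kymograph:
    """Project every frame, subtract background, and stack into a kymograph.

    Anchors are located on the time-averaged background-subtracted
    profile.
    """
    rows = []
    for frame in movie.frames:
        prof = project_frame(frame, movie.strand_roi)
        rows.append(subtract_background(prof, kernel_px))
    data = np.stack(rows)
    anchors = _locate_anchors(data.mean(axis=0))
    return Kymograph(
        data=data,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
        anchor_px=anchors,
    )
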