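"""Per-frame loop segmentation and trace tracking.

For each kymograph row: locate the loop as the intensity maximum, fit a
Gaussian around it, take the loop window as +/- 2 standard deviations
from the fitted center, split the strand signal into loop / region I
(left) / region II (right), and convert signal fractions to kilobases
of the 48.5 kb substrate.  Frames are chained into a LoopTrace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kymo import Kymograph, subtract_background
from .wlc import LAMBDA_KB

__all__ = [
    "LoopFit",
    "RegionPartition",
    "LoopTrace",
    "TraceRejected",
    "locate_loop",
    "fit_loop_gaussian",
    "partition_regions",
    "intensity_to_kb",
    "track_trace",
    "trace_from_truth",
]

#: Half-width of the loop window in fitted standard deviations.
LOOP_WINDOW_SIGMAS = 2.0

#: Fraction of a Gaussian's mass inside +/- 2 sigma (erf(2/sqrt 2)).
MASS_2SIGMA = math.erf(2.0 / math.sqrt(2.0))


class TraceRejected(ValueError):
    """Raised when too many frames of a kymograph fail segmentation."""


@dataclass
class LoopFit:
    """Gaussian fit to the loop peak of one profile."""

    center_px: float
    sigma_px: float
    amplitude: float
    offset: float
    converged: bool


@dataclass
class RegionPartition:
    """One frame's DNA partition into loop / region I / region II."""

    loop_kb: float
    region_i_kb: float
    region_ii_kb: float
    loop_window: tuple[int, int]  # inclusive pixel bounds of [mu-2s, mu+2s]
    loop_position_rel: float
    boundary_contact: bool = False


def locate_loop(
    profile: np.ndarray,
    anchors: tuple[int, int] | None = None,
    noise_sigmas: float = 5.0,
) -> int | None:
    """Position of the loop as the argmax within the anchor span.

    Returns ``None`` (no-loop flag) for a flat profile, i.e. when the
    peak does not rise above the profile's robust noise floor.  Ties are
    broken to the leftmost maximum (numpy argmax convention).
    """
    p = np.asarray(profile, dtype=float)
    a, b = anchors if anchors is not None else (0, p.size - 1)
    seg = p[a : b + 1]
    if seg.size == 0:
        raise ValueError("empty anchor span")
    offset = np.median(seg)
    noise = 1.4826 * np.median(np.abs(seg - offset))  # MAD -> sigma
    peak = seg.max() - offset
    if peak <= max(noise_sigmas * noise, 1e-12):
        return None
    return a + int(np.argmax(seg))


def _gauss(x, amplitude, mu, sigma, offset):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + offset


def fit_loop_gaussian(
    profile: np.ndarray,
    center_guess: float,
    window_halfwidth_px: int = 7,
    sigma_guess: float = 1.5,
) -> LoopFit:
    """Least-squares Gaussian+offset fit in a window around the peak.

    A fit that does not converge, or that converges to a negligible
    amplitude (pure offset: not a loop), is returned with
    ``converged=False`` and excluded downstream.
    """
    p = np.asarray(profile, dtype=float)
    lo = max(0, int(round(center_guess)) - window_halfwidth_px)
    hi = min(p.size - 1, int(round(center_guess)) + window_halfwidth_px)
    x = np.arange(lo, hi + 1, dtype=float)
    y = p[lo : hi + 1]
    if x.size < 5:
        return LoopFit(center_guess, sigma_guess, 0.0, float(np.median(y)), False)
    offset0 = float(np.median(np.concatenate([y[:2], y[-2:]])))
    amp0 = max(float(y.max() - offset0), 1e-12)
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=[amp0, center_guess, sigma_guess, offset0],
            bounds=(
                [0.0, lo - 1.0, 0.2, -np.inf],
                [np.inf, hi + 1.0, float(x.size), np.inf],
            ),
            maxfev=2000,
        )
    except RuntimeError:
        return LoopFit(center_guess, sigma_guess, 0.0, offset0, False)
    amplitude, mu, sigma, offset = (float(v) for v in popt)
    # pure-offset input: amplitude indistinguishable from zero
    significant = amplitude > max(1e-9, 0.02 * abs(offset))
    return LoopFit(mu, sigma, amplitude, offset, bool(significant))


def partition_regions(
    profile: np.ndarray,
    fit: LoopFit,
    anchors: tuple[int, int],
    boundary_margin_px: int = 3,
    total_kb: float = LAMBDA_KB,
) -> RegionPartition:
    """Split the strand signal into loop / region I / region II and
    convert to kilobases.

    The loop window is ``[mu - 2 sigma, mu + 2 sigma]``.  The loop signal
    is the integrated intensity of the fitted Gaussian above its offset;
    the offset pass-through under the window (incoming/outgoing strands)
    is split equally between the two outer regions.  Signal fractions
    are converted to kb of the ``total_kb`` substrate; the three regions
    sum to ``total_kb`` exactly.
    """
    if not fit.converged:
        raise ValueError("cannot partition with a non-converged fit")
    p = np.asarray(profile, dtype=float)
    al, ar = anchors
    lo = int(math.floor(fit.center_px - LOOP_WINDOW_SIGMAS * fit.sigma_px))
    hi = int(math.ceil(fit.center_px + LOOP_WINDOW_SIGMAS * fit.sigma_px))
    if lo < al or hi > ar:
        lo, hi = max(lo, al), min(hi, ar)
    n_win = hi - lo + 1
    if n_win <= 0:
        raise ValueError("loop window collapsed outside the anchor span")

    loop_signal = max(fit.amplitude * fit.sigma_px * math.sqrt(2.0 * math.pi), 0.0)
    passthrough = fit.offset * n_win
    region_i_signal = float(p[al:lo].sum()) + passthrough / 2.0
    region_ii_signal = float(p[hi + 1 : ar + 1].sum()) + passthrough / 2.0
    loop_kb, region_i_kb, region_ii_kb = intensity_to_kb(
        loop_signal, region_i_signal, region_ii_signal, total_kb=total_kb
    )
    return RegionPartition(
        loop_kb=loop_kb,
        region_i_kb=region_i_kb,
        region_ii_kb=region_ii_kb,
        loop_window=(lo, hi),
        loop_position_rel=(fit.center_px - al) / (ar - al),
        boundary_contact=(lo - al < boundary_margin_px) or (ar - hi < boundary_margin_px),
    )


def intensity_to_kb(
    loop_signal: float,
    region_i_signal: float,
    region_ii_signal: float,
    total_signal: float | None = None,
    total_kb: float = LAMBDA_KB,
) -> tuple[float, float, float]:
    """kb_r = total_kb * signal_r / total_signal for each region.

    With the default ``total_signal`` (the sum of the three region
    signals) the returned values sum to ``total_kb`` exactly.
    """
    if total_signal is None:
        total_signal = loop_signal + region_i_signal + region_ii_signal
    if total_signal <= 0:
        raise ValueError("total strand signal must be > 0")
    scale = total_kb / total_signal
    return loop_signal * scale, region_i_signal * scale, region_ii_signal * scale


@dataclass
class LoopTrace:
    """Per-frame quantification of one looping event.

    ``frames`` columns: frame, time_s, loop_kb, region_i_kb,
    region_ii_kb, loop_position_rel, boundary_contact, flag
    (``ok`` | ``interpolated``).
    """

    frames: pd.DataFrame
    anchor_px: tuple[int, int]
    pixel_size_um: float
    frame_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.frames["time_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("trace time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def end_to_end_um(self) -> float:
        return (self.anchor_px[1] - self.anchor_px[0]) * self.pixel_size_um

    @property
    def time_s(self) -> np.ndarray:
        return self.frames["time_s"].to_numpy()

    @property
    def loop_kb(self) -> np.ndarray:
        return self.frames["loop_kb"].to_numpy()

    def reversed(self) -> "LoopTrace":
        df = self.frames.iloc[::-1].reset_index(drop=True).copy()
        df["time_s"] = self.frames["time_s"].to_numpy()  # keep monotone axis
        df["frame"] = np.arange(len(df))
        return LoopTrace(
            df, self.anchor_px, self.pixel_size_um, self.frame_interval_s, dict(self.meta)
        )

    def to_csv(self, path) -> None:
        path = Path(path)
        self.frames.to_csv(path, index=False)
        meta = {
            "anchor_px": list(self.anchor_px),
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def from_csv(cls, path) -> "LoopTrace":
        path = Path(path)
        frames = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=frames,
            anchor_px=tuple(int(a) for a in meta.pop("anchor_px")),
            pixel_size_um=float(meta.pop("pixel_size_um")),
            frame_interval_s=float(meta.pop("frame_interval_s")),
            meta=meta,
        )


def track_trace(
    kymo: Kymograph,
    mode: str = "seeded",
    max_failed_frac: float = 0.3,
    search_halfwidth_px: int = 8,
    boundary_margin_px: int = 3,
    total_kb: float = LAMBDA_KB,
    median_kernel_px: int | None = 51,
) -> LoopTrace:
    """Segment every kymograph row and chain the partitions into a trace.

    ``mode='seeded'`` (default) restricts each frame's peak search to a
    window around the previous frame's center, which prevents jumps to
    transient noise maxima; ``mode='global'`` uses the per-frame argmax.
    Each profile is background-subtracted first (``median_kernel_px``,
    ``None`` to skip for pre-subtracted kymographs; the operation is
    idempotent).  Isolated failed frames are linearly interpolated
    (flagged); runs of failures are dropped.  More than
    ``max_failed_frac`` failures rejects the trace.
    """
    if mode not in ("seeded", "global"):
        raise ValueError("mode must be 'seeded' or 'global'")
    if kymo.n_frames < 20:
        raise ValueError("kymograph must have >= 20 frames for a trace")
    al, ar = kymo.anchor_px
    records: list[dict | None] = []
    prev_center: float | None = None
    prev_sigma = 1.5
    for k in range(kymo.n_frames):
        profile = kymo.data[k]
        if median_kernel_px is not None:
            kernel = min(median_kernel_px, profile.size if profile.size % 2 else profile.size - 1)
            profile = subtract_background(profile, kernel)
        if mode == "seeded" and prev_center is not None:
            a = max(al, int(round(prev_center)) - search_halfwidth_px)
            b = min(ar, int(round(prev_center)) + search_halfwidth_px)
            guess = locate_loop(profile, (a, b))
        else:
            guess = locate_loop(profile, (al, ar))
        part = None
        if guess is not None:
            halfwidth = max(7, int(math.ceil(6.0 * prev_sigma)))
            fit = fit_loop_gaussian(profile, guess, window_halfwidth_px=halfwidth,
                                    sigma_guess=prev_sigma)
            if fit.converged and al <= fit.center_px <= ar:
                part = partition_regions(
                    profile, fit, (al, ar),
                    boundary_margin_px=boundary_margin_px, total_kb=total_kb,
                )
                prev_center, prev_sigma = fit.center_px, fit.sigma_px
        records.append(
            None
            if part is None
            else {
                "frame": k,
                "time_s": k * kymo.frame_interval_s,
                "loop_kb": part.loop_kb,
                "region_i_kb": part.region_i_kb,
                "region_ii_kb": part.region_ii_kb,
                "loop_position_rel": part.loop_position_rel,
                "boundary_contact": part.boundary_contact,
                "flag": "ok",
            }
        )

    n_failed = sum(r is None for r in records)
    if n_failed > max_failed_frac * len(records):
        raise TraceRejected(
            f"{n_failed}/{len(records)} frames failed segmentation "
            f"(> {max_failed_frac:.0%})"
        )

    # isolated failures: linear interpolation between neighbours; runs dropped
    rows: list[dict] = []
    for k, rec in enumerate(records):
        if rec is not None:
            rows.append(rec)
            continue
        left = records[k - 1] if k > 0 else None
        right = records[k + 1] if k + 1 < len(records) else None
        if left is not None and right is not None:
            interp = {
                "frame": k,
                "time_s": k * kymo.frame_interval_s,
                "boundary_contact": bool(
                    left["boundary_contact"] or right["boundary_contact"]
                ),
                "flag": "interpolated",
            }
            for col in ("loop_kb", "region_i_kb", "region_ii_kb", "loop_position_rel"):
                interp[col] = (left[col] + right[col]) / 2.0
            rows.append(interp)

    df = pd.DataFrame(rows)
    return LoopTrace(
        frames=df,
        anchor_px=kymo.anchor_px,
        pixel_size_um=kymo.pixel_size_um,
        frame_interval_s=kymo.frame_interval_s,
        meta={"mode": mode, "n_failed": n_failed},
    )


def trace_from_truth(truth) -> LoopTrace:
    """Exact LoopTrace built from simulator ground truth (oracle path)."""
    strand = truth.strand
    df = pd.DataFrame(
        {
            "frame": np.arange(truth.n_frames),
            "time_s": truth.time_s,
            "loop_kb": truth.loop_kb,
            "region_i_kb": truth.region_i_kb,
            "region_ii_kb": truth.region_ii_kb,
            "loop_position_rel": truth.loop_position_rel,
            "boundary_contact": False,
            "flag": "ok",
        }
    )
    return LoopTrace(
        frames=df,
        anchor_px=strand.anchor_px,
        pixel_size_um=strand.pixel_size_um,
        frame_interval_s=strand.frame_interval_s,
        meta={"source": "ground_truth"},
    )
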