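"""Synthetic loop-extrusion events with ground truth.

Simulates a loop nucleating on a doubly-tethered strand and growing by
one- or two-sided reeling, with the reeling rate decaying linearly with
worm-like-chain tension until stall, and renders the result as a noisy
kymograph (or movie) with known per-frame truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .kymo import Kymograph, MovieStack
from .wlc import LAMBDA_KB, WLCParams, relative_extension, wlc_force

__all__ = [
    "StrandConfig",
    "ExtruderConfig",
    "GroundTruth",
    "simulate_extrusion",
    "render_kymograph",
    "render_movie",
    "generate_population",
]

MODES = ("one_sided_left", "one_sided_right", "two_sided")


@dataclass
class StrandConfig:
    """Geometry, imaging calibration and noise model for one strand."""

    end_to_end_um: float
    contour_length_kb: float = LAMBDA_KB
    contour_length_um: float = 18.0  # dye-corrected physical contour length
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.2
    n_frames: int = 300
    psf_sigma_px: float = 1.3
    line_intensity_per_kb: float = 200.0
    background_level: float = 20.0
    read_noise_sd: float = 3.0
    margin_px: int = 12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.end_to_end_um >= self.contour_length_um:
            raise ValueError(
                f"strand has no slack: end-to-end {self.end_to_end_um} um >= "
                f"contour {self.contour_length_um} um"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def span_px(self) -> int:
        """Anchor-to-anchor distance in whole pixels."""
        return max(3, round(self.end_to_end_um / self.pixel_size_um))

    @property
    def anchor_px(self) -> tuple[int, int]:
        return (self.margin_px, self.margin_px + self.span_px)

    def wlc(self, persistence_length_nm: float = 50.0, kBT_pN_nm: float = 4.11) -> WLCParams:
        return WLCParams(
            persistence_length_nm=persistence_length_nm,
            kBT_pN_nm=kBT_pN_nm,
            contour_length_um=self.contour_length_um,
            contour_length_kb=self.contour_length_kb,
        )


@dataclass
class ExtruderConfig:
    """One loop-extruding factor: reeling mode, zero-tension rates, stall."""

    mode: str
    rate_left_kbps: float = 0.0
    rate_right_kbps: float = 0.0
    stall_force_pN: float = 0.3
    landing_position_kb: float = LAMBDA_KB / 2
    start_frame: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.rate_left_kbps < 0 or self.rate_right_kbps < 0:
            raise ValueError("rates must be >= 0")
        if self.mode == "one_sided_left" and not (
            self.rate_left_kbps > 0 and self.rate_right_kbps == 0
        ):
            raise ValueError("one_sided_left requires rate_left > 0 and rate_right == 0")
        if self.mode == "one_sided_right" and not (
            self.rate_right_kbps > 0 and self.rate_left_kbps == 0
        ):
            raise ValueError("one_sided_right requires rate_right > 0 and rate_left == 0")
        if self.mode == "two_sided" and not (
            self.rate_left_kbps > 0 and self.rate_right_kbps > 0
        ):
            raise ValueError("two_sided requires both rates > 0")
        if not 0 < self.landing_position_kb < LAMBDA_KB:
            raise ValueError("landing_position_kb must be inside the strand")
        if self.stall_force_pN <= 0:
            raise ValueError("stall_force_pN must be > 0 (may be inf)")


@dataclass
class GroundTruth:
    """Per-frame true state of a simulated looping event.

    ``rate_left_kbps`` reels DNA into the loop from the left flank
    (region I), ``rate_right_kbps`` from the right flank (region II).
    """

    time_s: np.ndarray
    loop_kb: np.ndarray
    extruded_left_kb: np.ndarray
    extruded_right_kb: np.ndarray
    loop_position_kb: np.ndarray  # genomic midpoint of the loop interval
    loop_position_rel: np.ndarray  # physical position fraction between anchors
    tension_pN: np.ndarray
    strand: StrandConfig
    extruder: ExtruderConfig

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def region_i_kb(self) -> np.ndarray:
        """DNA left of the loop (kb)."""
        return self.extruder.landing_position_kb - self.extruded_left_kb

    @property
    def region_ii_kb(self) -> np.ndarray:
        """DNA right of the loop (kb)."""
        return (
            self.strand.contour_length_kb
            - self.extruder.landing_position_kb
            - self.extruded_right_kb
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "loop_kb": self.loop_kb,
                "extruded_left_kb": self.extruded_left_kb,
                "extruded_right_kb": self.extruded_right_kb,
                "region_i_kb": self.region_i_kb,
                "region_ii_kb": self.region_ii_kb,
                "loop_position_kb": self.loop_position_kb,
                "loop_position_rel": self.loop_position_rel,
                "tension_pN": self.tension_pN,
            }
        )

    def to_csv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {"strand": asdict(self.strand), "extruder": asdict(self.extruder)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))

    def trimmed(self, n_frames: int) -> "GroundTruth":
        """First ``n_frames`` frames as a new GroundTruth."""
        n = min(n_frames, self.n_frames)
        sl = slice(0, n)
        from dataclasses import replace

        return GroundTruth(
            time_s=self.time_s[sl],
            loop_kb=self.loop_kb[sl],
            extruded_left_kb=self.extruded_left_kb[sl],
            extruded_right_kb=self.extruded_right_kb[sl],
            loop_position_kb=self.loop_position_kb[sl],
            loop_position_rel=self.loop_position_rel[sl],
            tension_pN=self.tension_pN[sl],
            strand=replace(self.strand, n_frames=n),
            extruder=self.extruder,
        )

    def growth_end_frame(self, frac: float = 0.99) -> int:
        """First frame where the loop reaches ``frac`` of its final size."""
        if self.loop_kb[-1] <= 0:
            return 0
        return int(np.argmax(self.loop_kb > frac * self.loop_kb[-1]))


def simulate_extrusion(
    strand: StrandConfig,
    extruder: ExtruderConfig,
    wlc: WLCParams | None = None,
) -> GroundTruth:
    """Forward-Euler integration of tension-limited loop growth.

    At each camera frame the loop grows by ``(r_L(F) + r_R(F)) * dt``
    with ``r_i(F) = r_i0 * max(0, 1 - F / F_stall)`` and ``F`` the WLC
    tension at the current relative extension of the non-loop DNA.
    Growth halts when the tension reaches the stall force, when a reeled
    flank is exhausted, or at the geometric stall (RE -> 1).
    """
    if wlc is None:
        wlc = strand.wlc()
    total_kb = strand.contour_length_kb
    re0 = relative_extension(strand.end_to_end_um, wlc, 0.0)
    if re0 >= 1:
        raise ValueError(
            f"strand without slack: relative extension {re0:.3f} >= 1 at zero loop"
        )

    dt = strand.frame_interval_s
    n = strand.n_frames
    # loop size at geometric stall (RE == 1), minus a guard for wlc_force
    loop_geo = total_kb * (1.0 - strand.end_to_end_um / wlc.contour_length_um)

    exl = np.zeros(n)
    exr = np.zeros(n)
    tension = np.zeros(n)
    el = er = 0.0
    for k in range(n):
        loop = el + er
        re = relative_extension(strand.end_to_end_um, wlc, loop)
        f = wlc_force(min(re, 1.0 - 1e-9), wlc)
        exl[k] = el
        exr[k] = er
        tension[k] = f
        if k < extruder.start_frame:
            continue
        if math.isinf(extruder.stall_force_pN):
            decay = 1.0
        else:
            decay = max(0.0, 1.0 - f / extruder.stall_force_pN)
        dl = extruder.rate_left_kbps * decay * dt
        dr = extruder.rate_right_kbps * decay * dt
        # flank exhaustion: cannot reel in more DNA than remains on a side
        dl = min(dl, max(0.0, extruder.landing_position_kb - el))
        dr = min(dr, max(0.0, total_kb - extruder.landing_position_kb - er))
        # geometric stall: cap total growth so RE stays < 1
        headroom = max(0.0, loop_geo - 1e-9 - loop)
        if dl + dr > headroom:
            scale = headroom / (dl + dr) if dl + dr > 0 else 0.0
            dl *= scale
            dr *= scale
        el += dl
        er += dr

    loop_kb = exl + exr
    landing = extruder.landing_position_kb
    region_i = landing - exl
    region_ii = total_kb - landing - exr
    nonloop = region_i + region_ii
    pos_rel = np.where(nonloop > 0, region_i / np.where(nonloop > 0, nonloop, 1.0), 0.5)
    return GroundTruth(
        time_s=np.arange(n) * dt,
        loop_kb=loop_kb,
        extruded_left_kb=exl,
        extruded_right_kb=exr,
        loop_position_kb=landing + (exr - exl) / 2.0,
        loop_position_rel=pos_rel,
        tension_pN=tension,
        strand=strand,
        extruder=extruder,
    )


def _pixel_gaussian(n_px: int, center: float, sigma: float, total: float) -> np.ndarray:
    """Gaussian spot integrated over pixel bins [i-0.5, i+0.5)."""
    edges = np.arange(n_px + 1) - 0.5
    cdf = ndtr((edges - center) / sigma)
    return total * np.diff(cdf)


def _expected_profiles(truth: GroundTruth, strand: StrandConfig) -> np.ndarray:
    """Noise-free expected photon counts per pixel, without background."""
    al, ar = strand.anchor_px
    width = ar + strand.margin_px + 1
    n_line_cols = ar - al + 1
    out = np.zeros((truth.n_frames, width))
    for k in range(truth.n_frames):
        pos_rel = truth.loop_position_rel[k]
        if not 0.0 <= pos_rel <= 1.0:
            raise ValueError(f"loop position {pos_rel} outside anchors at frame {k}")
        nonloop_kb = strand.contour_length_kb - truth.loop_kb[k]
        prof = np.zeros(width)
        prof[al : ar + 1] = nonloop_kb * strand.line_intensity_per_kb / n_line_cols
        if truth.loop_kb[k] > 0:
            center = al + pos_rel * (ar - al)
            prof += _pixel_gaussian(
                width,
                center,
                strand.psf_sigma_px,
                truth.loop_kb[k] * strand.line_intensity_per_kb,
            )
        out[k] = prof
    return out


def render_kymograph(
    truth: GroundTruth,
    strand: StrandConfig | None = None,
    noiseless: bool = False,
    rng: np.random.Generator | None = None,
) -> Kymograph:
    """Render ground truth as a kymograph raster.

    Non-loop DNA is spread uniformly between the anchors; the loop is a
    pixel-integrated Gaussian spot of width ``psf_sigma_px`` whose total
    intensity is ``loop_kb * line_intensity_per_kb``.  Noise model:
    Poisson shot noise on the signal, then Gaussian read noise, then a
    constant background offset.  ``noiseless=True`` returns expected
    values (background still added).
    """
    strand = strand or truth.strand
    if truth.n_frames > strand.n_frames:
        raise ValueError("truth has more frames than the strand config allows")
    expected = _expected_profiles(truth, strand)
    if noiseless:
        data = expected + strand.background_level
    else:
        if rng is None:
            rng = np.random.default_rng(strand.seed)
        data = rng.poisson(expected).astype(float)
        if strand.read_noise_sd > 0:
            data += rng.normal(0.0, strand.read_noise_sd, size=data.shape)
        data += strand.background_level
    return Kymograph(
        data=data,
        pixel_size_um=strand.pixel_size_um,
        frame_interval_s=strand.frame_interval_s,
        anchor_px=strand.anchor_px,
    )


def render_movie(
    truth: GroundTruth,
    strand: StrandConfig | None = None,
    height: int = 15,
    noiseless: bool = False,
    rng: np.random.Generator | None = None,
) -> MovieStack:
    """Render ground truth as a 2-D movie (strand horizontal, mid-height).

    Each frame spreads the expected 1-D profile across rows with a
    pixel-integrated Gaussian of width ``psf_sigma_px``; noise is applied
    per pixel as in :func:`render_kymograph`.
    """
    strand = strand or truth.strand
    profiles = _expected_profiles(truth, strand)
    vertical = _pixel_gaussian(height, (height - 1) / 2.0, strand.psf_sigma_px, 1.0)
    expected = vertical[None, :, None] * profiles[:, None, :]
    if noiseless:
        frames = expected + strand.background_level
    else:
        if rng is None:
            rng = np.random.default_rng(strand.seed)
        frames = rng.poisson(expected).astype(float)
        if strand.read_noise_sd > 0:
            frames += rng.normal(0.0, strand.read_noise_sd, size=frames.shape)
        frames += strand.background_level
    return MovieStack(
        frames=frames,
        pixel_size_um=strand.pixel_size_um,
        frame_interval_s=strand.frame_interval_s,
        strand_roi=((0, height), (0, profiles.shape[1])),
    )


@dataclass
class PopulationRanges:
    """Sampling ranges for :func:`generate_population`.

    By default the stall force of each event is *coupled* to its initial
    relative extension (``stall = re0 - stall_couple_offset + jitter``),
    which keeps the simulated loop growth in the regime where it is well
    approximated by a single exponential — the kinetics observed
    experimentally.  Set ``stall_couple_re0=False`` to sample stall
    forces independently from ``stall_range_pN``.
    """

    re0_range: tuple[float, float] = (0.42, 0.52)
    rate_range_kbps: tuple[float, float] = (1.0, 3.0)
    stall_couple_re0: bool = True
    stall_couple_offset: float = 0.175  # pN per unit relative extension
    stall_jitter_pN: tuple[float, float] = (-0.005, 0.005)
    stall_range_pN: tuple[float, float] = (0.2, 0.5)
    landing_band: tuple[float, float] = (0.35, 0.65)  # fraction of strand length
    two_sided_ratio_range: tuple[float, float] = (0.8, 1.25)
    plateau_frac: float = 0.5  # post-stall recording as a fraction of growth time
    strand: StrandConfig = field(
        default_factory=lambda: StrandConfig(end_to_end_um=5.4, n_frames=1200)
    )


def generate_population(
    n_events: int,
    mixture: dict[str, float],
    seed: int | None = None,
    ranges: PopulationRanges | None = None,
    noiseless: bool = False,
) -> list[tuple[Kymograph, GroundTruth]]:
    """Simulate and render a reproducible population of looping events.

    ``mixture`` maps extrusion modes (``one_sided``, ``one_sided_left``,
    ``one_sided_right``, ``two_sided``) to fractions summing to 1; the
    generic ``one_sided`` picks left/right with equal probability.
    """
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    fracs = np.array(list(mixture.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions must sum to 1, got {fracs.sum()}")
    if any(m not in (*MODES, "one_sided") for m in mixture):
        raise ValueError(f"unknown mode in mixture: {sorted(mixture)}")
    ranges = ranges or PopulationRanges()
    rng = np.random.default_rng(seed)
    modes = rng.choice(list(mixture.keys()), size=n_events, p=fracs)

    events = []
    for mode in modes:
        if mode == "one_sided":
            mode = "one_sided_left" if rng.random() < 0.5 else "one_sided_right"
        base = ranges.strand
        re0 = rng.uniform(*ranges.re0_range)
        strand = StrandConfig(
            **{
                **asdict(base),
                "end_to_end_um": re0 * base.contour_length_um,
                "seed": int(rng.integers(0, 2**31)),
            }
        )
        rate = rng.uniform(*ranges.rate_range_kbps)
        if ranges.stall_couple_re0:
            stall = re0 - ranges.stall_couple_offset + rng.uniform(*ranges.stall_jitter_pN)
        else:
            stall = rng.uniform(*ranges.stall_range_pN)
        landing = rng.uniform(*ranges.landing_band) * strand.contour_length_kb
        if mode == "two_sided":
            ratio = rng.uniform(*ranges.two_sided_ratio_range)
            cfg = ExtruderConfig(
                mode=mode,
                rate_left_kbps=rate,
                rate_right_kbps=rate * ratio,
                stall_force_pN=stall,
                landing_position_kb=landing,
            )
        elif mode == "one_sided_left":
            # reel from the left flank; land right of center so it lasts
            cfg = ExtruderConfig(
                mode=mode,
                rate_left_kbps=rate,
                stall_force_pN=stall,
                landing_position_kb=max(landing, 0.55 * strand.contour_length_kb),
            )
        else:
            cfg = ExtruderConfig(
                mode=mode,
                rate_right_kbps=rate,
                stall_force_pN=stall,
                landing_position_kb=min(landing, 0.45 * strand.contour_length_kb),
            )
        truth = simulate_extrusion(strand, cfg)
        # record until shortly after stall (plateau_frac of the growth time)
        n_keep = max(80, int(truth.growth_end_frame() * (1.0 + ranges.plateau_frac)))
        truth = truth.trimmed(n_keep)
        kymo = render_kymograph(
            truth, noiseless=noiseless, rng=np.random.default_rng(strand.seed)
        )
        events.append((kymo, truth))
    return events
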