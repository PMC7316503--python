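"""Extrusion symmetry scoring and loop-displacement analysis.

The per-event symmetry score compares the DNA extruded from the two
flanking regions between the start and the end of a looping event:
score = (max(a,b) - min(a,b)) / (a + b), 1 for one-sided, 0 for
symmetric.  A flank that *gained* DNA (slippage out of the loop) counts
as zero extruded, with the gain recorded.  Loop displacement is the
first10/last10 change of relative loop position, sign-oriented so that
motion toward (or across) the strand center is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .segmentation import LoopTrace

__all__ = [
    "SymmetryResult",
    "DisplacementResult",
    "region_changes",
    "symmetry_score",
    "classify_symmetry",
    "loop_displacement",
    "center_bias",
]

#: Symmetry score below which an event is called two-sided.
TWO_SIDED_THRESHOLD = 0.5

#: Relative-position displacement below which a loop is called static.
STATIC_THRESHOLD = 0.08

#: Slippage above this many kb is flagged as substantial.
SUBSTANTIAL_SLIPPAGE_KB = 2.0

N_EDGE_FRAMES = 10


@dataclass
class SymmetryResult:
    a_kb: float  # DNA extruded from region I (>= 0 after clipping)
    b_kb: float  # DNA extruded from region II
    score: float
    symmetry_class: str  # 'one_sided' | 'two_sided'
    slippage_i_kb: float
    slippage_ii_kb: float
    substantial_slippage: bool


@dataclass
class DisplacementResult:
    displacement_rel: float  # positive toward/across center
    static: bool
    direction_class: str  # 'toward_center' | 'toward_boundary' | 'static'


def _edge_means(values: np.ndarray, n: int = N_EDGE_FRAMES) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v[:n].mean()), float(v[-n:].mean())


def region_changes(
    trace: LoopTrace, n_edge: int = N_EDGE_FRAMES
) -> tuple[float, float, float, float]:
    """DNA extruded from each flank over the event: (a, b, slip_I, slip_II).

    Per outer region, extruded = mean(first ``n_edge`` frames) - mean(last
    ``n_edge``).  A negative extruded amount means the region gained DNA
    (slippage out of the loop); it is clipped to 0 and the gain returned
    as that side's slippage.
    """
    if len(trace) < 2 * n_edge:
        raise ValueError(
            f"need >= {2 * n_edge} frames for first/last-{n_edge} statistics, "
            f"got {len(trace)}"
        )
    i_first, i_last = _edge_means(trace.frames["region_i_kb"].to_numpy(), n_edge)
    ii_first, ii_last = _edge_means(trace.frames["region_ii_kb"].to_numpy(), n_edge)
    a_raw = i_first - i_last
    b_raw = ii_first - ii_last
    a, slip_i = (a_raw, 0.0) if a_raw >= 0 else (0.0, -a_raw)
    b, slip_ii = (b_raw, 0.0) if b_raw >= 0 else (0.0, -b_raw)
    return a, b, slip_i, slip_ii


def symmetry_score(a: float, b: float) -> float:
    """(max(a,b) - min(a,b)) / (a + b) for non-negative extruded amounts."""
    if a < 0 or b < 0:
        raise ValueError("extruded amounts must be >= 0 (apply clipping first)")
    total = a + b
    if total == 0:
        raise ValueError("symmetry score undefined for a + b = 0 (no extrusion)")
    return (max(a, b) - min(a, b)) / total


def classify_symmetry(score: float, threshold: float = TWO_SIDED_THRESHOLD) -> str:
    """Score < threshold -> two_sided; >= threshold -> one_sided."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return "two_sided" if score < threshold else "one_sided"


def analyze_symmetry(trace: LoopTrace, n_edge: int = N_EDGE_FRAMES) -> SymmetryResult:
    """region_changes + score + classification for one trace."""
    a, b, slip_i, slip_ii = region_changes(trace, n_edge)
    score = symmetry_score(a, b)
    return SymmetryResult(
        a_kb=a,
        b_kb=b,
        score=score,
        symmetry_class=classify_symmetry(score),
        slippage_i_kb=slip_i,
        slippage_ii_kb=slip_ii,
        substantial_slippage=max(slip_i, slip_ii) > SUBSTANTIAL_SLIPPAGE_KB,
    )


def loop_displacement(
    trace: LoopTrace,
    n_edge: int = N_EDGE_FRAMES,
    static_threshold: float = STATIC_THRESHOLD,
) -> DisplacementResult:
    """Signed relative displacement of the loop along the strand.

    Positive if the loop moved toward (or crossed) the strand center,
    negative if it moved toward the nearest boundary, regardless of
    which half it started in.  Displacements below ``static_threshold``
    are classed static.  A loop starting exactly at the center can only
    move away from it, so its displacement is non-positive.
    """
    if len(trace) < 2 * n_edge:
        raise ValueError(f"need >= {2 * n_edge} frames, got {len(trace)}")
    p0, p1 = _edge_means(trace.frames["loop_position_rel"].to_numpy(), n_edge)
    raw = p1 - p0
    if p0 < 0.5:
        disp = raw
    elif p0 > 0.5:
        disp = -raw
    else:
        disp = -abs(raw)
    if abs(disp) < static_threshold:
        cls = "static"
    elif disp > 0:
        cls = "toward_center"
    else:
        cls = "toward_boundary"
    return DisplacementResult(
        displacement_rel=disp, static=(cls == "static"), direction_class=cls
    )


def center_bias(
    displacements: list[DisplacementResult], alpha: float = 0.05
) -> tuple[float, tuple[float, float], int]:
    """Fraction of non-static loops that moved toward the center.

    Returns (fraction, Wilson confidence interval, n non-static).
    """
    moving = [d for d in displacements if not d.static]
    if not moving:
        raise ValueError("all loops static: center bias undefined")
    k = sum(d.direction_class == "toward_center" for d in moving)
    n = len(moving)
    ci = proportion_confint(k, n, alpha=alpha, method="wilson")
    return k / n, (float(ci[0]), float(ci[1])), n
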