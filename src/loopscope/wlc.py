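"""Worm-like-chain force-extension computations.

Implements the Marko-Siggia interpolation formula, its numerical inverse,
relative-extension bookkeeping for a tethered strand with a growing loop,
per-event stall-force estimation, and the intercalating-dye contour-length
calibration (extension measured at a fixed reference force).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "WLCParams",
    "BoundaryContactError",
    "wlc_force",
    "wlc_extension",
    "relative_extension",
    "stall_force",
    "effective_contour_length",
    "load_dye_calibration",
    "save_dye_calibration",
    "contour_length_for_dye",
]

#: Contour length of bare (dye-free) B-form lambda DNA in micrometres.
BARE_LAMBDA_CONTOUR_UM = 16.49

#: Total length of the lambda-phage DNA substrate in kilobases.
LAMBDA_KB = 48.5


class BoundaryContactError(ValueError):
    """Raised when a stall-force estimate is requested for an event whose
    loop ended in contact with a strand anchor (such events are excluded
    from stall statistics)."""


@dataclass(frozen=True)
class WLCParams:
    """Constants for inextensible worm-like-chain force inference.

    Parameters
    ----------
    persistence_length_nm :
        Bending persistence length of double-stranded DNA (nm).
    kBT_pN_nm :
        Thermal energy (pN nm).
    contour_length_um :
        Effective physical contour length of the strand in micrometres,
        corrected for intercalating-dye lengthening.
    contour_length_kb :
        Total strand length in kilobases.
    """

    persistence_length_nm: float = 50.0
    kBT_pN_nm: float = 4.11
    contour_length_um: float = BARE_LAMBDA_CONTOUR_UM
    contour_length_kb: float = LAMBDA_KB

    def __post_init__(self) -> None:
        if self.persistence_length_nm <= 0:
            raise ValueError("persistence_length_nm must be > 0")
        if self.kBT_pN_nm <= 0:
            raise ValueError("kBT_pN_nm must be > 0")
        if self.contour_length_kb <= 0:
            raise ValueError("contour_length_kb must be > 0")
        if self.contour_length_um < BARE_LAMBDA_CONTOUR_UM - 1e-9:
            raise ValueError(
                "contour_length_um below the bare B-DNA lambda contour "
                f"({BARE_LAMBDA_CONTOUR_UM} um); dye correction can only lengthen"
            )

    def with_contour_length(self, contour_length_um: float) -> "WLCParams":
        return replace(self, contour_length_um=contour_length_um)


def wlc_force(rel_extension, params: WLCParams = WLCParams()):
    """Marko-Siggia interpolation force at relative extension ``x``.

    F = (kBT / P) * [ 1 / (4 (1 - x)^2) - 1/4 + x ]

    Parameters
    ----------
    rel_extension :
        Scalar or array of relative extensions in ``[0, 1)``.

    Returns
    -------
    Tension in pN (same shape as input).
    """
    x = np.asarray(rel_extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("relative extension must be >= 0")
    if np.any(x >= 1):
        raise ValueError("relative extension must be < 1 (overstretched)")
    scale = params.kBT_pN_nm / params.persistence_length_nm
    f = scale * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
    return float(f) if np.isscalar(rel_extension) else f


def wlc_extension(force, params: WLCParams = WLCParams(), xtol: float = 1e-12):
    """Inverse of :func:`wlc_force`: relative extension at a given tension.

    Root-finds the strictly monotone Marko-Siggia formula on ``[0, 1)``.
    """

    def _one(f: float) -> float:
        if f < 0:
            raise ValueError("force must be >= 0")
        if f == 0.0:
            return 0.0
        # bracket: F is strictly increasing, diverges as x -> 1
        hi = 1.0 - 1e-9
        if wlc_force(hi, params) < f:
            raise ValueError(f"force {f} pN beyond inversion bracket")
        return brentq(lambda x: wlc_force(x, params) - f, 0.0, hi, xtol=xtol)

    if np.isscalar(force):
        return _one(float(force))
    return np.array([_one(float(f)) for f in np.asarray(force, dtype=float).ravel()]).reshape(
        np.shape(force)
    )


def relative_extension(end_to_end_um, params: WLCParams, loop_kb=0.0):
    """Relative extension of the DNA outside the loop.

    RE = L / (CL_phys * (1 - loop_kb / CL_kb))

    where ``L`` is the anchor-to-anchor distance and ``CL_phys`` the
    dye-corrected physical contour length.  Values >= 1 are returned
    as-is (callers flag/mask them); a non-positive denominator raises.
    """
    loop = np.asarray(loop_kb, dtype=float)
    frac = 1.0 - loop / params.contour_length_kb
    if np.any(frac <= 0):
        raise ValueError("loop_kb >= total strand length: no DNA outside the loop")
    re = end_to_end_um / (params.contour_length_um * frac)
    return float(re) if np.isscalar(loop_kb) and np.isscalar(end_to_end_um) else re


def stall_force(trace, params: WLCParams, n_tail: int = 10) -> float:
    """Stall force of one looping event.

    Averages the steady-state loop size over the last ``n_tail`` frames,
    converts it to a relative extension and then to a single tension via
    the WLC model.  Events whose loop ended at (or within the configured
    margin of) a strand anchor are excluded from stall statistics and
    raise :class:`BoundaryContactError`.
    """
    df = trace.frames
    if len(df) < n_tail:
        raise ValueError(f"trace has {len(df)} frames; need >= {n_tail}")
    tail = df.iloc[-n_tail:]
    if "boundary_contact" in tail and bool(tail["boundary_contact"].any()):
        raise BoundaryContactError(
            "loop ended at a strand anchor; excluded from stall-force statistics"
        )
    loop_kb = float(tail["loop_kb"].mean())
    re = relative_extension(trace.end_to_end_um, params, loop_kb)
    if re >= 1:
        re = 1.0 - 1e-9  # numerical guard at geometric stall
    return wlc_force(re, params)


def effective_contour_length(
    measured_extension_um: float, force_pN: float, params: WLCParams = WLCParams()
) -> float:
    """Dye-corrected contour length from an extension at a known force.

    The strand is stretched at a fixed calibration force; the effective
    contour length is the measured end-to-end extension divided by the
    WLC relative extension at that force.
    """
    if measured_extension_um <= 0:
        raise ValueError("measured extension must be > 0")
    if force_pN <= 0:
        raise ValueError("calibration force must be > 0")
    return measured_extension_um / wlc_extension(force_pN, params)


# ---------------------------------------------------------------------------
# dye-concentration -> contour-length calibration table


def save_dye_calibration(table: dict[float, float], path) -> None:
    """Write a dye calibration table (dye nM -> contour length um) as CSV."""
    df = pd.DataFrame(
        {"dye_nM": list(table.keys()), "contour_length_um": list(table.values())}
    ).sort_values("dye_nM")
    df.to_csv(path, index=False)


def load_dye_calibration(path) -> dict[float, float]:
    df = pd.read_csv(path)
    if not {"dye_nM", "contour_length_um"} <= set(df.columns):
        raise ValueError("calibration CSV needs columns dye_nM, contour_length_um")
    return dict(zip(df["dye_nM"].astype(float), df["contour_length_um"].astype(float)))


def contour_length_for_dye(dye_nM: float, table: dict[float, float]) -> float:
    """Linear interpolation of the calibration table; clamps at the ends."""
    if not table:
        raise ValueError("empty calibration table")
    xs = np.array(sorted(table))
    ys = np.array([table[x] for x in xs])
    return float(np.interp(dye_nM, xs, ys))
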