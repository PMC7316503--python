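"""Loop-growth kinetics: exponential fits, smoothing, rate-vs-tension.

The initial extrusion rate is the t=0 derivative of a single-exponential
fit to loop size over time; the convergence gate is a 1e-8 relative
change of the least-squares cost.  A Savitzky-Golay (order 2, window 63)
smoothed derivative provides an independent rate estimate, and smoothed
relative extension feeds the WLC tension for rate-vs-tension curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .segmentation import LoopTrace
from .wlc import WLCParams, relative_extension, wlc_force

__all__ = [
    "ExpFitResult",
    "fit_exponential",
    "smooth_trace",
    "rate_vs_tension",
    "pool_rate_tension",
]

REL_COST_TOLERANCE = 1e-8
SAVGOL_WINDOW = 63
SAVGOL_ORDER = 2


@dataclass
class ExpFitResult:
    """Saturating-exponential fit loop(t) = Lf - (Lf - L0) exp(-t/tau)."""

    loop_initial_kb: float
    loop_final_kb: float
    tau_s: float
    initial_rate_kbps: float
    cost: float
    converged: bool
    t0_index: int = 0
    rel_cost_tolerance: float = REL_COST_TOLERANCE


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    l0, lf, tau = params
    return lf - (lf - l0) * np.exp(-t / tau)


def find_onset(loop_kb: np.ndarray, n_baseline: int = 5, n_sigmas: float = 3.0) -> int:
    """First index where the loop exceeds the pre-event level by
    ``n_sigmas`` baseline standard deviations; 0 if growth is immediate."""
    y = np.asarray(loop_kb, dtype=float)
    base = y[:n_baseline]
    level = float(base.mean())
    sd = float(base.std())
    above = np.flatnonzero(y > level + n_sigmas * sd)
    return int(above[0]) if above.size else 0


def fit_exponential(
    trace: LoopTrace | None = None,
    time_s: np.ndarray | None = None,
    loop_kb: np.ndarray | None = None,
    onset: int | str = "auto",
    rel_cost_tolerance: float = REL_COST_TOLERANCE,
) -> ExpFitResult:
    """Fit loop growth with a single saturating exponential.

    The initial extrusion rate is the model's derivative at the onset:
    ``(Lf - L0) / tau``.  Accepts either a :class:`LoopTrace` or raw
    ``time_s`` / ``loop_kb`` arrays.  ``converged`` requires the
    optimizer to satisfy the relative-cost tolerance with a physically
    meaningful (growing, positive-tau) solution; degenerate traces are
    flagged and excluded from rate statistics by callers.
    """
    if trace is not None:
        time_s, loop_kb = trace.time_s, trace.loop_kb
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(loop_kb, dtype=float)
    if t.size < 20:
        raise ValueError(f"need >= 20 frames for a kinetics fit, got {t.size}")

    i0 = find_onset(y) if onset == "auto" else int(onset)
    i0 = min(i0, t.size - 10)
    ts = t[i0:] - t[i0]
    ys = y[i0:]

    l0_guess = float(ys[0])
    lf_guess = float(ys[-1])
    tau_guess = max(float(ts[-1]) / 2.0, 1e-3)
    span = max(abs(lf_guess - l0_guess), 1e-9)

    res = least_squares(
        lambda p: _model(p, ts) - ys,
        x0=[l0_guess, lf_guess if abs(lf_guess - l0_guess) > 1e-12 else l0_guess + 1e-9,
            tau_guess],
        ftol=rel_cost_tolerance,
        xtol=1e-14,
        gtol=1e-14,
        method="trf",
        bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
    )
    l0, lf, tau = (float(v) for v in res.x)
    amplitude = lf - l0
    rate0 = amplitude / tau
    converged = bool(res.success) and tau > 0 and amplitude > max(1e-6, 1e-4 * span)
    return ExpFitResult(
        loop_initial_kb=l0,
        loop_final_kb=lf,
        tau_s=tau,
        initial_rate_kbps=rate0,
        cost=float(res.cost),
        converged=converged,
        t0_index=i0,
        rel_cost_tolerance=rel_cost_tolerance,
    )


def smooth_trace(
    values: np.ndarray,
    window: int = SAVGOL_WINDOW,
    order: int = SAVGOL_ORDER,
    deriv: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing (default order 2, window 63 points).

    Traces shorter than the window shrink it to the largest odd length
    <= n.  Edges are handled by polynomial extrapolation (``mode=interp``
    fits the edge polynomials to the data).  An order-``order``
    polynomial input is reproduced exactly.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 5:
        raise ValueError(f"need >= 5 points to smooth, got {y.size}")
    w = min(window, y.size if y.size % 2 == 1 else y.size - 1)
    if w % 2 == 0:
        w -= 1
    w = max(w, order + 2 if (order + 2) % 2 == 1 else order + 3)
    return savgol_filter(y, window_length=w, polyorder=order, deriv=deriv,
                         delta=delta, mode="interp")


def rate_vs_tension(
    trace: LoopTrace,
    fit: ExpFitResult,
    wlc: WLCParams,
    window: int = SAVGOL_WINDOW,
) -> pd.DataFrame:
    """Per-frame (tension, rate) curve for one event.

    Rate from the exponential fit, ``rate(t) = rate0 * exp(-t/tau)``;
    tension from the WLC force at the Savitzky-Golay-smoothed relative
    extension.  Also reports the smoothed-derivative rate as an
    independent estimate.  Frames at or beyond full extension (RE >= 1)
    are masked out.
    """
    if not fit.converged:
        raise ValueError("rate_vs_tension requires a converged exponential fit")
    t = trace.time_s
    loop = trace.loop_kb
    dt_rel = t - t[fit.t0_index]
    rate = fit.initial_rate_kbps * np.exp(-np.clip(dt_rel, 0.0, None) / fit.tau_s)

    loop_smooth = smooth_trace(loop, window=window)
    dt = float(np.median(np.diff(t)))
    rate_sg = smooth_trace(loop, window=window, deriv=1, delta=dt)

    re = relative_extension(trace.end_to_end_um, wlc,
                            np.clip(loop_smooth, 0.0, wlc.contour_length_kb * 0.999))
    ok = re < 1.0
    tension = np.full(t.size, np.nan)
    tension[ok] = wlc_force(re[ok], wlc)
    df = pd.DataFrame(
        {
            "time_s": t,
            "tension_pN": tension,
            "rate_kbps": rate,
            "rate_sg_kbps": rate_sg,
        }
    )
    return df[ok].reset_index(drop=True)


def pool_rate_tension(
    curves: list[pd.DataFrame], n_bins: int = 8
) -> pd.DataFrame:
    """Per-tension-bin mean +/- SD of extrusion rate *across events*.

    Global equal-count tension bins (quantiles of the pooled tensions);
    within each bin every event contributes its mean rate, and the
    reported mean/SD are taken over those per-event values, so identical
    curves give SD 0.  Bins with no points are dropped.
    """
    if len(curves) < 2:
        raise ValueError("need >= 2 curves to pool")
    tagged = [c.assign(_event=i) for i, c in enumerate(curves)]
    pooled = pd.concat(tagged, ignore_index=True).dropna(subset=["tension_pN"])
    edges = np.unique(
        np.quantile(pooled["tension_pN"], np.linspace(0.0, 1.0, n_bins + 1))
    )
    if edges.size < 2:
        edges = np.array([pooled["tension_pN"].min() - 1e-12,
                          pooled["tension_pN"].max() + 1e-12])
    labels = np.clip(np.searchsorted(edges, pooled["tension_pN"], side="right") - 1,
                     0, edges.size - 2)
    pooled = pooled.assign(_bin=labels)
    per_event = (
        pooled.groupby(["_bin", "_event"])
        .agg(tension_pN=("tension_pN", "mean"), rate_kbps=("rate_kbps", "mean"))
        .reset_index()
    )
    rows = []
    for _, grp in per_event.groupby("_bin"):
        rows.append(
            {
                "tension_pN": grp["tension_pN"].mean(),
                "rate_mean_kbps": grp["rate_kbps"].mean(),
                "rate_sd_kbps": grp["rate_kbps"].std(ddof=0),
                "n_events": len(grp),
            }
        )
    return pd.DataFrame(rows).sort_values("tension_pN").reset_index(drop=True)
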