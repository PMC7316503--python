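"""End-to-end orchestration: kymograph -> per-event summary -> run outputs."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, validate_config
from .dynamics import fit_exponential
from .kymo import Kymograph
from .segmentation import TraceRejected, track_trace
from .symmetry import analyze_symmetry, loop_displacement
from .wlc import BoundaryContactError, relative_extension, stall_force

log = logging.getLogger("loopscope")

__all__ = ["analyze_kymograph", "run_pipeline"]

EVENT_COLUMNS = [
    "event_id",
    "n_frames",
    "re0",
    "rate0_kbps",
    "tau_s",
    "fit_converged",
    "stall_pN",
    "boundary_contact",
    "a_kb",
    "b_kb",
    "symmetry_score",
    "symmetry_class",
    "slippage_kb",
    "displacement_rel",
    "direction_class",
    "error",
]


def analyze_kymograph(
    kymo: Kymograph, config: RunConfig, event_id: str = "event"
) -> dict:
    """Run the full per-event analysis chain on one kymograph.

    Returns a flat record (one row of the events table).  Stage failures
    are captured in the ``error`` field rather than raised, so batch runs
    survive malformed inputs.
    """
    rec: dict = {c: None for c in EVENT_COLUMNS}
    rec["event_id"] = event_id
    wlc = config.wlc()
    try:
        trace = track_trace(
            kymo,
            mode=config.tracking_mode,
            max_failed_frac=config.max_failed_frac,
            boundary_margin_px=config.boundary_margin_px,
            total_kb=config.contour_length_kb,
            median_kernel_px=config.median_kernel_px,
        )
    except (TraceRejected, ValueError) as exc:
        rec["error"] = f"tracking: {exc}"
        return rec
    rec["n_frames"] = len(trace)
    rec["re0"] = relative_extension(trace.end_to_end_um, wlc, 0.0)

    try:
        fit = fit_exponential(trace, rel_cost_tolerance=config.rel_cost_tolerance)
        rec["fit_converged"] = fit.converged
        if fit.converged:
            rec["rate0_kbps"] = fit.initial_rate_kbps
            rec["tau_s"] = fit.tau_s
    except ValueError as exc:
        rec["error"] = f"kinetics: {exc}"

    try:
        rec["stall_pN"] = stall_force(trace, wlc, n_tail=config.n_edge_frames)
        rec["boundary_contact"] = False
    except BoundaryContactError:
        rec["boundary_contact"] = True
    except ValueError as exc:
        rec["error"] = f"stall: {exc}"

    try:
        sym = analyze_symmetry(trace, n_edge=config.n_edge_frames)
        rec.update(
            a_kb=sym.a_kb,
            b_kb=sym.b_kb,
            symmetry_score=sym.score,
            symmetry_class=sym.symmetry_class,
            slippage_kb=max(sym.slippage_i_kb, sym.slippage_ii_kb),
        )
        disp = loop_displacement(
            trace, n_edge=config.n_edge_frames, static_threshold=config.static_threshold
        )
        rec["displacement_rel"] = disp.displacement_rel
        rec["direction_class"] = disp.direction_class
    except ValueError as exc:
        rec["error"] = f"symmetry: {exc}"
    return rec


def run_pipeline(
    config: RunConfig,
    inputs: list[Path | str] | list[Kymograph],
    out_dir: Path | str,
) -> Path:
    """Analyze a batch of kymographs and write a reproducible run directory.

    Writes ``events.csv``, ``population.csv``, ``provenance.json`` and
    ``run.log``.  Identical config + inputs give identical outputs.
    """
    diags = validate_config(config)
    errors = [d for d in diags if d.startswith("error:")]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    records = []
    input_names = []
    try:
        for i, item in enumerate(inputs):
            if isinstance(item, Kymograph):
                kymo, name = item, f"event_{i:04d}"
            else:
                name = Path(item).stem
                try:
                    kymo = Kymograph.from_tiff(item)
                except Exception as exc:  # malformed input: report, keep going
                    log.warning("skipping %s: %s", item, exc)
                    records.append(
                        {**{c: None for c in EVENT_COLUMNS},
                         "event_id": name, "error": f"io: {exc}"}
                    )
                    input_names.append(str(item))
                    continue
            input_names.append(name)
            rec = analyze_kymograph(kymo, config, event_id=name)
            if rec["error"]:
                log.warning("%s: %s", name, rec["error"])
            records.append(rec)

        events = pd.DataFrame(records, columns=EVENT_COLUMNS)
        events.to_csv(out / "events.csv", index=False, float_format="%.10g")

        ok = events[events["error"].isna()] if len(events) else events
        summary = {
            "n_inputs": len(records),
            "n_analyzed": int(len(ok)),
            "n_fit_converged": int(ok["fit_converged"].fillna(False).sum()) if len(ok) else 0,
            "mean_rate0_kbps": _safe_mean(ok, "rate0_kbps"),
            "mean_stall_pN": _safe_mean(ok[ok["boundary_contact"] == False], "stall_pN")
            if len(ok) else None,  # noqa: E712 (pandas elementwise compare)
            "frac_two_sided": _frac(ok, "symmetry_class", "two_sided"),
            "frac_toward_center": _frac(
                ok[ok["direction_class"] != "static"] if len(ok) else ok,
                "direction_class", "toward_center",
            ),
        }
        pd.DataFrame([summary]).to_csv(out / "population.csv", index=False,
                                       float_format="%.10g")

        provenance = {
            "config": json.loads(json.dumps(asdict(config), default=float)),
            "config_digest": config.digest(),
            "seed": config.seed,
            "loopscope_version": __version__,
            "python_version": platform.python_version(),
            "inputs": input_names,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        config.to_yaml(out / "config.yaml")
        log.info("run complete: %d inputs, %d analyzed", len(records), len(ok))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _safe_mean(df: pd.DataFrame, col: str):
    if len(df) == 0:
        return None
    vals = pd.to_numeric(df[col], errors="coerce").dropna()
    return float(vals.mean()) if len(vals) else None


def _frac(df: pd.DataFrame, col: str, value: str):
    if len(df) == 0:
        return None
    vals = df[col].dropna()
    if len(vals) == 0:
        return None
    return float(np.mean(vals == value))
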