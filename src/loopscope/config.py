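"""Run configuration: every analysis threshold in one serializable record."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .wlc import WLCParams

__all__ = ["RunConfig", "validate_config"]


@dataclass
class RunConfig:
    """All pipeline constants and thresholds, YAML round-trippable."""

    # WLC / geometry
    persistence_length_nm: float = 50.0
    kBT_pN_nm: float = 4.11
    contour_length_um: float = 18.0
    contour_length_kb: float = 48.5
    # kymograph processing
    median_kernel_px: int = 51
    # segmentation
    loop_window_sigmas: float = 2.0
    boundary_margin_px: int = 3
    tracking_mode: str = "seeded"
    max_failed_frac: float = 0.3
    # kinetics
    rel_cost_tolerance: float = 1e-8
    savgol_window: int = 63
    savgol_order: int = 2
    # symmetry / displacement
    n_edge_frames: int = 10
    symmetry_threshold: float = 0.5
    static_threshold: float = 0.08
    substantial_slippage_kb: float = 2.0
    # population
    slack_threshold: float = 0.6
    significance_alpha: float = 0.01
    # provenance
    seed: int = 0
    dye_calibration: dict = field(default_factory=dict)  # dye nM -> contour um

    def wlc(self) -> WLCParams:
        return WLCParams(
            persistence_length_nm=self.persistence_length_nm,
            kBT_pN_nm=self.kBT_pN_nm,
            contour_length_um=self.contour_length_um,
            contour_length_kb=self.contour_length_kb,
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Physical/logical consistency diagnostics; empty list means clean.

    Entries are prefixed ``error:`` or ``warning:``.
    """
    diags: list[str] = []
    if config.persistence_length_nm <= 0:
        diags.append("error: persistence_length_nm must be > 0")
    if config.kBT_pN_nm <= 0:
        diags.append("error: kBT_pN_nm must be > 0")
    if config.contour_length_um <= 0 or config.contour_length_kb <= 0:
        diags.append("error: contour lengths must be > 0")
    if config.median_kernel_px < 3 or config.median_kernel_px % 2 == 0:
        diags.append("error: median_kernel_px must be odd and >= 3")
    if config.loop_window_sigmas <= 0:
        diags.append("error: loop_window_sigmas must be > 0")
    if not 0 < config.rel_cost_tolerance < 1:
        diags.append("error: rel_cost_tolerance must be in (0, 1)")
    if config.savgol_window < config.savgol_order + 2:
        diags.append("error: savgol_window must exceed savgol_order + 1")
    if config.savgol_window % 2 == 0:
        diags.append("error: savgol_window must be odd")
    if config.tracking_mode not in ("seeded", "global"):
        diags.append("error: tracking_mode must be 'seeded' or 'global'")
    if not 0 < config.symmetry_threshold <= 1:
        diags.append("error: symmetry_threshold must be in (0, 1]")
    if config.static_threshold < 0:
        diags.append("error: static_threshold must be >= 0")
    if config.slack_threshold >= 1:
        diags.append("warning: slack_threshold >= 1 makes the slack filter vacuous")
    if config.slack_threshold <= 0:
        diags.append("error: slack_threshold must be > 0")
    if not 0 < config.significance_alpha < 1:
        diags.append("error: significance_alpha must be in (0, 1)")
    for dye, cl in config.dye_calibration.items():
        if cl < 16.49:
            diags.append(
                f"warning: calibration contour {cl} um at {dye} nM below bare lambda"
            )
    return diags
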