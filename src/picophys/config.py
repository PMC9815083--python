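"""Run configuration: flat key-value files with validated physical defaults.

A run config collects every printed instrument constant in one place —
pixel scale, imaging intervals, reactor geometry, refraction increments,
Cmol masses — so unit conversions happen once, at module boundaries.
Values are read from a flat YAML mapping; unknown keys are rejected and
each value records whether it came from the file or from the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

from picophys.qpi import ALPHA_CELL, ALPHA_BEAD
from picophys.stoichiometry import M_X_CMOL, M_S_CMOL

__all__ = ["RunConfig", "load_config", "save_config"]

#: 1% w/v == 10 g/L; converters live here so glucose concentrations quoted
#: in % w/v or ug/L elsewhere cannot silently mix with g/L.
PCT_WV_TO_G_L = 10.0
UG_L_TO_G_L = 1e-6


@dataclass(frozen=True)
class RunConfig:
    """All pipeline-level physical settings with instrument defaults."""

    pixel_size_um: float = 0.045
    frame_interval_mm_min: float = 5.0     # mother machine imaging
    frame_interval_plb_min: float = 20.0   # picoliter batch imaging
    refraction_increment_cell: float = ALPHA_CELL
    refraction_increment_bead: float = ALPHA_BEAD
    chamber_width_um: float = 60.0
    chamber_length_um: float = 100.0
    chamber_height_um: float = 1.0
    reactor_volume_pL: float = 606.0
    m_x_cmol: float = M_X_CMOL
    m_s_cmol: float = M_S_CMOL
    seed: int = 0
    output_dir: str = "picophys_out"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("seed", "output_dir"):
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"config key {f.name!r} must be positive")

    def provenance(self, overrides: dict | None = None) -> dict[str, str]:
        """Map each key to 'user' or 'default'."""
        overrides = overrides or {}
        return {f.name: "user" if f.name in overrides else "default"
                for f in fields(self)}


def load_config(path: str | Path) -> tuple[RunConfig, dict[str, str]]:
    """Load a flat key-value YAML config; unknown keys are an error.

    Returns the validated config and a provenance map (default vs user per
    key).  An empty file yields all defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**data)
    return cfg, cfg.provenance(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
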