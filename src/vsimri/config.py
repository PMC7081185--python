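"""Pipeline-wide configuration with YAML round-tripping.

Defaults are the study constants: B0 = 7 T, Δχ = 4.5e-7 (CGS), D = 800
um²/s, echo-train ΔR2 calibration 4.375, edema threshold 650 um²/s and the
histogram cutoffs VSI > 10 um and MVD > 200 mm⁻².
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .physics import GAMMA_PROTON, PhysicsConfig

log = logging.getLogger("vsimri")

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    B0: float = 7.0
    delta_chi: float = 4.5e-7
    gamma: float = GAMMA_PROTON
    chi_convention: str = "as_given"
    D: float = 800.0  # um^2/s
    scale_factor: float = 4.375
    adc_threshold: float = 650.0  # um^2/s
    vsi_cutoff: float = 10.0  # um
    mvd_cutoff: float = 200.0  # mm^-2
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("adc_threshold", "vsi_cutoff", "mvd_cutoff", "scale_factor", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def physics(self) -> PhysicsConfig:
        return PhysicsConfig(
            B0=self.B0,
            delta_chi=self.delta_chi,
            gamma=self.gamma,
            chi_convention=self.chi_convention,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a YAML config; absent keys take defaults (and are logged).

    Accepts either a flat mapping or the nested form with a ``physics``
    section ({B0, delta_chi, gamma, chi_convention}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if "physics" in raw:
        raw.update(raw.pop("physics"))
    if "simulation" in raw:
        sim = raw.pop("simulation")
        raw.setdefault("D", sim.get("D", 800.0))
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    for name in known - set(raw):
        log.info("config: %s absent, default %r applied", name, getattr(cfg, name))
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
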