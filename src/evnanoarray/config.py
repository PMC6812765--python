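"""Structured run configuration for the CLI.

A single YAML (or JSON) file holds one section per pipeline stage; every
section maps onto the corresponding dataclass, so preconditions are
checked at load time and unknown keys are rejected with the offending
section named. Precedence is CLI flag > config file > dataclass default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .detect import DetectionParams
from .morphometry import ClassThresholds
from .stats import CaptureModel
from .synthetic import LayoutSpec, RenderConfig

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "layout": LayoutSpec,
    "render": RenderConfig,
    "detection": DetectionParams,
    "thresholds": ClassThresholds,
    "capture": CaptureModel,
}

_TOP_LEVEL = set(_SECTIONS) | {"seed", "occupancy", "n_ldl", "cell_line", "evs_per_spot",
                               "fit_through_origin"}


def _build(cls, mapping: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"config section '{section}': unknown keys {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class RunConfig:
    """Validated parameters for a full simulate/process/analyze run."""

    layout: LayoutSpec = field(
        default_factory=lambda: LayoutSpec(field_width_nm=8000.0, field_height_nm=8000.0,
                                           pitch_nm=400.0)
    )
    render: RenderConfig = field(default_factory=RenderConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    capture: CaptureModel | None = None
    seed: int = 0
    occupancy: float = 0.20
    n_ldl: int = 0
    cell_line: str = "Sk-Br-3"
    evs_per_spot: int = 1
    fit_through_origin: bool = True

    def to_dict(self) -> dict:
        from dataclasses import asdict

        out: dict = {
            "layout": asdict(self.layout),
            "render": asdict(self.render),
            "detection": asdict(self.detection),
            "thresholds": asdict(self.thresholds),
            "capture": asdict(self.capture) if self.capture else None,
            "seed": self.seed,
            "occupancy": self.occupancy,
            "n_ldl": self.n_ldl,
            "cell_line": self.cell_line,
            "evs_per_spot": self.evs_per_spot,
            "fit_through_origin": self.fit_through_origin,
        }
        return out

    def digest(self) -> str:
        """Stable short hash of the full configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON, applying flat overrides
    (e.g. ``{"seed": 7, "render.noise_sd_nm": 0.2}``)."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config root must be a mapping")
    for key, val in (overrides or {}).items():
        if "." in key:
            sect, sub = key.split(".", 1)
            raw.setdefault(sect, {})[sub] = val
        else:
            raw[key] = val

    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ValueError(f"config: unknown top-level keys {sorted(unknown)}")

    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in raw and raw[name] is not None:
            kwargs[name] = _build(cls, dict(raw[name]), name)
    for scalar in ("seed", "occupancy", "n_ldl", "cell_line", "evs_per_spot",
                   "fit_through_origin"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    return RunConfig(**kwargs)
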