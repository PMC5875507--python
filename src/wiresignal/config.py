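"""Flat key-value configuration (YAML) for the detector model, penumbral
fractions and comparison tolerances.

Recognised keys (all optional; packaged defaults used otherwise)::

    n_wires: 40                 # wires / leaf pairs
    wire_pitch_cm: 1.0          # isocenter-projected wire spacing
    k: 1.0                      # signal per (mm * MU)
    lateral_exponent: 1.4034    # scatter decay, per cm
    scatter_cutoff_cm: 4.0      # scatter range limit
    closed_threshold_mm: 1.0    # separations <= this count as closed
    in_field_sigma: 0.01        # relative uncertainty of in-field wires
    penumbra_fractions: [0.30, 0.10, 0.04, 0.015]
    penumbra_sigmas: [0.10, 0.10, 0.10, 0.10]   # relative
    beam_tolerance: 0.05        # relative, per beam
    fraction_tolerance: 0.025   # relative, full fraction
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import DEFAULT_PENUMBRA, DetectorModel, PenumbraModel

__all__ = ["Settings", "load_settings", "save_settings"]

_MODEL_KEYS = {
    "n_wires": "n_wires",
    "wire_pitch_cm": "wire_pitch",
    "k": "k",
    "lateral_exponent": "lateral_exponent",
    "scatter_cutoff_cm": "scatter_cutoff",
    "closed_threshold_mm": "closed_threshold",
    "in_field_sigma": "in_field_sigma",
}


@dataclass(frozen=True)
class Settings:
    """Bundle of model parameters and verification tolerances."""

    detector: DetectorModel = field(default_factory=DetectorModel)
    penumbra: PenumbraModel = DEFAULT_PENUMBRA
    beam_tolerance: float = 0.05
    fraction_tolerance: float = 0.025

    def __post_init__(self) -> None:
        if self.beam_tolerance <= 0 or self.fraction_tolerance <= 0:
            raise ConfigError("tolerances must be > 0")

    def to_dict(self) -> dict:
        d = {file_key: getattr(self.detector, attr) for file_key, attr in _MODEL_KEYS.items()}
        d["penumbra_fractions"] = list(self.penumbra.fractions)
        d["penumbra_sigmas"] = list(self.penumbra.sigmas)
        d["beam_tolerance"] = self.beam_tolerance
        d["fraction_tolerance"] = self.fraction_tolerance
        return d


def load_settings(path: str | Path | None = None) -> Settings:
    """Load settings from a YAML file; missing keys take packaged defaults."""
    if path is None:
        return Settings()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return Settings()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a flat mapping")
    known = set(_MODEL_KEYS) | {
        "penumbra_fractions",
        "penumbra_sigmas",
        "beam_tolerance",
        "fraction_tolerance",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        model_kwargs = {
            attr: raw[file_key] for file_key, attr in _MODEL_KEYS.items() if file_key in raw
        }
        detector = DetectorModel(**model_kwargs)
        pen_kwargs = {}
        if "penumbra_fractions" in raw:
            pen_kwargs["fractions"] = tuple(raw["penumbra_fractions"])
        else:
            pen_kwargs["fractions"] = DEFAULT_PENUMBRA.fractions
        if "penumbra_sigmas" in raw:
            pen_kwargs["sigmas"] = tuple(raw["penumbra_sigmas"])
        else:
            pen_kwargs["sigmas"] = DEFAULT_PENUMBRA.sigmas
        penumbra = PenumbraModel(**pen_kwargs)
        return Settings(
            detector=detector,
            penumbra=penumbra,
            beam_tolerance=float(raw.get("beam_tolerance", 0.05)),
            fraction_tolerance=float(raw.get("fraction_tolerance", 0.025)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def save_settings(settings: Settings, path: str | Path) -> None:
    """Write settings as flat YAML, keys in a stable order."""
    Path(path).write_text(
        yaml.safe_dump(settings.to_dict(), sort_keys=True, default_flow_style=None)
    )
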