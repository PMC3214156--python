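"""Run configuration: defaults < YAML config file < CLI flags.

Every run echoes its fully resolved configuration (defaults included) into
its output header, together with a short hash, so any output row can be
reproduced by calling the underlying operation with the echoed parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .params import Dialect, FiberSpec, Mode, ProbeConfig, SizeConvention, TissueOptics

__all__ = ["RunConfig", "load_config_file", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "core_size": 200.0,
    "numerical_aperture": 0.22,
    "medium_index": 1.0,
    "mode": "single",
    "distance": 0.0,
    "tilt": 0.0,
    "fiber_spacing": 10.0,
    "dialect": "as_printed",
    "size_convention": "as_radius",
    "specular_reflectance": 0.0,
    "diffuse_reflectance": 1.0,
    "escape_ratio": 1.0,
    "d_min": 0.0,
    "d_max": None,  # None -> 5 x core_size
    "step": None,  # None -> d_max / 400
    "band_min": 475.0,
    "band_max": 700.0,
    "noise_sd": 0.0,
    "seed": 0,
}

_FLOAT_KEYS = {
    "core_size",
    "numerical_aperture",
    "medium_index",
    "distance",
    "tilt",
    "fiber_spacing",
    "specular_reflectance",
    "diffuse_reflectance",
    "escape_ratio",
    "d_min",
    "d_max",
    "step",
    "band_min",
    "band_max",
    "noise_sd",
}


def load_config_file(path: str) -> dict[str, Any]:
    """Load a flat key-value YAML config; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return dict(raw)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameters for one run."""

    values: dict[str, Any] = field(default_factory=lambda: dict(DEFAULTS))

    @classmethod
    def resolve(
        cls,
        config_file: str | None = None,
        overrides: Mapping[str, Any] | None = None,
    ) -> "RunConfig":
        """Merge defaults, config file, then non-None overrides (CLI flags)."""
        merged = dict(DEFAULTS)
        if config_file:
            merged.update(load_config_file(config_file))
        for key, val in (overrides or {}).items():
            if val is not None:
                merged[key] = val
        for key in _FLOAT_KEYS:
            if merged[key] is not None:
                merged[key] = float(merged[key])
        merged["seed"] = int(merged["seed"])
        if merged["d_max"] is None:
            merged["d_max"] = 5.0 * merged["core_size"]
        if merged["step"] is None:
            merged["step"] = merged["d_max"] / 400.0
        return cls(values=merged)

    def fiber(self) -> FiberSpec:
        return FiberSpec(
            core_size=self.values["core_size"],
            numerical_aperture=self.values["numerical_aperture"],
            medium_index=self.values["medium_index"],
        )

    def probe(self) -> ProbeConfig:
        return ProbeConfig(
            mode=Mode(self.values["mode"]),
            distance=self.values["distance"],
            tilt=self.values["tilt"],
            fiber_spacing=self.values["fiber_spacing"],
            dialect=Dialect(self.values["dialect"]),
            size_convention=SizeConvention(self.values["size_convention"]),
        )

    def tissue(self) -> TissueOptics:
        return TissueOptics(
            specular_reflectance=self.values["specular_reflectance"],
            diffuse_reflectance=self.values["diffuse_reflectance"],
            escape_ratio=self.values["escape_ratio"],
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header_lines(self, command: str) -> list[str]:
        """Deterministic '# key = value' echo block for output files."""
        lines = [f"# fiberprobe {command}"]
        lines += [f"# {k} = {self.values[k]}" for k in sorted(self.values)]
        lines.append(f"# config_hash = {self.config_hash()}")
        return lines
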