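"""Run configuration: a single YAML document describing a full pipeline run.

A run is reproducible from its config plus the base seed alone: the config
names the connectome source (file or synthetic spec), simulation parameters,
carrier bands, envelope settings, and an optional fit-scan block.  Validation
happens before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .envelopes import CarrierBand, EnvelopeConfig
from .errors import ValidationError
from .simulator import HopfParams


@dataclass
class SyntheticSCSpec:
    n: int = 90
    n_modules: int = 4
    intra_density: float = 1.0
    inter_density: float = 0.25
    weight_tail: float = 0.65
    module_weight_contrast: float = 2.5


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    connectome_file: str | None = None
    connectome_delimiter: str | None = None
    synthetic_sc: SyntheticSCSpec | None = None
    alpha: float = 0.2
    simulation: HopfParams = field(default_factory=lambda: HopfParams(f_f=12.0))
    band_centers: list[float] = field(
        default_factory=lambda: [float(f) for f in range(4, 29, 2)]
    )
    band_half_width: float = 2.0
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    fit: dict | None = None  # optional: {target: path|'self', f_f_values, g_values, bands}
    output_dir: str = "hopfnet_run"
    base_seed: int = 0
    log_level: str = "INFO"

    def bands(self) -> list[CarrierBand]:
        return [CarrierBand(f, self.band_half_width) for f in self.band_centers]

    def validate(self) -> None:
        if (self.connectome_file is None) == (self.synthetic_sc is None):
            raise ValidationError(
                "config must name exactly one connectome source "
                "(connectome_file or synthetic_sc)"
            )
        self.simulation.validate()
        for band in self.bands():
            band.validate(self.simulation.output_rate)
        if self.envelope.env_rate <= 2 * self.envelope.lowpass_cutoff:
            raise ValidationError("env_rate must exceed twice the low-pass cutoff")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValidationError(f"unknown log level {self.log_level!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic_sc" in raw and raw["synthetic_sc"] is not None:
            raw["synthetic_sc"] = SyntheticSCSpec(**raw["synthetic_sc"])
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            raw["simulation"] = HopfParams(**raw["simulation"])
        if "envelope" in raw and isinstance(raw["envelope"], dict):
            raw["envelope"] = EnvelopeConfig(**raw["envelope"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must hold a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
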