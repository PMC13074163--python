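"""Run configuration: YAML blocks per pipeline stage with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "default_config", "load_config"]

_KNOWN_KEYS = {
    "phantom": {
        "grid_shape", "spacing", "noise_sigma", "target_snr", "n_channels",
        "pz_tsc", "tz_tsc", "lesion_tsc", "blood_tsc", "body_tsc",
        "constant_sensitivities",
    },
    "sequence": {
        "tr", "te", "flip_angle", "n_spokes", "n_samples", "nominal_resolution",
    },
    "recon": {
        "kernel_width", "kaiser_beta", "oversampling", "zero_fill", "hanning",
        "ramp_fraction", "fov_mm",
    },
    "combine": {"block_size", "smoothing"},
    "b1": {
        "sigma1", "size1", "sigma2", "size2", "threshold_method",
        "threshold_value", "normalize_map", "enabled",
    },
    "quantify": {
        "blood_tsc", "erosion_mm", "shift_mm", "two_pass_reference",
    },
    "stats": {"power_cases", "min_n_cases", "alpha"},
}
_TOP_LEVEL = set(_KNOWN_KEYS) | {"seed", "out"}


@dataclass
class RunConfig:
    phantom: dict = field(default_factory=dict)
    sequence: dict = field(default_factory=dict)
    recon: dict = field(default_factory=dict)
    combine: dict = field(default_factory=dict)
    b1: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    seed: int = 0
    out: str = "run_output"

    def validate(self) -> "RunConfig":
        for block in _KNOWN_KEYS:
            values = getattr(self, block)
            if not isinstance(values, dict):
                raise ValueError(f"config block {block!r} must be a mapping")
            unknown = set(values) - _KNOWN_KEYS[block]
            if unknown:
                raise ValueError(
                    f"unknown keys in config block {block!r}: {sorted(unknown)}"
                )
        return self

    def to_dict(self) -> dict:
        return {
            **{b: dict(getattr(self, b)) for b in _KNOWN_KEYS},
            "seed": self.seed,
            "out": self.out,
        }


def default_config() -> RunConfig:
    """The study-condition defaults: full-size acquisition, default phantom."""
    return RunConfig(
        phantom={"grid_shape": [64, 64, 64], "spacing": [2.5, 2.5, 2.5],
                 "noise_sigma": 0.0, "n_channels": 16},
        sequence={},
        recon={"kernel_width": 4.0, "oversampling": 2.0, "zero_fill": 2,
               "hanning": False, "ramp_fraction": 0.25},
        combine={"block_size": 8},
        b1={},
        quantify={"blood_tsc": 81.0, "two_pass_reference": True},
        stats={"power_cases": [{"d": 0.99, "n": 9}, {"d": 1.34, "n": 36}],
               "min_n_cases": [{"d": 0.99, "power": 0.8}, {"d": 0.99, "power": 0.9},
                               {"d": 0.5, "power": 0.8}],
               "alpha": 0.05},
    ).validate()


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: raw.get(k, {}) for k in _KNOWN_KEYS},
                    seed=raw.get("seed", 0), out=raw.get("out", "run_output"))
    return cfg.validate()
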