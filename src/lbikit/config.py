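"""Run configuration: YAML/JSON schema with unknown-key rejection."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

_CAMERA_KEYS = {"width", "height", "bit_depth", "pixel_size", "saturation",
                "noise_sigma", "n_frames"}
_CALIBRATION_KEYS = {"mu_s_range_policy", "mu_a_range_policy", "mu_a_map_policy",
                     "scatter_levels_pct", "absorber_levels_pct"}
_FIT_KEYS = {"n_rel", "min_points", "window_floor_fraction"}
_TOP_KEYS = {"camera", "calibration", "fda_basis", "fit", "seed"}


@dataclass
class RunConfig:
    """Validated knobs shared by the command-line entry points."""

    camera: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    fda_basis: str = "linear"
    fit: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name, keys, got in (
            ("camera", _CAMERA_KEYS, self.camera),
            ("calibration", _CALIBRATION_KEYS, self.calibration),
            ("fit", _FIT_KEYS, self.fit),
        ):
            unknown = set(got) - keys
            if unknown:
                raise ConfigError(f"unknown {name} config keys: {sorted(unknown)}")
        if self.fda_basis not in ("linear", "polynomial-2"):
            raise ConfigError(f"unknown fda_basis {self.fda_basis!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
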