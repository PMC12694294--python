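"""Run configuration: every tunable of the pipeline in one place.

Defaults mirror the acquisition and processing conditions the pipeline
is designed for: 201 Hz wearable recordings, a 1 Hz zero-phase
Butterworth low-pass on the altitude channel, altitude-average windows
w1 = 1.25 s / w2 = 2.5 s for the maximum windowed altitude drop, and the
standard-atmosphere reference pressure p0 = 101.325 kPa.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError


def _default_hyperparams() -> dict[str, dict[str, Any]]:
    return {
        "RF": {"n_estimators": 300},
        "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
        "XGB": {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1},
        "LR": {"C": 1.0, "max_iter": 2000},
    }


@dataclass
class RunConfig:
    """All pipeline knobs with their defaults.

    Frequencies in Hz, times in s, pressures in kPa, accelerations in g,
    altitudes in m.
    """

    filter_order: int = 4
    cutoff_hz: float = 1.0
    w1_s: float = 1.25
    w2_s: float = 2.5
    p0_kpa: float = 101.325
    peak_prominence_g: float = 0.5
    peak_separation_s: float = 0.25
    entropy_bins: int = 16
    avm_low_band_hz: tuple[float, float] = (0.5, 3.0)
    avm_high_band_hz: tuple[float, float] = (3.0, 20.0)
    alt_low_band_hz: tuple[float, float] = (0.0, 0.3)
    alt_high_band_hz: tuple[float, float] = (0.3, 1.0)
    delta_h_window_s: float = 1.25  # which window feeds the alt_delta_h feature
    feature_preset: str = "fusion27"
    cv_folds: int = 5
    holdout_fraction: float = 0.2
    seed: int = 20250101
    hyperparams: dict[str, dict[str, Any]] = field(default_factory=_default_hyperparams)

    def __post_init__(self) -> None:
        for name in ("cutoff_hz", "w1_s", "w2_s", "p0_kpa", "peak_prominence_g",
                     "peak_separation_s", "delta_h_window_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.entropy_bins < 2:
            raise ConfigError("entropy_bins must be >= 2")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError("holdout_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # tuples serialize as lists; normalize for hashing/round-trips
        return json.loads(json.dumps(d))

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (embedded in outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | None = None) -> RunConfig:
    """Load a YAML config, failing closed on unknown keys.

    ``path=None`` or an empty file returns all defaults. Unknown keys are
    errors rather than warnings: a silently ignored typo ("cutofff")
    would corrupt benchmark comparability.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("avm_low_band_hz", "avm_high_band_hz", "alt_low_band_hz", "alt_high_band_hz"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def write_schema(path: str) -> None:
    """Write a ``config.schema`` YAML documenting every key and its default."""
    defaults = RunConfig().to_dict()
    with open(path, "w") as fh:
        fh.write("# fallfusion run configuration schema: key -> default value\n")
        fh.write("# frequencies Hz, times s, pressures kPa, accelerations g, altitudes m\n")
        yaml.safe_dump(defaults, fh, sort_keys=True)
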