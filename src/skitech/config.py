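"""Run configuration: one serializable object holding every tunable of the
pipeline (filter cut-offs, marker detection, feature thresholds, rule
thresholds, asymmetry flagging, seed).  YAML round-trips losslessly and
unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .asymmetry import DEFAULT_FLAG_THRESHOLD, DEFAULT_MIN_HALF_CYCLES
from .classify import RuleThresholds
from .features import FeatureParams
from .preprocess import (DEFAULT_ACCEL_CUTOFF_HZ, DEFAULT_FILTER_ORDER,
                         DEFAULT_GYRO_CUTOFF_HZ, DEFAULT_TAP_MAX_GAP_S,
                         DEFAULT_TAP_MIN_GAP_S, DEFAULT_TAP_THRESHOLD_G)
from .synth import MARKER_PREFIX_S


@dataclass(frozen=True)
class MarkerConfig:
    threshold_g: float = DEFAULT_TAP_THRESHOLD_G
    min_gap_s: float = DEFAULT_TAP_MIN_GAP_S
    max_gap_s: float = DEFAULT_TAP_MAX_GAP_S
    #: seconds from marker onset to the start of analysable movement
    #: (taps plus quiet standing).
    trim_after_s: float = MARKER_PREFIX_S


@dataclass(frozen=True)
class AsymmetryConfig:
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD
    min_half_cycles: int = DEFAULT_MIN_HALF_CYCLES


@dataclass
class RunConfig:
    accel_cutoff_hz: float = DEFAULT_ACCEL_CUTOFF_HZ
    gyro_cutoff_hz: float = DEFAULT_GYRO_CUTOFF_HZ
    filter_order: int = DEFAULT_FILTER_ORDER
    marker: MarkerConfig = field(default_factory=MarkerConfig)
    features: FeatureParams = field(default_factory=FeatureParams)
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    asymmetry: AsymmetryConfig = field(default_factory=AsymmetryConfig)
    seed: int = 0
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))


def _build(cls, data: dict, path: str):
    """Construct a (possibly nested) dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or "config"
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = {"marker": MarkerConfig, "features": FeatureParams,
                  "thresholds": RuleThresholds,
                  "asymmetry": AsymmetryConfig}.get(name)
        if target is not None and isinstance(value, dict):
            kwargs[name] = _build(target, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)
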