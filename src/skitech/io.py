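"""Reading and writing trunk-IMU sensor streams and analysis reports.

The interchange format is a plain 7-column CSV holding a uniformly sampled
6-channel recording: three linear-acceleration channels in g (forward,
sideways, upward) and three angular-rate channels in degrees/second (roll,
pitch, yaw), nominally at 100 Hz.  Analysis results are written as JSON
documents with a schema version so reports remain parseable as the rule set
evolves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

#: fixed channel order; readers and writers never reorder or rename.
CHANNELS = ("fwd_a", "side_a", "up_a", "roll", "pitch", "yaw")
ACCEL_CHANNELS = ("fwd_a", "side_a", "up_a")
GYRO_CHANNELS = ("roll", "pitch", "yaw")

#: CSV column names, in file order.
TIME_COLUMN = "time_s"
CSV_COLUMNS = ("time_s", "fwd_a_g", "side_a_g", "up_a_g",
               "roll_dps", "pitch_dps", "yaw_dps")
_COLUMN_TO_CHANNEL = dict(zip(CSV_COLUMNS[1:], CHANNELS))

REPORT_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when a sensor CSV does not match the documented layout."""


@dataclass
class SignalSeries:
    """A uniformly sampled 6-channel IMU recording.

    Parameters
    ----------
    sample_rate_hz:
        Sampling rate shared by all channels, > 0.  Default 100 Hz.
    fwd_a, side_a, up_a:
        Linear acceleration in g (forward/backward, left/right, up/down).
    roll, pitch, yaw:
        Angular rate in degrees/second about the unit's forward, transverse
        and vertical axes.
    meta:
        Free-form annotations (athlete id, technique label if known,
        generator seed, filter provenance, ...).
    """

    fwd_a: np.ndarray
    side_a: np.ndarray
    up_a: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    sample_rate_hz: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(getattr(self, name)) for name in CHANNELS}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        if self.n_samples < 1:
            raise ValueError("channels must contain at least one sample")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.fwd_a)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Implicit sample times: index / sample rate."""
        return np.arange(self.n_samples) / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def channel_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}

    def replace(self, **channels: Any) -> "SignalSeries":
        """Copy with some channels (or meta / rate) replaced."""
        kwargs = {name: getattr(self, name) for name in CHANNELS}
        kwargs["sample_rate_hz"] = self.sample_rate_hz
        kwargs["meta"] = dict(self.meta)
        kwargs.update(channels)
        return SignalSeries(**kwargs)

    def to_frame(self) -> pd.DataFrame:
        data = {TIME_COLUMN: self.times()}
        for col, chan in _COLUMN_TO_CHANNEL.items():
            data[col] = getattr(self, chan)
        return pd.DataFrame(data)


def read_signal_csv(path: str | Path) -> SignalSeries:
    """Read a sensor CSV into a :class:`SignalSeries`.

    The header must name exactly the seven documented columns.  Sample times
    must be strictly increasing and uniform to within 1% of the median step;
    the sample rate is inferred from the median step.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in frame.columns if c not in CSV_COLUMNS]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    if len(frame) < 1:
        raise FormatError(f"{path}: no data rows")

    t = frame[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) > 1:
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise FormatError(f"{path}: time_s is not strictly increasing")
        median_step = float(np.median(steps))
        if np.any(np.abs(steps - median_step) > 0.01 * median_step):
            raise FormatError(
                f"{path}: non-uniform time step (tolerance 1% of median)")
        rate = 1.0 / median_step
    else:
        rate = 100.0

    channels = {chan: frame[col].to_numpy(dtype=float)
                for col, chan in _COLUMN_TO_CHANNEL.items()}
    return SignalSeries(sample_rate_hz=rate,
                        meta={"source": str(path)}, **channels)


def write_signal_csv(series: SignalSeries, path: str | Path) -> None:
    """Write a :class:`SignalSeries` as the documented 7-column CSV.

    Sample times are regenerated as index / sample rate; values are written
    with 6 decimal places.
    """
    series.to_frame().to_csv(Path(path), index=False, float_format="%.6f")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return str(obj)


def write_report(result: Any, path: str | Path) -> None:
    """Serialize a classification or asymmetry result to a JSON report.

    ``result`` may be any object exposing ``to_dict()`` (or a plain mapping);
    the document gains a ``schema_version`` field and is written with stable
    key order so re-serializing a parsed report is byte-idempotent.
    """
    doc = _jsonable(result)
    if not isinstance(doc, dict):
        raise TypeError("report result must serialize to a JSON object")
    doc.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    """Parse a report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
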