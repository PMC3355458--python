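"""Signal conditioning: Butterworth low-pass filtering, tap-marker
localization and analysis-block extraction.

Technique patterns live well below 3 Hz while pole/ski impacts and sensor
noise sit higher, so the conditioning stage is a zero-phase low-pass
Butterworth: 2.0 Hz cut-off for the accelerometer channels and 1.0 Hz for
the gyroscope channels by default.  Zero-phase (forward-backward)
application keeps filtered peaks aligned with the events that caused them,
at the price of a squared magnitude response.

Recordings are synchronized by sharply tapping the sensor unit three times
before the athlete starts moving; :func:`find_tap_marker` localizes that
triple spike on the acceleration magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import ACCEL_CHANNELS, GYRO_CHANNELS, SignalSeries

DEFAULT_ACCEL_CUTOFF_HZ = 2.0
DEFAULT_GYRO_CUTOFF_HZ = 1.0
DEFAULT_FILTER_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """A low-pass Butterworth design.

    ``cutoff_hz`` is the half-power (-3 dB) frequency of a single pass;
    ``zero_phase`` selects forward-backward application (zero net delay,
    squared magnitude response).
    """

    cutoff_hz: float
    order: int = DEFAULT_FILTER_ORDER
    kind: str = "lowpass-butterworth"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        if self.kind != "lowpass-butterworth":
            raise ValueError("only lowpass-butterworth filters are supported")

    def sos(self, sample_rate_hz: float) -> np.ndarray:
        if not self.cutoff_hz < sample_rate_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below the Nyquist "
                f"frequency {sample_rate_hz / 2} Hz")
        return signal.butter(self.order, self.cutoff_hz,
                             btype="lowpass", fs=sample_rate_hz, output="sos")


def default_accel_spec() -> FilterSpec:
    return FilterSpec(DEFAULT_ACCEL_CUTOFF_HZ)


def default_gyro_spec() -> FilterSpec:
    return FilterSpec(DEFAULT_GYRO_CUTOFF_HZ)


def single_pass_gain(spec: FilterSpec, sample_rate_hz: float,
                     freq_hz: float | np.ndarray) -> np.ndarray:
    """Magnitude response of one forward pass at ``freq_hz``."""
    sos = spec.sos(sample_rate_hz)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freq_hz), fs=sample_rate_hz)
    return np.abs(h)


def effective_gain(spec: FilterSpec, sample_rate_hz: float,
                   freq_hz: float | np.ndarray) -> np.ndarray:
    """Amplitude gain actually applied to a sinusoid at ``freq_hz``.

    Squared single-pass magnitude under zero-phase application.
    """
    g = single_pass_gain(spec, sample_rate_hz, freq_hz)
    return g ** 2 if spec.zero_phase else g


def measure_cutoff(spec: FilterSpec, sample_rate_hz: float) -> float:
    """Locate the single-pass half-power (1/sqrt(2)) frequency by bisection.

    The Butterworth magnitude response is monotone decreasing, so bisection
    on the evaluated response converges to the design cut-off.
    """
    target = 1.0 / np.sqrt(2.0)
    lo, hi = 1e-6, sample_rate_hz / 2 * (1 - 1e-9)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if single_pass_gain(spec, sample_rate_hz, mid)[0] > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _filter_channel(x: np.ndarray, spec: FilterSpec,
                    sample_rate_hz: float) -> np.ndarray:
    sos = spec.sos(sample_rate_hz)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def apply_lowpass(series: SignalSeries,
                  accel_spec: FilterSpec | None = None,
                  gyro_spec: FilterSpec | None = None) -> SignalSeries:
    """Low-pass filter all six channels.

    Acceleration channels use ``accel_spec`` (default 2.0 Hz), angular-rate
    channels ``gyro_spec`` (default 1.0 Hz).  Output length equals input
    length; DC gain is exactly 1, so gravity offsets survive.
    """
    accel_spec = accel_spec or default_accel_spec()
    gyro_spec = gyro_spec or default_gyro_spec()
    min_len = 3 * max(accel_spec.order, gyro_spec.order) + 1
    if series.n_samples <= min_len:
        raise ValueError(
            f"series too short to filter: {series.n_samples} samples")
    out = {}
    for name in ACCEL_CHANNELS:
        out[name] = _filter_channel(series.channel(name), accel_spec,
                                    series.sample_rate_hz)
    for name in GYRO_CHANNELS:
        out[name] = _filter_channel(series.channel(name), gyro_spec,
                                    series.sample_rate_hz)
    meta = dict(series.meta)
    meta["filter"] = {
        "accel_cutoff_hz": accel_spec.cutoff_hz,
        "gyro_cutoff_hz": gyro_spec.cutoff_hz,
        "order": accel_spec.order,
        "zero_phase": accel_spec.zero_phase,
    }
    return series.replace(meta=meta, **out)


#: Acceleration-magnitude excursion (above the 1 g static baseline) that
#: counts as a tap, and the allowed spacing between consecutive taps.
DEFAULT_TAP_THRESHOLD_G = 3.0
DEFAULT_TAP_MIN_GAP_S = 0.2
DEFAULT_TAP_MAX_GAP_S = 1.5


def find_tap_marker(series: SignalSeries,
                    threshold_g: float = DEFAULT_TAP_THRESHOLD_G,
                    min_gap_s: float = DEFAULT_TAP_MIN_GAP_S,
                    max_gap_s: float = DEFAULT_TAP_MAX_GAP_S) -> int | None:
    """Locate the three-tap synchronization marker on an unfiltered series.

    Returns the sample index of the first of three acceleration-magnitude
    spikes exceeding ``threshold_g`` above the 1 g gravity baseline, with
    consecutive onsets separated by ``min_gap_s``..``max_gap_s``.  Returns
    ``None`` (no-marker sentinel) when no such triple exists.
    """
    mag = np.sqrt(series.fwd_a ** 2 + series.side_a ** 2 + series.up_a ** 2)
    above = (mag - 1.0) > threshold_g
    if not above.any():
        return None
    # spike onsets: rising edges of the above-threshold mask
    edges = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    fs = series.sample_rate_hz
    gaps = np.diff(edges) / fs
    for i in range(len(edges) - 2):
        if (min_gap_s <= gaps[i] <= max_gap_s
                and min_gap_s <= gaps[i + 1] <= max_gap_s):
            return int(edges[i])
    return None


def select_block(series: SignalSeries, start_s: float,
                 duration_s: float = 10.0) -> SignalSeries:
    """Extract the half-open analysis window [start, start + duration).

    Ten-second blocks are the conventional analysis unit; the window is
    expressed in seconds and converted to samples at the series rate.
    """
    if start_s < 0:
        raise ValueError("start_s must be non-negative")
    fs = series.sample_rate_hz
    i0 = int(round(start_s * fs))
    i1 = int(round((start_s + duration_s) * fs))
    if i1 > series.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + duration_s}) s exceeds the "
            f"{series.duration_s:.2f} s recording")
    out = {name: series.channel(name)[i0:i1] for name in
           ("fwd_a", "side_a", "up_a", "roll", "pitch", "yaw")}
    meta = dict(series.meta)
    meta["block"] = {"start_s": start_s, "duration_s": duration_s}
    return series.replace(meta=meta, **out)
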