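"""Per-recording discriminative features of the segmented, filtered signal.

These quantities realize the published per-technique signature tables:
per-cycle channel peak magnitudes, forward-acceleration peak multiplicity
(major/minor structure), side-acceleration regularity, the poling-to-cycle
ratio, and the circular timing of the yaw peak relative to the pitch peak.
Medians across cycles are used throughout for robustness to cycle-to-cycle
irregularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cycles import CycleSegmentation, detect_peaks
from .io import SignalSeries


@dataclass(frozen=True)
class FeatureParams:
    """Tunable thresholds of the feature stage."""

    fwd_prominence_g: float = 0.05       # FwdA peak detection floor
    fwd_min_separation_s: float = 0.15
    poling_prominence_dps: float = 45.0  # poling pitch peaks
    yaw_prominence_dps: float = 20.0
    sidea_prominence_g: float = 0.1
    sidea_min_peak_g: float = 0.1        # "regular cycle" magnitude floor
    sidea_cv_max: float = 0.5
    sidea_alternation_min: float = 0.9   # fraction of sign alternations
    minor_fraction: float = 0.25         # of the major peak's prominence
    major_fraction: float = 0.6


@dataclass
class FeatureVector:
    """Summary of one segmented recording's discriminative quantities."""

    pitch_peak_dps: float        # median per-cycle |pitch| peak
    roll_peak_dps: float
    yaw_peak_dps: float
    sidea_peak_g: float          # median per-half-cycle |SideA| excursion
    sidea_cv: float
    sidea_regular: bool          # regular alternating skate cycle present
    fwd_peaks_per_cycle: float   # majors + minors, median over cycles
    fwd_major_per_cycle: float
    fwd_major_minor: bool        # distinct major & minor FwdA peaks
    pitch_yaw_ratio: float       # poling pitch peaks per yaw peak
    yaw_pitch_lag: float         # cycle fractions in (-0.5, 0.5]
    yaw_trough_width_ratio: float
    pitch_precedes_fwd: bool

    def __post_init__(self) -> None:
        if not -0.5 < self.yaw_pitch_lag <= 0.5:
            raise ValueError("yaw_pitch_lag must lie in (-0.5, 0.5]")

    def to_dict(self) -> dict:
        return {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                for k, v in self.__dict__.items()}


def _wrap_cycle_fraction(x: np.ndarray | float) -> np.ndarray | float:
    """Map lag(s) in cycle fractions to the principal range (-0.5, 0.5]."""
    w = np.mod(np.asarray(x, dtype=float) + 0.5, 1.0) - 0.5
    w = np.where(w == -0.5, 0.5, w)
    return w if np.ndim(x) else float(w)


def circular_median(lags: np.ndarray) -> float:
    """Median on the circle of unit circumference.

    The returned value is the observed lag minimizing the summed circular
    distance to all others (earliest such lag on ties), wrapped to
    (-0.5, 0.5].
    """
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("circular_median of an empty set")
    dist = np.abs(_wrap_cycle_fraction(lags[:, None] - lags[None, :]))
    best = int(np.argmin(dist.sum(axis=1)))
    return float(_wrap_cycle_fraction(lags[best]))


def _per_cycle_peak_magnitude(x: np.ndarray, seg: CycleSegmentation) -> float:
    return float(np.median([np.max(np.abs(x[b0:b1]))
                            for b0, b1 in seg.cycles()]))


def _cycle_argmax_times(x: np.ndarray, seg: CycleSegmentation,
                        magnitude: bool = False,
                        baseline: float = 0.0) -> np.ndarray:
    """Per-cycle index of the maximum (or maximum-|.|) sample."""
    times = []
    for b0, b1 in seg.cycles():
        window = x[b0:b1] - baseline
        if magnitude:
            window = np.abs(window)
        times.append(b0 + int(np.argmax(window)))
    return np.asarray(times)


def yaw_pitch_timing(series: SignalSeries, seg: CycleSegmentation) -> float:
    """Circular median lag of the yaw extremum after the pitch peak.

    Per cycle, the pitch peak is the maximum pitch sample (poling) and the
    yaw event is the extremum of largest magnitude about the channel
    median — peak or trough, so an athlete leading on the other side
    (inverted yaw) yields the same timing.  Negative lag means yaw precedes
    pitch (single-time signature); positive means yaw follows (offset
    signature).
    """
    if seg.n_cycles < 1:
        raise ValueError("timing needs at least one cycle")
    t_pitch = _cycle_argmax_times(series.pitch, seg)
    yaw_med = float(np.median(series.yaw))
    t_yaw = _cycle_argmax_times(series.yaw, seg, magnitude=True,
                                baseline=yaw_med)
    periods = np.diff(seg.boundaries)
    lags = (t_yaw - t_pitch) / periods
    return circular_median(_wrap_cycle_fraction(lags))


def pitch_fwd_order(series: SignalSeries, seg: CycleSegmentation) -> bool:
    """True iff the poling pitch peak precedes the main FwdA peak."""
    if seg.n_cycles < 1:
        raise ValueError("ordering needs at least one cycle")
    t_pitch = _cycle_argmax_times(series.pitch, seg)
    t_fwd = _cycle_argmax_times(series.fwd_a, seg)
    periods = np.diff(seg.boundaries)
    lags = _wrap_cycle_fraction((t_fwd - t_pitch) / periods)
    return bool(circular_median(lags) > 0)


def _sidea_stats(series: SignalSeries, seg: CycleSegmentation,
                 params: FeatureParams) -> tuple[float, float, bool]:
    """Median half-cycle |SideA| excursion, its CV, and regularity."""
    x = series.side_a
    med = float(np.median(x))
    excursions, signs = [], []
    halves = seg.halves or [(b0, b1, "none") for b0, b1 in seg.cycles()]
    for h0, h1, _ in halves:
        if h1 <= h0:
            continue
        # each half starts at an anchor extremum; read SideA there, since
        # a peak-to-trough half contains both extreme values
        value = x[h0] - med
        excursions.append(abs(value))
        signs.append(np.sign(value))
    excursions = np.asarray(excursions)
    peak = float(np.median(excursions))
    mean = float(np.mean(excursions))
    cv = float(np.std(excursions) / mean) if mean > 0 else float("inf")
    flips = np.asarray(signs[:-1]) != np.asarray(signs[1:])
    alternating = (len(signs) >= 4
                   and float(np.mean(flips)) >= params.sidea_alternation_min)
    regular = bool(alternating and cv < params.sidea_cv_max
                   and peak >= params.sidea_min_peak_g)
    return peak, cv, regular


def _fwd_peak_structure(series: SignalSeries, seg: CycleSegmentation,
                        params: FeatureParams) -> tuple[float, float, bool]:
    """Per-cycle FwdA peak counts: total (major+minor), majors, and
    whether a distinct minor-peak class is present.

    The major class is the largest-prominence peak of the cycle together
    with any peak at >= ``major_fraction`` of it; minors fall in
    [``minor_fraction``, ``major_fraction``); smaller bumps are ignored.
    """
    fs = series.sample_rate_hz
    peaks = detect_peaks(series.fwd_a, params.fwd_prominence_g,
                         params.fwd_min_separation_s, fs, name="fwd_a")
    if len(peaks) == 0:
        return 0.0, 0.0, False
    proms = signal.peak_prominences(series.fwd_a, peaks.indices)[0]
    totals, majors, minors = [], [], []
    for b0, b1 in seg.cycles():
        mask = (peaks.indices >= b0) & (peaks.indices < b1)
        p = proms[mask]
        if p.size == 0:
            totals.append(0)
            majors.append(0)
            minors.append(0)
            continue
        pmax = p.max()
        n_major = int(np.sum(p >= params.major_fraction * pmax))
        n_minor = int(np.sum((p >= params.minor_fraction * pmax)
                             & (p < params.major_fraction * pmax)))
        totals.append(n_major + n_minor)
        majors.append(n_major)
        minors.append(n_minor)
    return (float(np.median(totals)), float(np.median(majors)),
            bool(np.median(minors) >= 1))


def _pitch_yaw_ratio(series: SignalSeries, seg: CycleSegmentation,
                     params: FeatureParams) -> float:
    fs = series.sample_rate_hz
    b0, b1 = seg.boundaries[0], seg.boundaries[-1]
    # magnitude clauses are on peak values; prominence alone would count a
    # low-amplitude oscillation whose peak-to-trough swing clears the bound
    pitch = detect_peaks(series.pitch, params.poling_prominence_dps, 0.2, fs)
    yaw = detect_peaks(series.yaw, params.yaw_prominence_dps, 0.2, fs)
    n_pitch = int(np.sum((pitch.indices >= b0) & (pitch.indices < b1)
                         & (pitch.values >= params.poling_prominence_dps)))
    n_yaw = int(np.sum((yaw.indices >= b0) & (yaw.indices < b1)
                       & (yaw.values >= params.yaw_prominence_dps)))
    return n_pitch / n_yaw if n_yaw else 0.0


def _yaw_width_ratio(series: SignalSeries, params: FeatureParams) -> float:
    """Median yaw trough width over peak width at half prominence."""
    widths = {}
    for sign in (1.0, -1.0):
        y = sign * series.yaw
        idx, _ = signal.find_peaks(y, prominence=params.yaw_prominence_dps)
        if idx.size == 0:
            return float("nan")
        widths[sign] = float(np.median(
            signal.peak_widths(y, idx, rel_height=0.5)[0]))
    return widths[-1.0] / widths[1.0]


def extract_features(series: SignalSeries, seg: CycleSegmentation,
                     params: FeatureParams | None = None) -> FeatureVector:
    """Compute the full feature vector for a filtered, segmented recording."""
    params = params or FeatureParams()
    if seg.n_cycles < 2:
        raise ValueError("feature extraction needs at least 2 cycles")
    sidea_peak, sidea_cv, sidea_regular = _sidea_stats(series, seg, params)
    fwd_total, fwd_major, fwd_mm = _fwd_peak_structure(series, seg, params)
    return FeatureVector(
        pitch_peak_dps=_per_cycle_peak_magnitude(series.pitch, seg),
        roll_peak_dps=_per_cycle_peak_magnitude(series.roll, seg),
        yaw_peak_dps=_per_cycle_peak_magnitude(series.yaw, seg),
        sidea_peak_g=sidea_peak,
        sidea_cv=sidea_cv,
        sidea_regular=sidea_regular,
        fwd_peaks_per_cycle=fwd_total,
        fwd_major_per_cycle=fwd_major,
        fwd_major_minor=fwd_mm,
        pitch_yaw_ratio=_pitch_yaw_ratio(series, seg, params),
        yaw_pitch_lag=yaw_pitch_timing(series, seg),
        yaw_trough_width_ratio=_yaw_width_ratio(series, params),
        pitch_precedes_fwd=pitch_fwd_order(series, seg),
    )
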