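"""Peak detection, movement-cycle segmentation and rate estimation.

A cycle is one full repetition of a technique's movement pattern.  Skating
cycles are anchored on the side-acceleration channel, whose alternating
peaks and troughs identify the left and right skate; classical cycles are
anchored on the yaw channel when a kick signature is present (diagonal
stride, kick double pole), falling back to the poling pitch channel for
double pole, which has no kick and therefore no defined sides.  The cycle
convention is peak-to-peak on the anchor channel, with half-open,
0-based sample intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import SignalSeries

#: anchor-peak prominence floors: skating side acceleration (g) and
#: classical yaw / fallback pitch (d/s; kick-free yaw stays below 20 d/s).
SIDEA_ANCHOR_PROMINENCE_G = 0.1
GYRO_ANCHOR_PROMINENCE_DPS = 20.0
#: pitch-peak prominence that separates poling (>= 50 d/s clauses) from the
#: no-poling free skate (< 40 d/s clause) with margin on both sides.
POLING_PROMINENCE_DPS = 45.0
#: anchor peaks of distinct cycles are never closer than this.
ANCHOR_MIN_SEPARATION_S = 0.4


class SegmentationError(ValueError):
    """Raised when a recording has no usable cyclical structure."""


@dataclass
class PeakList:
    """Detected local extrema of one channel."""

    channel: str
    indices: np.ndarray
    values: np.ndarray
    polarity: str = "peak"  # or "trough"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.polarity not in ("peak", "trough"):
            raise ValueError("polarity must be 'peak' or 'trough'")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class CycleSegmentation:
    """Half-open cycles [b_i, b_{i+1}) with optional per-half side labels."""

    boundaries: np.ndarray               # n_cycles + 1 anchor-peak indices
    anchor_channel: str
    halves: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if len(self.boundaries) < 2:
            raise ValueError("a segmentation needs at least one cycle")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def cycles(self) -> list[tuple[int, int]]:
        b = self.boundaries
        return [(int(b[i]), int(b[i + 1])) for i in range(self.n_cycles)]

    @property
    def side_labels(self) -> list[str]:
        return [label for _, _, label in self.halves]

    def to_dict(self) -> dict:
        return {
            "anchor_channel": self.anchor_channel,
            "boundaries": self.boundaries.tolist(),
            "halves": [[int(a), int(b), s] for a, b, s in self.halves],
        }


def detect_peaks(channel: np.ndarray, min_prominence: float,
                 min_separation_s: float, sample_rate_hz: float,
                 polarity: str = "peak", name: str = "") -> PeakList:
    """Local extrema with topographic prominence >= ``min_prominence`` and
    pairwise separation >= ``min_separation_s``.

    Troughs are found by negation.  Plateau ties break toward the earlier
    sample.
    """
    x = np.asarray(channel, dtype=float)
    if x.size == 0:
        raise ValueError("cannot detect peaks on an empty channel")
    if not min_prominence > 0:
        raise ValueError("min_prominence must be positive")
    y = -x if polarity == "trough" else x
    distance = max(1, int(round(min_separation_s * sample_rate_hz)))
    idx, props = signal.find_peaks(y, prominence=min_prominence,
                                   distance=distance,
                                   plateau_size=(1, None))
    left = props.get("left_edges", idx)
    return PeakList(channel=name, indices=left, values=x[left],
                    polarity=polarity)


def _anchor_extrema(x: np.ndarray, prominence: float,
                    sample_rate_hz: float) -> tuple[PeakList, PeakList]:
    peaks = detect_peaks(x, prominence, ANCHOR_MIN_SEPARATION_S,
                         sample_rate_hz)
    troughs = detect_peaks(x, prominence, ANCHOR_MIN_SEPARATION_S,
                           sample_rate_hz, polarity="trough")
    return peaks, troughs


def segment_cycles(series: SignalSeries, family: str) -> CycleSegmentation:
    """Segment a *filtered* recording into technique cycles.

    ``family`` is ``"skating"`` or ``"classical"``.  Skating anchors on the
    side-acceleration channel and labels the peak half-cycle L and the
    trough half R.  Classical anchors on yaw when a kick signature is
    detectable (peak prominence >= 20 d/s), labelling kick sides the same
    way; otherwise it falls back to pitch with no side labels (double
    pole).
    """
    fs = series.sample_rate_hz
    if family == "skating":
        anchor = "side_a"
        peaks, troughs = _anchor_extrema(series.side_a,
                                         SIDEA_ANCHOR_PROMINENCE_G, fs)
        sided = True
    elif family == "classical":
        anchor = "yaw"
        peaks, troughs = _anchor_extrema(series.yaw,
                                         GYRO_ANCHOR_PROMINENCE_DPS, fs)
        sided = True
        # a kick signature needs yaw peaks *reaching* 20 d/s, not merely
        # prominent ones (kick-free yaw stays below 20 d/s in magnitude)
        if len(peaks) >= 2 and np.median(
                np.abs(peaks.values)) < GYRO_ANCHOR_PROMINENCE_DPS:
            peaks = PeakList(channel="yaw", indices=[], values=[])
        if len(peaks) < 2:  # no kick signature: double pole, pitch anchor
            anchor = "pitch"
            peaks, troughs = _anchor_extrema(series.pitch,
                                             GYRO_ANCHOR_PROMINENCE_DPS, fs)
            sided = False
    else:
        raise ValueError("family must be 'skating' or 'classical'")

    if len(peaks) < 2:
        raise SegmentationError(
            f"no cyclical structure on {anchor}: "
            f"{len(peaks)} anchor peak(s) found")

    boundaries = peaks.indices
    if len(boundaries) >= 4:
        spans = np.diff(boundaries)
        cv = float(np.std(spans) / np.mean(spans))
        if cv > 0.4:
            raise SegmentationError(
                f"irregular cycle durations on {anchor} "
                f"(CV {cv:.2f}); no cyclical structure")
    halves: list[tuple[int, int, str]] = []
    trough_idx = troughs.indices
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        inside = trough_idx[(trough_idx > b0) & (trough_idx < b1)]
        if inside.size:
            mid = int(inside[np.argmin(np.abs(inside - (b0 + b1) / 2))])
        else:
            mid = int((b0 + b1) // 2)
        first, second = ("L", "R") if sided else ("none", "none")
        halves.append((int(b0), mid, first))
        halves.append((mid, int(b1), second))
    return CycleSegmentation(boundaries=boundaries, anchor_channel=anchor,
                             halves=halves)


def cycle_rate(seg: CycleSegmentation, sample_rate_hz: float) -> float:
    """Cycles per second over the segmented span."""
    if len(seg.boundaries) < 2:
        raise ValueError("cycle rate needs at least two boundaries")
    span_s = (seg.boundaries[-1] - seg.boundaries[0]) / sample_rate_hz
    return seg.n_cycles / span_s


def poling_rate(series: SignalSeries, seg: CycleSegmentation,
                prominence_dps: float = POLING_PROMINENCE_DPS
                ) -> tuple[float, float]:
    """Poling actions per second and per cycle.

    Poling manifests as large pitch peaks; peaks above the poling
    prominence within the segmented span are counted.  Returns
    ``(rate_hz, peaks_per_cycle)``; both 0 when no peaks clear the bound.
    """
    fs = series.sample_rate_hz
    peaks = detect_peaks(series.pitch, prominence_dps, 0.2, fs, name="pitch")
    b0, b1 = seg.boundaries[0], seg.boundaries[-1]
    # a poling peak must *reach* the bound, not merely be that prominent
    count = int(np.sum((peaks.indices >= b0) & (peaks.indices < b1)
                       & (peaks.values >= prominence_dps)))
    span_s = (b1 - b0) / fs
    return count / span_s, count / seg.n_cycles
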