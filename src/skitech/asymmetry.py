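"""Left/right movement asymmetry from side-labelled cycle halves.

A one-sided inefficiency shows up as a systematically lower forward
acceleration and higher upward acceleration on the affected side's kick.
The index used is the standard mean-normalized limb-symmetry difference
(mean_L - mean_R) / ((mean_L + mean_R) / 2), computed on per-half-cycle
peak excursions about the channel median (so gravity offsets cancel), for
the forward, upward and roll channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cycles import CycleSegmentation, detect_peaks
from .io import SignalSeries

ASYMMETRY_CHANNELS = ("fwd_a", "up_a", "roll")
DEFAULT_FLAG_THRESHOLD = 0.15
DEFAULT_MIN_HALF_CYCLES = 3


@dataclass
class SideProfiles:
    """Per-side, per-half-cycle peak excursions for the asymmetry channels."""

    values: dict[str, dict[str, np.ndarray]]
    n_half_cycles: dict[str, int]


@dataclass
class AsymmetryReport:
    """Per-channel side means and symmetry indices."""

    channels: dict[str, dict[str, float]]  # mean_L, mean_R, index
    n_half_cycles: dict[str, int]
    flag_threshold: float
    flagged: bool
    label: str = "asymmetry"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "channels": self.channels,
            "n_half_cycles": dict(self.n_half_cycles),
            "flag_threshold": self.flag_threshold,
            "flagged": self.flagged,
        }


#: extremum-detection floors for the asymmetry channels.
_PROMINENCE = {"fwd_a": 0.05, "up_a": 0.03, "roll": 5.0}


def side_profiles(series: SignalSeries,
                  seg: CycleSegmentation) -> SideProfiles:
    """Collect per-half-cycle peak excursions by side.

    Only detected local extrema are scored, each assigned to the half that
    contains its sample, so values approaching the next half's extremum at
    a window edge never leak across sides.  Forward and upward channels
    score their positive peaks above the channel median (the quantities
    that drop on an inefficient kick); roll scores the magnitude of its
    dominant extremum, peak or trough, since the two sides express roll
    with opposite sign.  Requires a segmentation with L/R labels:
    techniques without defined sides (double pole) have none.
    """
    sides_present = {label for _, _, label in seg.halves}
    if not {"L", "R"} <= sides_present:
        raise ValueError("technique has no defined sides")
    fs = series.sample_rate_hz
    collected: dict[str, dict[str, list[float]]] = {
        c: {"L": [], "R": []} for c in ASYMMETRY_CHANNELS}
    counts = {"L": 0, "R": 0}
    for h0, h1, label in seg.halves:
        if label in ("L", "R") and h1 > h0:
            counts[label] += 1

    for c in ASYMMETRY_CHANNELS:
        x = series.channel(c)
        # accel channels are referenced to their median (removes the
        # gravity offset); the angular-rate baseline is physically 0 d/s
        med = float(np.median(x)) if c != "roll" else 0.0
        extrema: list[tuple[int, float]] = []
        for polarity in ("peak", "trough"):
            if c != "roll" and polarity == "trough":
                continue
            pl = detect_peaks(x, _PROMINENCE[c], 0.1, fs, polarity=polarity)
            extrema.extend((int(i), abs(float(v) - med) if c == "roll"
                            else float(v) - med)
                           for i, v in zip(pl.indices, pl.values))
        for h0, h1, label in seg.halves:
            if label not in ("L", "R") or h1 <= h0:
                continue
            inside = [v for i, v in extrema if h0 <= i < h1]
            if inside:
                collected[c][label].append(max(inside))
    values = {c: {s: np.asarray(v) for s, v in sides.items()}
              for c, sides in collected.items()}
    return SideProfiles(values=values, n_half_cycles=counts)


def asymmetry_index(profiles: SideProfiles,
                    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
                    min_half_cycles: int = DEFAULT_MIN_HALF_CYCLES
                    ) -> AsymmetryReport:
    """Mean-normalized L/R difference per channel, with a flag when any
    |index| exceeds ``flag_threshold`` (a reporting convention, not a
    clinical bound)."""
    for side in ("L", "R"):
        if profiles.n_half_cycles[side] < min_half_cycles:
            raise ValueError(
                f"need >= {min_half_cycles} half-cycles per side, got "
                f"{profiles.n_half_cycles[side]} on {side}")
    channels: dict[str, dict[str, float]] = {}
    flagged = False
    for c, sides in profiles.values.items():
        mean_l = float(np.mean(sides["L"]))
        mean_r = float(np.mean(sides["R"]))
        denom = 0.5 * (mean_l + mean_r)
        index = (mean_l - mean_r) / denom if denom > 0 else 0.0
        channels[c] = {"mean_L": mean_l, "mean_R": mean_r, "index": index}
        flagged = flagged or abs(index) > flag_threshold
    return AsymmetryReport(channels=channels,
                           n_half_cycles=profiles.n_half_cycles,
                           flag_threshold=flag_threshold, flagged=flagged)


def swap_sides(profiles: SideProfiles) -> SideProfiles:
    """Relabel L as R and vice versa (sign convention check helper)."""
    return SideProfiles(
        values={c: {"L": sides["R"], "R": sides["L"]}
                for c, sides in profiles.values.items()},
        n_half_cycles={"L": profiles.n_half_cycles["R"],
                       "R": profiles.n_half_cycles["L"]})
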