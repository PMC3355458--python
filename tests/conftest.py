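"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from skitech import (CHANNELS, SignalSeries, TechniqueLabel, apply_lowpass,
                     default_params, find_tap_marker, generate,
                     segment_cycles, select_block)

ALL_TECHNIQUES = ("DP", "KDP", "DS", "G2", "G3", "G4", "G5")


def prepare(technique: str, seed: int = 1, **overrides):
    """Generate, marker-trim, filter and segment one default recording."""
    series = generate(default_params(technique, seed=seed, **overrides))
    marker = find_tap_marker(series)
    fs = series.sample_rate_hz
    start = marker / fs + 3.5
    trimmed = select_block(series, start, series.duration_s - start)
    filtered = apply_lowpass(trimmed)
    family = TechniqueLabel(technique).family
    seg = segment_cycles(filtered,
                         "skating" if family == "skating" else "classical")
    return filtered, seg


@pytest.fixture(scope="session")
def prepared():
    """Session-cached (filtered, segmentation) per technique at seed 1."""
    return {t: prepare(t, seed=1) for t in ALL_TECHNIQUES}


def noise_series(seed: int = 0, n: int = 2000, accel_sd: float = 0.05,
                 gyro_sd: float = 5.0) -> SignalSeries:
    """Structureless sensor-scale white noise on all six channels."""
    rng = np.random.default_rng(seed)
    data = {}
    for i, name in enumerate(CHANNELS):
        sd = accel_sd if i < 3 else gyro_sd
        data[name] = rng.normal(0.0, sd, n)
    return SignalSeries(**data)


# --- independent O(n^2) peak oracle -------------------------------------

def _plateau_maxima(x: np.ndarray) -> list[tuple[int, int]]:
    """(left_edge, midpoint) of every interior local maximum/plateau."""
    out = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append((i, (i + j) // 2))
            i = j + 1
        else:
            i += 1
    return out


def _prominence(x: np.ndarray, mid: int) -> float:
    """Topographic prominence by exhaustive scan to the nearest higher
    ground on each side (signal border otherwise)."""
    peak = x[mid]
    mins = []
    for step in (-1, 1):
        j = mid + step
        lowest = peak
        while 0 <= j < len(x) and x[j] <= peak:
            lowest = min(lowest, x[j])
            j += step
        mins.append(lowest)
    return peak - max(mins)


def oracle_peaks(x: np.ndarray, min_prominence: float,
                 distance: int) -> np.ndarray:
    """Brute-force reference for peak detection: local maxima (plateau
    left edge), highest-first distance pruning, then prominence filter."""
    x = np.asarray(x, dtype=float)
    cands = _plateau_maxima(x)
    # highest first; among equal heights the later peak wins the window
    order = sorted(range(len(cands)),
                   key=lambda k: (x[cands[k][1]], cands[k][1]),
                   reverse=True)
    kept_mids: list[int] = []
    kept: list[tuple[int, int]] = []
    for k in order:
        left, mid = cands[k]
        if all(abs(mid - m) >= distance for m in kept_mids):
            kept_mids.append(mid)
            kept.append((left, mid))
    survivors = [left for left, mid in kept
                 if _prominence(x, mid) >= min_prominence]
    return np.asarray(sorted(survivors), dtype=int)
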