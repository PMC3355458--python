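"""Filter design, tap-marker localization and block extraction."""

import itertools

import numpy as np
import pytest

from skitech import (CHANNELS, FilterSpec, SignalSeries, apply_lowpass,
                     find_tap_marker, measure_cutoff, select_block,
                     single_pass_gain)
from skitech.preprocess import effective_gain

from .conftest import noise_series


def _sine_series(freq_hz: float, duration_s: float = 20.0,
                 fs: float = 100.0, amplitude: float = 1.0) -> SignalSeries:
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return SignalSeries(**{c: x.copy() for c in CHANNELS},
                        sample_rate_hz=fs)


def test_constant_input_passes_unchanged():
    series = SignalSeries(**{c: np.full(500, 3.25) for c in CHANNELS})
    out = apply_lowpass(series)
    for name in CHANNELS:
        np.testing.assert_allclose(out.channel(name), 3.25, atol=1e-9)


def test_stopband_and_passband_match_frequency_response_oracle():
    # measured attenuation of a pure tone equals the design's evaluated
    # zero-phase gain at that frequency
    spec = FilterSpec(2.0)
    for freq, rtol in ((8.0, None), (0.5, 0.02)):
        series = _sine_series(freq)
        out = apply_lowpass(series, accel_spec=spec)
        core = slice(300, 1700)  # avoid edge transients
        measured = np.max(np.abs(out.fwd_a[core]))
        expected = effective_gain(spec, 100.0, freq)[0]
        if rtol is None:
            assert measured < 0.01          # 8 Hz tone essentially removed
            assert expected < 0.001
        else:
            assert measured == pytest.approx(1.0, rel=rtol)
            assert measured == pytest.approx(expected, rel=0.01)


def test_attenuation_at_twice_cutoff_exceeds_40_db():
    for cutoff in (1.0, 2.0):
        gain = effective_gain(FilterSpec(cutoff), 100.0, 2 * cutoff)[0]
        assert 20 * np.log10(gain) < -40.0


def test_passband_filtering_near_idempotent():
    series = _sine_series(0.5)
    once = apply_lowpass(series)
    twice = apply_lowpass(once)
    core = slice(300, 1700)
    a1 = np.max(np.abs(once.fwd_a[core]))
    a2 = np.max(np.abs(twice.fwd_a[core]))
    assert abs(a2 - a1) / a1 < 0.04


@pytest.mark.parametrize("cutoff, tol", [(2.0, 0.01), (1.0, 0.005)])
def test_measured_halfpower_frequency_matches_design(cutoff, tol):
    assert measure_cutoff(FilterSpec(cutoff), 100.0) == pytest.approx(
        cutoff, abs=tol)


def test_measured_cutoff_independent_of_sample_rate():
    spec = FilterSpec(2.0)
    assert measure_cutoff(spec, 200.0) == pytest.approx(
        measure_cutoff(spec, 100.0), rel=1e-3)


def test_zero_phase_keeps_peak_location():
    fs = 100.0
    n = 1000
    t = np.arange(n) / fs
    x = np.exp(-0.5 * ((t - 5.0) / 0.4) ** 2)  # isolated symmetric peak
    series = SignalSeries(**{c: x.copy() for c in CHANNELS},
                          sample_rate_hz=fs)
    out = apply_lowpass(series)
    assert abs(int(np.argmax(out.fwd_a)) - int(np.argmax(x))) <= 1


def test_cutoff_above_nyquist_rejected():
    series = noise_series(n=500)
    with pytest.raises(ValueError):
        apply_lowpass(series, accel_spec=FilterSpec(60.0))


def test_too_short_series_rejected():
    short = SignalSeries(**{c: np.zeros(10) for c in CHANNELS})
    with pytest.raises(ValueError):
        apply_lowpass(short)


# --- tap marker ---------------------------------------------------------

def _with_spikes(onsets_samples, n=2000, spike=5.0, width=5):
    data = {c: np.zeros(n) for c in CHANNELS}
    data["fwd_a"] += 1.0  # upright gravity baseline
    for i0 in onsets_samples:
        data["fwd_a"][i0:i0 + width] += spike
    return SignalSeries(**data)


def test_marker_found_at_first_spike():
    series = _with_spikes([50, 100, 150])
    assert find_tap_marker(series) == 50


def test_quiet_standing_has_no_marker():
    series = _with_spikes([])
    assert find_tap_marker(series) is None


def test_two_spikes_is_not_a_marker():
    assert find_tap_marker(_with_spikes([50, 100])) is None


def test_marker_agrees_with_brute_force_triple_scan():
    # oracle: the first run of three consecutive spike onsets whose two
    # gaps both fall in the 0.2-1.5 s window
    def oracle(onsets):
        s = sorted(onsets)
        for i in range(len(s) - 2):
            if all(0.2 <= (b - a) / 100.0 <= 1.5
                   for a, b in zip(s[i:i + 3], s[i + 1:i + 3])):
                return s[i]
        return None

    for onsets in itertools.combinations([30, 80, 200, 260, 320, 1900], 3):
        series = _with_spikes(list(onsets))
        assert find_tap_marker(series) == oracle(onsets), onsets


def test_generated_recordings_carry_a_marker():
    from skitech import default_params, generate
    series = generate(default_params("G4", seed=3))
    idx = find_tap_marker(series)
    assert idx is not None
    assert idx / series.sample_rate_hz == pytest.approx(0.25, abs=0.05)


# --- block selection ----------------------------------------------------

def test_ten_second_block_has_thousand_samples():
    series = noise_series(n=2000)
    block = select_block(series, 5.0, 10.0)
    assert block.n_samples == 1000
    np.testing.assert_array_equal(block.fwd_a, series.fwd_a[500:1500])


def test_full_length_block_is_identity():
    series = noise_series(n=2000)
    block = select_block(series, 0.0, 20.0)
    assert block.n_samples == series.n_samples
    np.testing.assert_array_equal(block.yaw, series.yaw)


def test_out_of_range_block_rejected():
    series = noise_series(n=2000)
    with pytest.raises(ValueError):
        select_block(series, 15.0, 10.0)
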