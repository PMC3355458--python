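"""Feature extraction: the per-technique signature conformance matrix,
timing features, and invariances."""

import numpy as np
import pytest

from skitech import extract_features, pitch_fwd_order, yaw_pitch_timing
from skitech.cycles import segment_cycles
from skitech.features import circular_median

from .conftest import prepare

# Conformance matrix: every quantitative signature clause per technique,
# evaluated on the default generated-and-filtered recordings.
SIGNATURES = {
    "DP":  dict(pitch_min=75, roll_max=20, sidea_regular=False,
                fwd_per_cycle=1, pitch_precedes_fwd=True),
    "KDP": dict(pitch_min=75, roll_min=20, sidea_regular=False,
                fwd_per_cycle=2, fwd_major_minor=True,
                pitch_precedes_fwd=True),
    "DS":  dict(pitch_max=50, roll_min=20, sidea_regular=False,
                fwd_per_cycle=2),
    "G2":  dict(pitch_min=50, roll_min=50, sidea_regular=True,
                lag_sign=+1, pitch_precedes_fwd=True),
    "G3":  dict(pitch_min=75, sidea_regular=True, ratio=2.0,
                fwd_per_cycle=2, pitch_precedes_fwd=True),
    "G4":  dict(pitch_min=75, sidea_regular=True, ratio=1.0,
                lag_sign=-1, fwd_major_minor=True, trough_wider=True,
                pitch_precedes_fwd=True),
    "G5":  dict(pitch_max=40, roll_min=50, sidea_regular=True,
                fwd_per_cycle=2),
}


@pytest.mark.parametrize("technique", sorted(SIGNATURES))
def test_signature_conformance(technique, prepared):
    filtered, seg = prepared[technique]
    fv = extract_features(filtered, seg)
    sig = SIGNATURES[technique]
    if "pitch_min" in sig:
        assert fv.pitch_peak_dps >= sig["pitch_min"]
    if "pitch_max" in sig:
        assert fv.pitch_peak_dps <= sig["pitch_max"]
    if "roll_min" in sig:
        assert fv.roll_peak_dps >= sig["roll_min"]
    if "roll_max" in sig:
        assert fv.roll_peak_dps <= sig["roll_max"]
    assert fv.sidea_regular == sig["sidea_regular"]
    if "fwd_per_cycle" in sig:
        assert fv.fwd_peaks_per_cycle == pytest.approx(
            sig["fwd_per_cycle"], abs=0.5)
    if "fwd_major_minor" in sig:
        assert fv.fwd_major_minor == sig["fwd_major_minor"]
    if "ratio" in sig:
        assert fv.pitch_yaw_ratio == pytest.approx(sig["ratio"], abs=0.1)
    if "lag_sign" in sig:
        assert np.sign(fv.yaw_pitch_lag) == sig["lag_sign"]
    if "trough_wider" in sig:
        assert fv.yaw_trough_width_ratio > 1.0
    if "pitch_precedes_fwd" in sig:
        assert fv.pitch_precedes_fwd == sig["pitch_precedes_fwd"]


def test_zero_noise_diagonal_stride_has_exactly_two_fwd_peaks():
    filtered, seg = prepare("DS", seed=1, noise_sd_g=0.0, noise_sd_dps=0.0,
                            hf_noise_g=0.0, hf_noise_dps=0.0)
    fv = extract_features(filtered, seg)
    assert fv.fwd_peaks_per_cycle == 2.0


@pytest.mark.parametrize("technique, expected", [
    ("G4", -0.10),   # yaw peak precedes the pitch peak
    ("G2", +0.05),   # yaw peak just after the pitch peak
])
def test_yaw_pitch_lag_recovers_generator_phase(technique, expected,
                                                prepared):
    filtered, seg = prepared[technique]
    assert yaw_pitch_timing(filtered, seg) == pytest.approx(expected,
                                                            abs=0.03)


def test_identical_pitch_and_yaw_have_zero_lag(prepared):
    filtered, seg = prepared["G4"]
    twin = filtered.replace(yaw=filtered.pitch.copy())
    assert yaw_pitch_timing(twin, seg) == pytest.approx(0.0, abs=0.01)


def test_pitch_fwd_order_antisymmetric(prepared):
    filtered, seg = prepared["DP"]
    assert pitch_fwd_order(filtered, seg) is True
    swapped = filtered.replace(pitch=filtered.fwd_a.copy(),
                               fwd_a=filtered.pitch.copy())
    assert pitch_fwd_order(swapped, seg) is False


def test_features_invariant_to_dropping_a_leading_cycle(prepared):
    filtered, seg = prepared["G4"]
    fv0 = extract_features(filtered, seg)
    cut = seg.boundaries[1]  # drop exactly one cycle from the front
    shifted = filtered.replace(
        **{c: filtered.channel(c)[cut:] for c in
           ("fwd_a", "side_a", "up_a", "roll", "pitch", "yaw")})
    seg2 = segment_cycles(shifted, "skating")
    fv1 = extract_features(shifted, seg2)
    assert fv1.pitch_peak_dps == pytest.approx(fv0.pitch_peak_dps, rel=0.03)
    assert fv1.roll_peak_dps == pytest.approx(fv0.roll_peak_dps, rel=0.03)
    assert fv1.sidea_peak_g == pytest.approx(fv0.sidea_peak_g, rel=0.03)
    assert fv1.yaw_pitch_lag == pytest.approx(fv0.yaw_pitch_lag, abs=0.02)
    assert fv1.pitch_yaw_ratio == pytest.approx(fv0.pitch_yaw_ratio,
                                                abs=0.15)


def test_amplitude_features_scale_with_gain(prepared):
    filtered, seg = prepared["G3"]
    fv0 = extract_features(filtered, seg)
    doubled = filtered.replace(
        **{c: 2.0 * filtered.channel(c) for c in
           ("fwd_a", "side_a", "up_a", "roll", "pitch", "yaw")})
    fv2 = extract_features(doubled, seg)
    assert fv2.pitch_peak_dps == pytest.approx(2 * fv0.pitch_peak_dps,
                                               rel=0.01)
    assert fv2.roll_peak_dps == pytest.approx(2 * fv0.roll_peak_dps,
                                              rel=0.01)
    assert fv2.sidea_peak_g == pytest.approx(2 * fv0.sidea_peak_g, rel=0.01)


def test_too_few_cycles_rejected(prepared):
    filtered, seg = prepared["G4"]
    from skitech.cycles import CycleSegmentation
    one_cycle = CycleSegmentation(boundaries=seg.boundaries[:2],
                                  anchor_channel=seg.anchor_channel,
                                  halves=seg.halves[:2])
    with pytest.raises(ValueError):
        extract_features(filtered, one_cycle)


def test_circular_median_handles_wraparound():
    lags = np.array([0.48, 0.49, -0.49, -0.48, 0.50])
    med = circular_median(lags)
    assert abs(med) >= 0.48  # near the wrap point, not near zero
    assert circular_median(np.array([0.1])) == pytest.approx(0.1)
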