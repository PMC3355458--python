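"""Generator behaviour: gravity model, template defaults, determinism,
fixture grid, and the trunk-lean gradient effect."""

import math

import numpy as np
import pytest

from skitech import (CHANNELS, GenParams, TechniqueLabel, default_params,
                     generate, gravity_components, make_fixture_set)
from skitech.synth import MARKER_PREFIX_S

from .conftest import ALL_TECHNIQUES


@pytest.mark.parametrize("lean, expected", [
    (0.0, (1.0, 0.0)),       # upright: forward channel carries all of gravity
    (90.0, (0.0, 1.0)),      # fully forward: upward channel carries it
    (30.0, (0.8660, 0.5000)),
])
def test_gravity_components(lean, expected):
    fwd, up = gravity_components(lean)
    assert fwd == pytest.approx(expected[0], abs=1e-4)
    assert up == pytest.approx(expected[1], abs=1e-4)


@pytest.mark.parametrize("lean", [-1.0, 90.5, 180.0])
def test_gravity_domain_error(lean):
    with pytest.raises(ValueError):
        gravity_components(lean)


def test_default_pitch_amplitudes_respect_published_bounds():
    assert default_params("DP").amp["pitch"] == 100.0 > 75.0
    assert default_params("G5").amp["pitch"] == 25.0 < 40.0
    assert default_params("DS").amp["pitch"] == 40.0 < 50.0
    assert default_params("G2").amp["roll"] == 60.0 > 50.0


def test_family_attribute():
    assert TechniqueLabel.DS.family == "classical"
    assert all(TechniqueLabel(g).family == "skating"
               for g in ("G2", "G3", "G4", "G5"))


def test_seed_determinism():
    a = generate(default_params("G3", seed=5))
    b = generate(default_params("G3", seed=5))
    c = generate(default_params("G3", seed=6))
    for name in CHANNELS:
        np.testing.assert_array_equal(a.channel(name), b.channel(name))
    assert not np.array_equal(a.fwd_a, c.fwd_a)


def test_quiet_standing_prefix_reads_gravity():
    series = generate(default_params("DP", seed=1))
    fs = series.sample_rate_hz
    i0, i1 = int(1.5 * fs), int(MARKER_PREFIX_S * fs)
    assert np.mean(series.fwd_a[i0:i1]) == pytest.approx(
        math.cos(math.radians(15.0)), abs=0.02)


@pytest.mark.parametrize("lean", [0.0, 20.0, 63.0, 90.0])
def test_gravity_norm_without_movement_or_noise(lean):
    params = default_params(
        "DS", seed=0, amp={c: 0.0 for c in CHANNELS}, noise_sd_g=0.0,
        noise_sd_dps=0.0, trunk_lean_deg=lean, tap_marker=False)
    series = generate(params)
    norm = np.sqrt(series.fwd_a ** 2 + series.side_a ** 2
                   + series.up_a ** 2)
    np.testing.assert_allclose(norm, 1.0, atol=1e-9)


def test_lean_monotonically_shifts_gravity_between_fwd_and_up():
    leans = [0.0, 10.0, 20.0, 30.0, 45.0]
    fwd_means, up_means = [], []
    for lean in leans:
        s = generate(default_params("DS", seed=2, trunk_lean_deg=lean,
                                    tap_marker=False))
        fwd_means.append(np.mean(s.fwd_a))
        up_means.append(np.mean(s.up_a))
    assert all(a > b for a, b in zip(fwd_means, fwd_means[1:]))
    assert all(a < b for a, b in zip(up_means, up_means[1:]))


def test_g3_pitch_runs_at_twice_the_cycle_frequency():
    s = generate(default_params("G3", seed=1, noise_sd_g=0.0,
                                noise_sd_dps=0.0, hf_noise_g=0.0,
                                hf_noise_dps=0.0, tap_marker=False))
    pitch_up = int(np.sum((s.pitch[:-1] < 0) & (s.pitch[1:] >= 0)))
    side = s.side_a - np.mean(s.side_a)
    side_up = int(np.sum((side[:-1] < 0) & (side[1:] >= 0)))
    assert pitch_up == pytest.approx(2 * side_up, abs=2)


def test_duration_shorter_than_one_cycle_rejected():
    with pytest.raises(ValueError, match="cycle"):
        generate(default_params("DP", duration_s=1.0, cycle_rate_hz=0.5))


def test_fixture_set_counts_and_determinism():
    fx1 = make_fixture_set(seed=7, n_per_technique=3, duration_s=10.0)
    fx2 = make_fixture_set(seed=7, n_per_technique=3, duration_s=10.0)
    assert len(fx1) == 21
    labels = [label.value for _, label in fx1]
    assert all(labels.count(t) == 3 for t in ALL_TECHNIQUES)
    for (s1, l1), (s2, l2) in zip(fx1, fx2):
        assert l1 == l2
        np.testing.assert_array_equal(s1.fwd_a, s2.fwd_a)
        np.testing.assert_array_equal(s1.yaw, s2.yaw)


def test_g2_left_lead_inverts_yaw_and_roll():
    base = dict(seed=9, noise_sd_g=0.0, noise_sd_dps=0.0,
                hf_noise_g=0.0, hf_noise_dps=0.0, tap_marker=False)
    right = generate(default_params("G2", lead_side="R", **base))
    left = generate(default_params("G2", lead_side="L", **base))
    np.testing.assert_allclose(left.yaw, -right.yaw, atol=1e-9)
    np.testing.assert_allclose(left.roll, -right.roll, atol=1e-9)
    np.testing.assert_allclose(left.side_a, right.side_a, atol=1e-9)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        GenParams(technique="DP", trunk_lean_deg=120.0)
    with pytest.raises(ValueError):
        GenParams(technique="DP", asymmetry_ratio=0.0)
    with pytest.raises(ValueError):
        GenParams(technique="DP", lead_side="X")
    with pytest.raises(ValueError):
        GenParams(technique="DP", amp={"pitch": -5.0})
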