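"""Synthetic trunk-IMU recordings for the seven cross-country skiing
techniques.

Each technique is encoded as a harmonic template: per channel, a short list
of harmonics of the cycle rate with relative weights and peak positions
(in cycle fractions).  The template describes the *conditioned* signal —
the low-pass filtered traces on which the field's per-technique signatures
(peak magnitudes, peaks-per-cycle counts, inter-channel phase order) are
defined.  :func:`generate` therefore deconvolves the designed waveform by
the known zero-phase response of the default conditioning filters before
adding gravity, wide-band noise, an 8 Hz vibration contaminant and the
three-tap synchronization marker, so that filtering the generated recording
with the default settings reproduces the designed amplitudes.  Raw
amplitudes are correspondingly larger than filtered ones, as with real
impulsive poling.

Gravity follows the trunk-orientation contract of the sensor mount: with
the athlete upright the forward-acceleration channel reads +1 g, and
pitching the trunk fully forward transfers the entire 1 g to the upward
channel; the sideways channel never carries gravity.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ACCEL_CHANNELS, CHANNELS, SignalSeries
from .preprocess import (FilterSpec, default_accel_spec, default_gyro_spec,
                         single_pass_gain)


class TechniqueLabel(str, enum.Enum):
    """The seven techniques: three classical, four skating gears."""

    DP = "DP"    # Double Pole
    KDP = "KDP"  # Kick Double Pole
    DS = "DS"    # Diagonal Stride
    G2 = "G2"    # Offset Skate
    G3 = "G3"    # Double Time
    G4 = "G4"    # Single Time
    G5 = "G5"    # Free Skate

    @property
    def family(self) -> str:
        return "classical" if self in (TechniqueLabel.DP, TechniqueLabel.KDP,
                                       TechniqueLabel.DS) else "skating"


CLASSICAL = (TechniqueLabel.DP, TechniqueLabel.KDP, TechniqueLabel.DS)
SKATING = (TechniqueLabel.G2, TechniqueLabel.G3, TechniqueLabel.G4,
           TechniqueLabel.G5)

DEFAULT_CYCLE_RATE_HZ = {"classical": 0.8, "skating": 0.7}

# Common peak positions (cycle fractions).  The poling pitch peak precedes
# the main forward-acceleration peak by 0.15 cycle in every poling
# technique; the G4 yaw peak precedes the pitch peak by 0.10 cycle while
# the G2 yaw peak follows it by 0.05 cycle.
_P_FWD = 0.30
_P_PITCH = 0.15

Harmonic = tuple[int, float]  # (multiple of cycle rate, signed weight)


@dataclass(frozen=True)
class _Template:
    """Per-channel harmonic recipe plus default amplitudes and phases."""

    amp: dict[str, float]                    # peak amplitude (g or d/s)
    phase: dict[str, float]                  # fundamental peak position
    harmonics: dict[str, tuple[Harmonic, ...]]
    anchor: str                              # channel defining the cycle
    sided: bool                              # L/R structure present


_H1 = ((1, 1.0),)
_H_EVEN2 = ((2, 1.0),)            # two even peaks per cycle (left/right)
_H2 = ((2, 1.0), (1, 0.15))       # two near-even peaks, main one slightly taller
_H_MAJOR_MINOR = ((1, 0.43), (2, 0.57))   # distinct major + minor peak
_H_DOUBLE = ((1, 1.0), (2, -0.4))         # double peak (twin humps)
_H_WIDE_TROUGH = ((1, 1.0), (2, 0.2))     # narrow peak, wide trough

_TEMPLATES: dict[TechniqueLabel, _Template] = {
    # --- classical ---
    TechniqueLabel.DP: _Template(
        amp={"fwd_a": 0.30, "side_a": 0.02, "up_a": 0.15,
             "roll": 10.0, "pitch": 100.0, "yaw": 10.0},
        phase={"fwd_a": _P_FWD, "side_a": 0.10, "up_a": _P_FWD + 0.50,
               "roll": _P_PITCH, "pitch": _P_PITCH, "yaw": _P_PITCH},
        harmonics={c: _H1 for c in CHANNELS},
        anchor="pitch", sided=False),
    TechniqueLabel.KDP: _Template(
        amp={"fwd_a": 0.35, "side_a": 0.02, "up_a": 0.15,
             "roll": 40.0, "pitch": 100.0, "yaw": 40.0},
        phase={"fwd_a": _P_FWD, "side_a": 0.10, "up_a": 0.80,
               "roll": 0.70, "pitch": _P_PITCH, "yaw": 0.65},
        harmonics={**{c: _H1 for c in CHANNELS}, "fwd_a": _H_MAJOR_MINOR},
        anchor="yaw", sided=True),
    TechniqueLabel.DS: _Template(
        amp={"fwd_a": 0.25, "side_a": 0.02, "up_a": 0.12,
             "roll": 40.0, "pitch": 40.0, "yaw": 40.0},
        # fwd/up carry two truly even peaks per cycle (left/right kick);
        # roll sits 0.05 cycle after the yaw kick so its extrema fall
        # safely inside the half-cycles rather than on their boundaries
        phase={"fwd_a": _P_FWD, "side_a": 0.10, "up_a": 0.38,
               "roll": 0.70, "pitch": _P_PITCH, "yaw": 0.65},
        harmonics={**{c: _H1 for c in CHANNELS},
                   "fwd_a": _H_EVEN2, "up_a": _H_EVEN2},
        anchor="yaw", sided=True),
    # --- skating ---
    TechniqueLabel.G2: _Template(
        amp={"fwd_a": 0.30, "side_a": 0.40, "up_a": 0.15,
             "roll": 60.0, "pitch": 60.0, "yaw": 50.0},
        phase={"fwd_a": _P_FWD, "side_a": 0.10, "up_a": 0.12,
               "roll": 0.30, "pitch": _P_PITCH, "yaw": _P_PITCH + 0.05},
        harmonics={**{c: _H1 for c in CHANNELS},
                   "fwd_a": _H_DOUBLE, "yaw": _H_WIDE_TROUGH},
        anchor="side_a", sided=True),
    TechniqueLabel.G3: _Template(
        amp={"fwd_a": 0.30, "side_a": 0.40, "up_a": 0.15,
             "roll": 40.0, "pitch": 90.0, "yaw": 45.0},
        phase={"fwd_a": _P_FWD, "side_a": 0.10, "up_a": 0.55,
               "roll": 0.40, "pitch": _P_PITCH, "yaw": 0.20},
        harmonics={**{c: _H1 for c in CHANNELS}, "fwd_a": _H2, "pitch": _H2},
        anchor="side_a", sided=True),
    TechniqueLabel.G4: _Template(
        amp={"fwd_a": 0.35, "side_a": 0.40, "up_a": 0.15,
             "roll": 45.0, "pitch": 90.0, "yaw": 45.0},
        phase={"fwd_a": _P_FWD, "side_a": 0.10, "up_a": 0.78,
               "roll": 0.40, "pitch": _P_PITCH, "yaw": _P_PITCH - 0.10},
        harmonics={**{c: _H1 for c in CHANNELS},
                   "fwd_a": _H_MAJOR_MINOR, "yaw": _H_WIDE_TROUGH},
        anchor="side_a", sided=True),
    TechniqueLabel.G5: _Template(
        amp={"fwd_a": 0.20, "side_a": 0.40, "up_a": 0.08,
             "roll": 60.0, "pitch": 25.0, "yaw": 45.0},
        phase={"fwd_a": _P_FWD, "side_a": 0.10, "up_a": 0.40,
               "roll": 0.30, "pitch": _P_PITCH, "yaw": 0.20},
        harmonics={**{c: _H1 for c in CHANNELS}, "fwd_a": _H2, "up_a": _H2},
        anchor="side_a", sided=True),
}

# Tap-marker layout: three 5 g, 50 ms half-sine spikes with onsets 0.5 s
# apart, followed by quiet standing; movement starts MARKER_PREFIX_S into
# the recording when the marker is enabled.
TAP_SPIKE_G = 5.0
TAP_SPIKE_S = 0.05
TAP_ONSETS_S = (0.25, 0.75, 1.25)
MARKER_PREFIX_S = 3.5


@dataclass
class GenParams:
    """Full parameterization of one synthetic technique recording."""

    technique: TechniqueLabel
    duration_s: float = 20.0
    cycle_rate_hz: float | None = None   # family default when None
    amp: dict[str, float] = field(default_factory=dict)
    phase: dict[str, float] = field(default_factory=dict)
    noise_sd_g: float = 0.05
    noise_sd_dps: float = 5.0
    hf_noise_g: float = 0.1      # 8 Hz contaminant, removed by the filter
    hf_noise_dps: float = 10.0
    trunk_lean_deg: float = 15.0
    asymmetry_ratio: float = 1.0  # L-side amplitude scale on FwdA/UpA/Roll
    lead_side: str = "R"          # leading side for G2
    tap_marker: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.technique = TechniqueLabel(self.technique)
        tpl = _TEMPLATES[self.technique]
        if self.cycle_rate_hz is None:
            self.cycle_rate_hz = DEFAULT_CYCLE_RATE_HZ[self.technique.family]
        self.amp = {**tpl.amp, **self.amp}
        self.phase = {**tpl.phase, **self.phase}
        self.phase = {c: p % 1.0 for c, p in self.phase.items()}
        if not self.duration_s > 0 or not self.cycle_rate_hz > 0:
            raise ValueError("duration_s and cycle_rate_hz must be positive")
        if any(a < 0 for a in self.amp.values()):
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.trunk_lean_deg <= 90:
            raise ValueError("trunk_lean_deg must lie in [0, 90]")
        if not self.asymmetry_ratio > 0:
            raise ValueError("asymmetry_ratio must be positive")
        if self.lead_side not in ("L", "R"):
            raise ValueError("lead_side must be 'L' or 'R'")


def gravity_components(trunk_lean_deg: float) -> tuple[float, float]:
    """Static gravity split between the forward and upward channels.

    Upright (0 deg) mounts read +1 g on the forward channel; a fully
    forward-rotated trunk (90 deg) transfers the whole 1 g to the upward
    channel.  The sideways channel never carries gravity.
    """
    if not 0 <= trunk_lean_deg <= 90:
        raise ValueError("trunk_lean_deg must lie in [0, 90]")
    rad = math.radians(trunk_lean_deg)
    return math.cos(rad), math.sin(rad)


def default_params(technique: TechniqueLabel | str, **overrides) -> GenParams:
    """Default generator parameters for one technique.

    The defaults encode the published per-technique signatures: poling
    pitch amplitudes (DP/KDP 100, G3/G4 90, G2 60 d/s) above their
    detection bounds, the non-poling ones (DS 40, G5 25 d/s) below, kick
    and skate roll/yaw magnitudes, skating side-acceleration alternation,
    and the inter-channel phase order (pitch before the main forward peak;
    G4 yaw before pitch; G2 yaw after pitch; G3 pitch at twice the cycle
    frequency).
    """
    return GenParams(technique=TechniqueLabel(technique), **overrides)


def template_info(technique: TechniqueLabel | str) -> dict:
    """Anchor channel and sidedness of a technique's template."""
    tpl = _TEMPLATES[TechniqueLabel(technique)]
    return {"anchor": tpl.anchor, "sided": tpl.sided}


def _design_gain(channel: str, freq_hz: np.ndarray,
                 sample_rate_hz: float) -> np.ndarray:
    """Zero-phase amplitude gain of the default conditioning filter."""
    spec = default_accel_spec() if channel in ACCEL_CHANNELS \
        else default_gyro_spec()
    freq = np.clip(np.abs(freq_hz), 0.0, sample_rate_hz / 2 * (1 - 1e-9))
    return single_pass_gain(spec, sample_rate_hz, freq) ** 2


def _base_waveform(harmonics: tuple[Harmonic, ...], peak_pos: float,
                   cycle_frac: np.ndarray) -> np.ndarray:
    """Unit-normalized sum of harmonics peaking (value 1) at ``peak_pos``."""
    def evaluate(frac):
        out = np.zeros_like(frac)
        for k, w in harmonics:
            out += w * np.cos(2 * np.pi * k * (frac - peak_pos))
        return out

    grid = evaluate(np.linspace(0.0, 1.0, 2048, endpoint=False))
    return evaluate(cycle_frac) / grid.max()


def _asymmetry_gain(cycle_frac: np.ndarray, anchor_pos: float,
                    ratio: float, taper: float = 0.06) -> np.ndarray:
    """Flat-top gain = ``ratio`` over the L half-cycle, 1 over the R half.

    The L half-cycle is the half beginning at the anchor channel's peak.
    Cosine tapers of ``taper`` cycle at the edges keep the modulation
    band-limited so it survives the conditioning filter.
    """
    x = (cycle_frac - anchor_pos) % 1.0
    w = np.zeros_like(x)
    core = (x >= taper) & (x <= 0.5 - taper)
    w[core] = 1.0
    rise = x < taper
    w[rise] = 0.5 * (1 - np.cos(np.pi * x[rise] / taper))
    fall = (x > 0.5 - taper) & (x < 0.5)
    w[fall] = 0.5 * (1 - np.cos(np.pi * (0.5 - x[fall]) / taper))
    return 1.0 + (ratio - 1.0) * w


def _precompensate(target: np.ndarray, channel: str,
                   sample_rate_hz: float) -> np.ndarray:
    """Raw waveform whose default-filtered version equals ``target``.

    Spectral division by the known zero-phase filter gain; components where
    the gain falls below 1e-3 are dropped rather than amplified.
    """
    n = len(target)
    spec = np.fft.rfft(target)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    gain = _design_gain(channel, freqs, sample_rate_hz)
    usable = gain > 1e-3
    spec[usable] /= gain[usable]
    spec[~usable] = 0.0
    return np.fft.irfft(spec, n)


def generate(params: GenParams, sample_rate_hz: float = 100.0) -> SignalSeries:
    """Generate one synthetic technique recording.

    The movement part of each channel is the technique's harmonic template
    (pre-compensated for the default conditioning filters), with left/right
    alternation carried by the anchor channel's sign, optional L-side
    amplitude scaling on the forward/upward/roll channels, gravity offsets
    on the forward and upward channels, white noise, an 8 Hz vibration
    contaminant, and — if enabled — a three-tap marker plus quiet standing
    prepended.  Bit-for-bit reproducible for a fixed seed.
    """
    tpl = _TEMPLATES[params.technique]
    f = params.cycle_rate_hz
    if params.duration_s < 1.0 / f:
        raise ValueError(
            f"duration {params.duration_s} s is shorter than one "
            f"{1.0 / f:.2f} s cycle")
    fs = sample_rate_hz
    n_move = int(round(params.duration_s * fs))
    t = np.arange(n_move) / fs
    # the spectral pre-compensation is circular, so build the movement on a
    # whole number of cycles (no wrap discontinuity) and truncate afterwards
    n_cycles_ext = math.ceil(params.duration_s * f - 1e-9)
    n_ext = max(n_move, int(round(n_cycles_ext / f * fs)))
    cycle_frac = f * np.arange(n_ext) / fs

    anchor_pos = params.phase[tpl.anchor]
    movement: dict[str, np.ndarray] = {}
    for chan in CHANNELS:
        wave = params.amp[chan] * _base_waveform(
            tpl.harmonics[chan], params.phase[chan], cycle_frac)
        if (tpl.sided and params.asymmetry_ratio != 1.0
                and chan in ("fwd_a", "up_a", "roll")):
            wave = wave * _asymmetry_gain(cycle_frac, anchor_pos,
                                          params.asymmetry_ratio)
        if (params.technique is TechniqueLabel.G2 and params.lead_side == "L"
                and chan in ("roll", "yaw")):
            wave = -wave  # left-leading offset skate inverts roll and yaw
        movement[chan] = _precompensate(wave, chan, fs)[:n_move]

    fwd_g, up_g = gravity_components(params.trunk_lean_deg)
    gravity = {"fwd_a": fwd_g, "side_a": 0.0, "up_a": up_g,
               "roll": 0.0, "pitch": 0.0, "yaw": 0.0}

    n_prefix = int(round(MARKER_PREFIX_S * fs)) if params.tap_marker else 0
    n_total = n_prefix + n_move
    t_all = np.arange(n_total) / fs

    rng = np.random.default_rng(params.seed)
    channels: dict[str, np.ndarray] = {}
    moving = any(params.amp[c] > 0 for c in CHANNELS)
    for chan in CHANNELS:  # fixed stream order: channel order
        x = np.full(n_total, gravity[chan])
        x[n_prefix:] += movement[chan]
        if moving:  # movement-induced vibration contaminant
            hf = params.hf_noise_g if chan in ACCEL_CHANNELS \
                else params.hf_noise_dps
            x[n_prefix:] += hf * np.cos(2 * np.pi * 8.0 * t)
        sd = params.noise_sd_g if chan in ACCEL_CHANNELS \
            else params.noise_sd_dps
        if sd > 0:
            x += rng.normal(0.0, sd, n_total)
        channels[chan] = x

    if params.tap_marker:
        spike_n = max(1, int(round(TAP_SPIKE_S * fs)))
        pulse = TAP_SPIKE_G * np.sin(np.pi * np.arange(spike_n) / spike_n)
        for onset in TAP_ONSETS_S:
            i0 = int(round(onset * fs))
            channels["fwd_a"][i0:i0 + spike_n] += pulse

    # ground truth for downstream tests: anchor-peak cycle boundaries
    move_start_s = n_prefix / fs
    first_peak = move_start_s + anchor_pos / f
    boundaries = []
    k = 0
    while first_peak + k / f < n_total / fs - 1e-9:
        boundaries.append(first_peak + k / f)
        k += 1
    meta = {
        "technique": params.technique.value,
        "family": params.technique.family,
        "seed": params.seed,
        "cycle_rate_hz": f,
        "movement_start_s": move_start_s,
        "cycle_boundaries_s": boundaries,
        "sided": tpl.sided,
        "anchor": tpl.anchor,
        "lead_side": params.lead_side,
        "trunk_lean_deg": params.trunk_lean_deg,
        "asymmetry_ratio": params.asymmetry_ratio,
    }
    return SignalSeries(sample_rate_hz=fs, meta=meta, **channels)


def make_fixture_set(seed: int, n_per_technique: int,
                     duration_s: float = 20.0
                     ) -> list[tuple[SignalSeries, TechniqueLabel]]:
    """A deterministic labelled fixture grid over all seven techniques.

    Each recording jitters the defaults: cycle rate +/-20%, trunk lean
    0-30 deg, noise x0.5-2, amplitudes x0.8-1.2, and a random leading side
    for the offset skate.
    """
    if n_per_technique < 1:
        raise ValueError("n_per_technique must be >= 1")
    rng = np.random.default_rng(seed)
    fixtures = []
    for technique in (*CLASSICAL, *SKATING):
        base = default_params(technique)
        for _ in range(n_per_technique):
            rate = base.cycle_rate_hz * rng.uniform(0.8, 1.2)
            lean = rng.uniform(0.0, 30.0)
            noise_scale = rng.uniform(0.5, 2.0)
            amp_scale = rng.uniform(0.8, 1.2)
            lead = "L" if rng.random() < 0.5 else "R"
            child_seed = int(rng.integers(0, 2 ** 31))
            params = default_params(
                technique,
                duration_s=duration_s,
                cycle_rate_hz=rate,
                amp={c: a * amp_scale for c, a in base.amp.items()},
                noise_sd_g=0.05 * noise_scale,
                noise_sd_dps=5.0 * noise_scale,
                trunk_lean_deg=lean,
                lead_side=lead,
                seed=child_seed,
            )
            fixtures.append((generate(params), TechniqueLabel(technique)))
    return fixtures
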