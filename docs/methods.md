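# Methods

## Signal model and conventions

A recording is a uniformly sampled 6-channel series at 100 Hz: linear
acceleration FwdA/SideA/UpA in g and angular rate Roll/Pitch/Yaw in °/s.
Channel names are semantic, not geometric: the mount is defined by its
behaviour — with the athlete upright the FwdA channel reads +1 g of
gravity, and pitching the trunk forward by an angle θ redistributes it as
FwdA = cos θ, UpA = sin θ, SideA = 0. Gravity is deliberately **not**
removed before analysis; the classification features either use
zero-baseline gyro channels or reference accelerations to a robust
baseline, so the static offset is harmless and carries useful information
(trunk lean, terrain gradient: steeper inclines shift the gravity share
from FwdA toward UpA, which the generator exposes as `trunk_lean_deg` and
the test suite checks as a strict monotonicity).

A cycle is one full repetition of the movement pattern. Cycles are
delimited peak-to-peak on an anchor channel, as half-open 0-based sample
intervals: SideA for skating (its alternating peak/trough identifies the
left and right skate), yaw for classical techniques with a kick (DS, KDP;
the kick rotates the upper body), falling back to pitch for Double Pole,
which has no kick and therefore no defined sides. Where a cycle "starts"
is a convention; it only fixes the sign convention of the timing features
below, and both are documented together.

## Synthetic recordings

No public recordings exist for this sensor configuration, so the
generator is a first-class, tested component. Each technique is a
harmonic template: per channel, 1–3 harmonics of the cycle rate with
relative weights and peak positions in cycle fractions. Templates encode
the published signature set:

- poling pitch amplitudes: DP/KDP 100, G3/G4 90, G2 60, DS 40, G5 25 °/s
  (above/below the 75 / 50 / 40 °/s decision bounds with margin);
- kick/skate roll and yaw magnitudes (DS/KDP 40, G2 roll 60, G5 roll 60,
  DP roll/yaw 10 °/s, i.e. below the 20 °/s kick ceiling);
- skating SideA 0.4 g alternation vs. classical 0.02 g;
- phase order: the poling pitch peak precedes the main FwdA peak by 0.15
  cycle; the G4 yaw peak leads the pitch peak by 0.10 cycle while the G2
  yaw peak trails it by 0.05; G3 pitch runs at twice the cycle frequency;
- FwdA multiplicity: one major peak (DP), major + minor (KDP, G4), two
  even peaks (DS, G3, G5), a double peak (G2).

FwdA/UpA movement amplitudes (0.2–0.35 g) and the default cycle rates
(0.8 Hz classical, 0.7 Hz skating) are free parameters — the source
tables give no numbers for them — chosen as typical moderate-intensity
values and configurable throughout. The fixture grid jitters cycle rate
±20 %, amplitudes ±20 %, lean 0–30°, noise ×0.5–2 and the G2 leading
side.

**Amplitudes parameterize the conditioned signal.** The signature tables
describe the low-pass-filtered traces, so `generate` designs the filtered
waveform and *deconvolves* it by the known zero-phase response of the
default filters (spectral division on a whole number of cycles;
components where the squared-magnitude gain falls below 1e-3 are dropped
rather than amplified). Raw peaks are therefore larger than filtered
ones — markedly so for the G3 poling pitch at 1.4 Hz against the 1.0 Hz
gyro filter — mirroring how impulsive pole plants are smoothed in real
data. A consequence worth noting: modulation sidebands above the 1e-3
gain floor survive conditioning exactly, while those beyond it are lost,
which is why an injected left/right amplitude asymmetry is recovered
almost exactly on the 2 Hz-filtered FwdA channel but attenuated on the
1 Hz-filtered roll channel.

On top of the movement template the generator adds gravity, per-channel
white noise (0.05 g / 5 °/s), an 8 Hz vibration contaminant
(0.1 g / 10 °/s, entirely removed by the filters, present only while
moving), optional left-side amplitude scaling of FwdA/UpA/Roll over the
left half-cycle (flat-top window with 0.06-cycle cosine tapers), sign
inversion of roll/yaw for a left-leading Offset Skate, and — by default —
a synchronization marker: three 5 g, 50 ms half-sine spikes at 0.5 s
spacing followed by quiet standing, with movement starting 3.5 s in. All
randomness flows from one `numpy` generator seeded per recording; streams
are drawn in fixed channel order, so output is bit-reproducible.

What the generator does **not** emulate: biomechanical forcing, terrain
profiles over time, within-recording technique changes, cycle-to-cycle
phase drift, sensor bias/drift, or the athlete-specific style variation
real data show. Green tests therefore demonstrate that the pipeline
recovers what the signature tables assert under realistic noise — not
field performance on arbitrary athletes.

## Conditioning

Zero-phase (forward–backward) Butterworth low-pass, order 4, 2.0 Hz for
accelerometer channels and 1.0 Hz for gyroscope channels. Order and phase
handling are not dictated by the source material; order 4 is the
biomechanics convention and zero-phase keeps filtered peaks aligned with
the events that caused them (verified: an isolated symmetric peak moves
by ≤1 sample). The effective amplitude response is the squared single-pass
magnitude; DC gain is exactly 1. `measure_cutoff` locates the single-pass
half-power frequency by bisection, valid because the Butterworth
magnitude is monotone. Edge transients are handled by `scipy`'s default
odd-extension padding.

The tap marker is localized on the raw acceleration magnitude: the first
of three excursions > 3 g above the 1 g baseline with consecutive onsets
0.2–1.5 s apart (threshold and spacing are inventions, exposed in
config). Absence is reported as `None`, never an exception.

## Feature and rule numerics

- Medians across cycles everywhere, for robustness to irregular cycles.
- Poling pitch peaks require prominence ≥ 45 °/s **and** peak value
  ≥ 45 °/s: the value condition keeps a low-amplitude oscillation whose
  peak-to-trough swing clears the bound (e.g. the 25 °/s G5 pitch, whose
  prominence is ~50 °/s) from counting as poling; 45 sits between the
  50 °/s G2 poling clause and the 40 °/s G5 ceiling. The same
  value-gating applies to the yaw-anchor decision (kick yaw must *reach*
  20 °/s).
- FwdA peak classes per cycle: the largest-prominence peak plus any peak
  ≥ 60 % of it are "major"; peaks in [25 %, 60 %) are "minor"; smaller
  bumps are ignored. "Distinct major and minor" (KDP, G4) means the
  median minor count is ≥ 1.
- SideA regularity = alternating signs at the anchor extrema, coefficient
  of variation < 0.5, median excursion ≥ 0.1 g. The excursion is read at
  each half-cycle's starting extremum because a peak-to-trough half
  contains both extreme values.
- Yaw–pitch timing: per cycle, the lag from the pitch maximum to the yaw
  extremum of largest |value|, in cycle fractions wrapped to (−0.5, 0.5],
  combined by a circular median (the observed lag minimizing summed
  circular distance). Using the dominant extremum rather than the peak
  makes the measure invariant to the roll/yaw inversion of a left-leading
  Offset Skate; the G2/G4 yaw templates carry a small second harmonic
  that makes the lead-side extremum dominant (and realizes the
  wider-trough-than-peak G4 signature).
- Segmentation rejects anchor peak trains whose spacing CV exceeds 0.4
  ("no cyclical structure"), which is what turns structureless noise into
  an honest `none` label instead of a spurious technique.
- `classify_series` tries both family hypotheses and keeps the classified
  label with the higher confidence (fraction of path-consistent rules);
  tie goes to skating. Unclassifiable inputs return a `none` result with
  diagnostics, never an exception.
- G2 is tested against its own 50 °/s poling bound only *after* the G5
  no-poling test, so a 50–75 °/s pitch never disqualifies it. The
  ratio tolerance (0.35) and zero-lag band (0.02 cycle) quantify
  qualitative orderings and are configuration, not constants of nature.
- KDP vs DP uses the roll/yaw kick signature rather than detecting the
  "slight hump" the kick adds to the KDP pitch curve: that hump does not
  survive 1 Hz filtering reliably, while the kick's roll/yaw rotation
  does.

## Asymmetry index

Per half-cycle and side, the analysis collects the dominant detected
extremum of FwdA, UpA (positive peaks above the channel median — the
median, not the mean, so the gravity offset cancels without gravity
correction) and Roll (|extremum| about the physical 0 °/s baseline).
Only detected local extrema are scored, assigned to the half containing
their sample — window-edge values approaching a neighbouring half's
extremum never leak across sides. The index per channel is the standard
limb-symmetry form (mean_L − mean_R)/((mean_L + mean_R)/2), in [−2, 2];
an injected L-amplitude ratio r implies index 2(r − 1)/(r + 1). A report
is flagged when any |index| > 0.15 — a reporting convention, not a
clinical bound. At least 3 half-cycles per side are required. Double Pole
has no defined sides and is rejected explicitly.

Known limitation: with heavy gyro filtering the roll index underestimates
an injected amplitude asymmetry (sidebands of the half-cycle modulation
fall outside the 1 Hz passband); FwdA, filtered at 2 Hz, recovers the
closed form within ±0.05 and is the primary asymmetry readout.

## Problem sizes

Default recordings are 20 s (14–16 cycles) plus the 3.5 s marker prefix;
the fixture grid is 10 jittered recordings per technique; the round-trip
identity check runs all 7 techniques over 20 seeds. These sizes give
±1-cycle segmentation resolution below 1 % of the measured rates and keep
the whole suite in the tens of seconds.

## Design choices that were genuinely open

- CSV over the vendor's proprietary binary format; times implicit
  (index/rate) on write, uniformity enforced (1 % of the median step) on
  read because all downstream mathematics assumes uniform sampling.
- Peak-to-peak cycle convention (affects lag signs; documented above).
- Plateau ties in peak detection break toward the earlier sample.
- The left half-cycle is the one beginning at the anchor peak; the
  left/right assignment of anchor peak vs. trough is a convention, and
  the G2 tests assert label invariance under lead-side flips rather than
  a particular assignment.
- Exit codes 0 / 2 / 64 / 1 (success / unclassifiable / usage /
  processing error).
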