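# skitech

Rule-based analysis of cross-country skiing technique from a single
trunk-mounted micro-sensor (tri-axial accelerometer + gyroscope, 100 Hz).

Each of the seven competition techniques — the classical sub-techniques
Double Pole (DP), Kick Double Pole (KDP) and Diagonal Stride (DS), and the
skating gears Offset Skate (G2), Double Time (G3), Single Time (G4) and
Free Skate (G5) — leaves a characteristic cyclical signature on the six
sensor channels: forward/sideways/upward acceleration (FwdA, SideA, UpA,
in g) and roll/pitch/yaw angular rate (in °/s). `skitech` implements the
full pipeline around those signatures:

- **synth** — a harmonic-template generator producing labelled synthetic
  recordings per technique (cycle rate, amplitudes, phase order, trunk
  lean, left/right asymmetry, measurement noise, three-tap sync marker);
- **preprocess** — zero-phase low-pass Butterworth conditioning (2.0 Hz
  accelerometer / 1.0 Hz gyroscope, order 4), tap-marker localization,
  10-second analysis blocks;
- **cycles** — prominence-based peak detection and movement-cycle
  segmentation with left/right half-cycle labels (SideA anchors skating
  cycles, yaw anchors classical kick cycles), cycle- and poling-rate
  estimation;
- **features / classify** — the discriminative quantities (per-cycle peak
  magnitudes, FwdA peak multiplicity, poling-to-cycle ratio, yaw–pitch
  timing) and a transparent decision tree with a full evidence trail;
- **asymmetry** — per-channel left/right limb-symmetry indices
  `(mean_L − mean_R) / ((mean_L + mean_R)/2)` from per-half-cycle peaks.

The decision tree, in brief: a regular alternating SideA cycle ⇒ skating,
else classical. Classical: pitch < 50 °/s with a roll kick ⇒ DS; pitch
≥ 75 °/s with / without the kick ⇒ KDP / DP. Skating: pitch < 40 °/s ⇒ G5
(no poling); two poling pitch peaks per yaw cycle ⇒ G3; otherwise the yaw
peak leading the pitch peak ⇒ G4, trailing it ⇒ G2.

## Worked example

Simulate a Single Time (G4) recording and classify it:

```sh
$ skitech simulate --technique G4 --seed 1 --out g4.csv
$ skitech classify g4.csv --out report.json
G4
```

The report carries the whole evidence trail. For this recording it reads
(abbreviated): SideA half-cycle peak 0.399 g ≥ 0.1 g (skating family);
pitch peak 90.4 °/s, so not G5 (< 40 fails); poling-to-cycle ratio 1.0,
so not G3 (|ratio − 2| ≤ 0.35 fails); yaw–pitch lag −0.10 cycle < −0.02
(yaw leads pitch) ⇒ **G4**, confidence 1.0. The segmentation block reports
12 cycles at 0.70 Hz.

Quantify an injected left-side weakness (L amplitudes scaled ×0.8) on a
Diagonal Stride recording:

```sh
$ skitech simulate --technique DS --seed 3 --asymmetry 0.8 --no-marker --out ds.csv
$ skitech preprocess ds.csv --out ds_f.csv
$ skitech segment ds_f.csv --family classical --out seg.json
$ skitech asymmetry ds_f.csv seg.json --out asym.json
```

`asym.json` then contains `index(FwdA) = −0.256`, `index(UpA) = −0.279`,
`index(Roll) = −0.102`, `flagged: true` — the L-side peaks are
systematically lower, close to the value 2(0.8−1)/(0.8+1) = −0.22 implied
by the injected scaling (exact on marker-trimmed recordings).

Exit codes: 0 classified / success, 2 unclassifiable recording, 64 usage
error, 1 processing error.

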