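"""Rule-based technique classification with a full evidence trail.

The decision tree follows the published signature tables.  Family first:
a regular alternating side-acceleration cycle means skating, otherwise
classical.  Classical splits on poling pitch magnitude and the roll/yaw
kick signature (diagonal stride below 50 d/s pitch with a kick; kick
double pole above 75 d/s with a kick; double pole above 75 d/s without).
Skating tests the no-poling bound first (free skate below 40 d/s — this
ordering means the offset skate, whose poling bound is the lower 50 d/s,
is never rejected for a 50-75 d/s pitch), then the double-time 2:1
poling-to-cycle ratio, and finally the offset/single-time yaw-pitch
timing, with the forward-acceleration major/minor structure breaking
near-zero lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cycles import SegmentationError, cycle_rate, segment_cycles
from .features import FeatureParams, FeatureVector, extract_features
from .io import SignalSeries
from .preprocess import (FilterSpec, apply_lowpass, find_tap_marker,
                         select_block)

_OPS = {
    "ge": lambda v, t: v >= t,
    "le": lambda v, t: v <= t,
    "gt": lambda v, t: v > t,
    "lt": lambda v, t: v < t,
}


@dataclass(frozen=True)
class RuleThresholds:
    """Decision thresholds, with their published sources.

    poling_pitch_dps (75) and ds_pitch_max_dps (50) come from the classical
    signature table; g2_poling_pitch_dps (50), g5_pitch_max_dps (40) and
    g2_roll_min_dps (50) from the skating table; kick_roll_min_dps (20)
    from the double-pole "below 20 d/s" noise ceiling.  ratio_tol and
    lag_zero_band quantify qualitative orderings and are conventions.
    """

    poling_pitch_dps: float = 75.0
    g2_poling_pitch_dps: float = 50.0
    ds_pitch_max_dps: float = 50.0
    g5_pitch_max_dps: float = 40.0
    kick_roll_min_dps: float = 20.0
    g2_roll_min_dps: float = 50.0
    ratio_tol: float = 0.35
    lag_zero_band: float = 0.02

    def __post_init__(self) -> None:
        if any(getattr(self, f.name) <= 0 for f in
               self.__dataclass_fields__.values()):  # type: ignore[attr-defined]
            raise ValueError("all thresholds must be positive")


@dataclass
class RuleEvidence:
    rule: str
    value: float
    threshold: float
    op: str
    passed: bool


@dataclass
class ClassificationResult:
    """Predicted label plus the ordered evidence trail that produced it."""

    label: str                      # technique code or "none"
    evidence: list[RuleEvidence] = field(default_factory=list)
    confidence: float = 0.0         # fraction of path-consistent rules
    segmentation: dict | None = None
    diagnostics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "confidence": self.confidence,
            "evidence": [vars(e) for e in self.evidence],
            "segmentation": self.segmentation,
            "diagnostics": list(self.diagnostics),
        }


class _Trail:
    """Evidence recorder: each consulted rule is logged exactly once."""

    def __init__(self) -> None:
        self.evidence: list[RuleEvidence] = []
        self._expected: list[bool] = []

    def check(self, rule: str, value: float, threshold: float, op: str,
              expect: bool | None = None) -> bool:
        passed = bool(_OPS[op](value, threshold))
        self.evidence.append(RuleEvidence(rule, float(value),
                                          float(threshold), op, passed))
        self._expected.append(passed if expect is None else expect)
        return passed

    def confidence(self) -> float:
        if not self.evidence:
            return 0.0
        consistent = sum(e.passed == x
                         for e, x in zip(self.evidence, self._expected))
        return consistent / len(self.evidence)


def classify(fv: FeatureVector,
             th: RuleThresholds | None = None) -> ClassificationResult:
    """Map a feature vector to a technique label.

    Total over valid feature vectors: combinations matched by no rule path
    yield a ``"none"`` label with the evidence trail, never an exception.
    """
    th = th or RuleThresholds()
    trail = _Trail()
    ck = trail.check

    sidea_ok = ck("family_sidea_peak", fv.sidea_peak_g, 0.1, "ge",
                  expect=fv.sidea_regular)
    skating = fv.sidea_regular
    label = "none"
    if not skating:
        ds_pitch = ck("ds_pitch_max", fv.pitch_peak_dps,
                      th.ds_pitch_max_dps, "lt", expect=None)
        kick = ck("kick_roll_min", fv.roll_peak_dps,
                  th.kick_roll_min_dps, "ge", expect=None)
        if ds_pitch and kick:
            label = "DS"
        else:
            poling = ck("poling_pitch", fv.pitch_peak_dps,
                        th.poling_pitch_dps, "ge", expect=True)
            if poling:
                label = "KDP" if kick else "DP"
    else:
        g5 = ck("g5_pitch_max", fv.pitch_peak_dps,
                th.g5_pitch_max_dps, "lt", expect=None)
        if g5:
            label = "G5"
        else:
            g3 = ck("g3_ratio_near_2", abs(fv.pitch_yaw_ratio - 2.0),
                    th.ratio_tol, "le", expect=None)
            if g3:
                label = "G3"
            else:
                leads = ck("g4_yaw_leads_pitch", fv.yaw_pitch_lag,
                           -th.lag_zero_band, "lt", expect=None)
                if leads:
                    label = "G4"
                else:
                    follows = ck("g2_yaw_follows_pitch", fv.yaw_pitch_lag,
                                 th.lag_zero_band, "gt", expect=None)
                    if follows:
                        label = "G2"
                    else:
                        mm = ck("tiebreak_fwd_major_minor",
                                float(fv.fwd_major_minor), 0.5, "ge",
                                expect=None)
                        label = "G4" if mm else "G2"
            if label == "G2":
                ck("g2_poling_pitch", fv.pitch_peak_dps,
                   th.g2_poling_pitch_dps, "ge", expect=True)
                ck("g2_roll_min", fv.roll_peak_dps,
                   th.g2_roll_min_dps, "ge", expect=True)
    result = ClassificationResult(label=label, evidence=trail.evidence)
    result.confidence = trail.confidence() if label != "none" else 0.0
    return result


def replay_evidence(evidence: list[RuleEvidence],
                    th: RuleThresholds | None = None) -> str:
    """Re-derive the label from an evidence trail's pass/fail flags alone.

    Used to verify that the recorded trail fully determines the decision.
    """
    flags = {e.rule: e.passed for e in evidence}
    if flags.get("g5_pitch_max") is not None or "g3_ratio_near_2" in flags:
        if flags.get("g5_pitch_max"):
            return "G5"
        if flags.get("g3_ratio_near_2"):
            return "G3"
        if flags.get("g4_yaw_leads_pitch"):
            return "G4"
        if flags.get("g2_yaw_follows_pitch"):
            return "G2"
        if "tiebreak_fwd_major_minor" in flags:
            return "G4" if flags["tiebreak_fwd_major_minor"] else "G2"
        return "none"
    if "ds_pitch_max" in flags:
        if flags["ds_pitch_max"] and flags.get("kick_roll_min"):
            return "DS"
        if flags.get("poling_pitch"):
            return "KDP" if flags.get("kick_roll_min") else "DP"
    return "none"


def classify_series(series: SignalSeries, config=None) -> ClassificationResult:
    """End-to-end classification of a raw recording.

    Pipeline: tap-marker trim, low-pass conditioning, segmentation under
    both family hypotheses, feature extraction, rule classification; the
    family hypothesis yielding a classified label with higher confidence
    wins.  Returns a ``"none"`` result with diagnostics when neither
    hypothesis produces a usable segmentation.
    """
    from .config import RunConfig
    cfg: RunConfig = config or RunConfig()

    if series.duration_s < 5.0:
        return ClassificationResult(
            label="none", diagnostics=["recording shorter than 5 s"])

    marker = find_tap_marker(series, cfg.marker.threshold_g,
                             cfg.marker.min_gap_s, cfg.marker.max_gap_s)
    work = series
    if marker is not None:
        start_s = marker / series.sample_rate_hz + cfg.marker.trim_after_s
        if series.duration_s - start_s >= 5.0:
            work = select_block(series, start_s,
                                series.duration_s - start_s)

    filtered = apply_lowpass(work,
                             FilterSpec(cfg.accel_cutoff_hz,
                                        cfg.filter_order),
                             FilterSpec(cfg.gyro_cutoff_hz,
                                        cfg.filter_order))

    candidates: list[ClassificationResult] = []
    diagnostics: list[str] = []
    for family in ("skating", "classical"):
        try:
            seg = segment_cycles(filtered, family)
            if seg.n_cycles < 2:
                raise SegmentationError("fewer than 2 cycles")
            fv = extract_features(filtered, seg, cfg.features)
        except (SegmentationError, ValueError) as exc:
            diagnostics.append(f"{family}: {exc}")
            continue
        res = classify(fv, cfg.thresholds)
        res.segmentation = {
            "family": family,
            "anchor_channel": seg.anchor_channel,
            "n_cycles": seg.n_cycles,
            "cycle_rate_hz": cycle_rate(seg, filtered.sample_rate_hz),
        }
        res.diagnostics = list(diagnostics)
        candidates.append(res)

    classified = [c for c in candidates if c.label != "none"]
    if classified:
        return max(classified, key=lambda c: c.confidence)
    if candidates:
        return candidates[0]
    return ClassificationResult(label="none", diagnostics=diagnostics)
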