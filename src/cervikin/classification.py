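"""Peak detection and classification of the normal extension sequence.

A recording shows the normal pattern ('+') when, in the terminal phase of
extension, the maximal contribution of C4-C5 comes first, followed by C5-C6
and then C6-C7, judged purely by the order of the significant peaks along the
cumulative-rotation axis. Peaks with a per-frame rotation prominence below
0.3 degrees are deemed insignificant. A late C4-C5 peak much smaller than its
main peak is normal and does not disqualify; peak prominence (not raw height)
is used throughout so shoulders on a monotone rise are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from cervikin.segments import SEGMENTS
from cervikin.kinematics import SSCCurve


@dataclass(frozen=True)
class Peak:
    """One local maximum of a segment's contribution curve."""

    segment: str
    x: float        #: cumulative-rotation coordinate (degrees)
    height: float   #: contribution at the peak (degrees per frame)
    prominence: float
    significant: bool


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the sequence classifier.

    significance_threshold : degrees of per-frame rotation below which a peak
        is deemed insignificant (0.3).
    terminal_phase_fraction : trailing fraction of cumulative rotation in
        which the pattern is read (0.5 = second half of extension).
    trailing_c45_max_ratio : a late C4-C5 peak must stay below this fraction
        of the selected C4-C5 peak to count as the normal small trailing peak.
    tie_tolerance : peaks closer than this (degrees of cumulative rotation)
        have no defined order and classify '-' with reason 'tie'.
    """

    significance_threshold: float = 0.3
    terminal_phase_fraction: float = 0.5
    trailing_c45_max_ratio: float = 0.5
    tie_tolerance: float = 0.5

    def __post_init__(self):
        if self.significance_threshold <= 0:
            raise ValueError("significance_threshold must be positive")
        if not 0 < self.terminal_phase_fraction <= 1:
            raise ValueError("terminal_phase_fraction must be in (0, 1]")
        if not 0 < self.trailing_c45_max_ratio < 1:
            raise ValueError("trailing_c45_max_ratio must be in (0, 1)")


@dataclass
class SequenceClassification:
    """Outcome of the sequence classification for one recording."""

    presence: str                     #: '+' or '-'
    selected: dict[str, Peak] = field(default_factory=dict)
    reasons: list[str] = field(default_factory=list)
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self):
        if self.presence not in ("+", "-"):
            raise ValueError("presence must be '+' or '-'")
        if self.presence == "+" and self.reasons:
            raise ValueError("a '+' classification cannot carry reasons")


def detect_peaks(curve: SSCCurve, config: ClassifierConfig | None = None
                 ) -> dict[str, list[Peak]]:
    """Local maxima of each segment's contribution curve.

    The curve is padded with zero contribution on both sides (no motion
    outside the movement), so maxima at the window edges are detected.
    Plateaus count as a single peak at their midpoint. Sub-threshold maxima
    are returned flagged insignificant.
    """
    if config is None:
        config = ClassifierConfig()
    out: dict[str, list[Peak]] = {}
    for seg in SEGMENTS:
        y = curve.y[seg]
        peaks: list[Peak] = []
        if len(y):
            ypad = np.concatenate([[0.0], y, [0.0]])
            idx, props = find_peaks(ypad, prominence=0.0, plateau_size=1)
            for k, i in enumerate(idx):
                le, re = props["left_edges"][k], props["right_edges"][k]
                mid = int((le + re) // 2)
                j = min(max(mid - 1, 0), len(y) - 1)
                prom = float(props["prominences"][k])
                peaks.append(Peak(
                    segment=seg,
                    x=float(curve.x[j]),
                    height=float(ypad[i]),
                    prominence=prom,
                    significant=prom >= config.significance_threshold - 1e-12,
                ))
        out[seg] = sorted(peaks, key=lambda p: p.x)
    return out


def classify(curve_or_peaks, config: ClassifierConfig | None = None) -> SequenceClassification:
    """Classify one recording as having ('+') or lacking ('-') the sequence.

    Within the terminal phase (last ``terminal_phase_fraction`` of cumulative
    rotation) each segment's highest significant peak is selected; presence is
    '+' iff the selected peaks are ordered C4-C5 < C5-C6 < C6-C7, no pair lies
    within ``tie_tolerance``, and every later C4-C5 local maximum stays below
    ``trailing_c45_max_ratio`` times the selected C4-C5 peak. Otherwise '-'
    with explicit reason codes. An insufficient-motion curve classifies '-'
    with that reason.
    """
    if config is None:
        config = ClassifierConfig()

    if isinstance(curve_or_peaks, SSCCurve):
        curve = curve_or_peaks
        if curve.insufficient_motion:
            return SequenceClassification("-", reasons=["insufficient-motion"], config=config)
        peaks = detect_peaks(curve, config)
        t0 = curve.x_start + (1.0 - config.terminal_phase_fraction) * curve.block_net
    else:
        peaks = curve_or_peaks
        all_x = [p.x for ps in peaks.values() for p in ps]
        if not all_x:
            return SequenceClassification(
                "-", reasons=[f"no-significant-peak:{s}" for s in SEGMENTS], config=config)
        span = max(all_x) - min(all_x)
        t0 = min(all_x) + (1.0 - config.terminal_phase_fraction) * span

    reasons: list[str] = []
    selected: dict[str, Peak] = {}
    for seg in SEGMENTS:
        cands = [p for p in peaks[seg] if p.significant and p.x >= t0 - 1e-9]
        if not cands:
            reasons.append(f"no-significant-peak:{seg}")
        else:
            selected[seg] = max(cands, key=lambda p: (p.prominence, -p.x))

    if len(selected) == len(SEGMENTS):
        xs = [selected[s].x for s in SEGMENTS]
        if any(abs(xs[i] - xs[j]) <= config.tie_tolerance
               for i in range(3) for j in range(i + 1, 3)):
            reasons.append("tie")
        elif not (xs[0] < xs[1] < xs[2]):
            reasons.append("order-violation")

    if len(selected) == len(SEGMENTS):
        # A C4-C5 peak at the very end of extension (after the selected C6-C7
        # peak) is normal only while much smaller than the main C4-C5 peak.
        # The rule compares visible heights and applies whether or not the
        # late peak clears the significance threshold: it is relative, and a
        # threshold-gated version would let raising the threshold flip '-'
        # to '+'.
        sel = selected["C4-C5"]
        limit = config.trailing_c45_max_ratio * sel.height
        after = selected["C6-C7"].x
        if any(p.x > after and p.height >= limit for p in peaks["C4-C5"]):
            reasons.append("trailing-c45-too-large")

    if reasons:
        return SequenceClassification("-", selected=selected, reasons=sorted(set(reasons)),
                                      config=config)
    return SequenceClassification("+", selected=selected, config=config)


def cohort_prevalence(classifications) -> float:
    """Percentage of '+' classifications in a cohort.

    Accepts SequenceClassification objects, '+'/'-' strings, or booleans.
    """
    items = list(classifications)
    if not items:
        raise ValueError("cannot compute prevalence of an empty cohort")
    count = 0
    for c in items:
        if isinstance(c, SequenceClassification):
            count += c.presence == "+"
        elif isinstance(c, str):
            if c not in ("+", "-"):
                raise ValueError(f"unrecognized classification {c!r}")
            count += c == "+"
        else:
            count += bool(c)
    return 100.0 * count / len(items)
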