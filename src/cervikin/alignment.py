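"""Sagittal alignment (Cobb angles) and study eligibility filters.

Cobb angles are measured between two endplate lines on a neutral lateral
radiograph: C2-C7 alignment between the inferior endplates of C2 and C7, and
per-segment alignment between the superior endplate of the upper vertebra and
the inferior endplate of the lower vertebra. Lordosis is positive, kyphosis
negative. Landmarks are pixel coordinates (origin top-left, y down); by
default the subject faces the left of the image, the standard lateral view —
set ``facing="right"`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cervikin.records import CohortRecord
from cervikin.segments import SEGMENT_PAIRS


@dataclass
class LandmarkSet:
    """Endplate landmarks on one lateral radiograph.

    ``points`` maps ``(vertebra, endplate)`` — endplate in
    {"superior", "inferior"} — to an (anterior, posterior) pair of pixel
    (x, y) points.
    """

    points: dict[tuple[str, str], tuple[tuple[float, float], tuple[float, float]]]
    facing: str = "left"

    def __post_init__(self):
        if self.facing not in ("left", "right"):
            raise ValueError("facing must be 'left' or 'right'")
        for key, (a, p) in self.points.items():
            if np.allclose(a, p):
                raise ValueError(f"endplate {key} has coincident landmark points")

    def line(self, vertebra: str, endplate: str):
        try:
            return self.points[(vertebra, endplate)]
        except KeyError:
            raise KeyError(f"no landmarks for {vertebra} {endplate} endplate") from None


def _line_angle(line, facing: str) -> float:
    """Orientation (degrees, y-up sense) of the anterior->posterior direction."""
    (ax, ay), (px, py) = line
    dx, dy = px - ax, py - ay
    if dx == 0 and dy == 0:
        raise ValueError("endplate line is degenerate (coincident points)")
    ang = math.degrees(math.atan2(-dy, dx))  # pixel y points down
    if facing == "right":
        ang = 180.0 - ang
    return ang


def cobb_angle(line1, line2, facing: str = "left") -> float:
    """Signed Cobb angle (degrees) between two endplate lines.

    ``line1`` is the upper (cranial) endplate line, ``line2`` the lower
    (caudal) one, each an ``((ax, ay), (px, py))`` anterior/posterior pair.
    Lordosis (lines converging posteriorly) is positive; magnitude <= 90.
    Swapping the two lines negates the angle.
    """
    d = _line_angle(line2, facing) - _line_angle(line1, facing)
    d = (d + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    if d > 90.0:
        d -= 180.0
    elif d <= -90.0:
        d += 180.0
    return d


def cobb_c2_c7(landmarks: LandmarkSet) -> float:
    """C2-C7 sagittal alignment: inferior C2 endplate vs inferior C7 endplate."""
    return cobb_angle(landmarks.line("C2", "inferior"),
                      landmarks.line("C7", "inferior"), facing=landmarks.facing)


def segment_cobb(landmarks: LandmarkSet, segment: str) -> float:
    """Segmental alignment: superior endplate of the upper vertebra vs
    inferior endplate of the lower vertebra."""
    try:
        upper, lower = SEGMENT_PAIRS[segment]
    except KeyError:
        raise ValueError(f"unknown segment {segment!r}") from None
    return cobb_angle(landmarks.line(upper, "superior"),
                      landmarks.line(lower, "inferior"), facing=landmarks.facing)


@dataclass
class EligibilityResult:
    included: bool
    reasons: list[str] = field(default_factory=list)


def eligibility(record: CohortRecord,
                age_range: tuple[float, float] = (55.0, 70.0),
                max_ndi: float = 4.0,
                max_ks: int = 3) -> EligibilityResult:
    """Apply the study's inclusion filter to one individual.

    Included iff age is within ``age_range`` (inclusive), NDI points <= 4,
    and every segmental Kellgren score <= 3 (a score of 4 excludes).
    Missing required fields raise ``ValueError``.
    """
    for name in ("age", "ndi_points", "ks"):
        if getattr(record, name) is None:
            raise ValueError(f"record {record.id}: missing required field {name!r}")
    reasons = []
    if not age_range[0] <= record.age <= age_range[1]:
        reasons.append(f"age {record.age:g} outside [{age_range[0]:g}, {age_range[1]:g}]")
    if record.ndi_points > max_ndi:
        reasons.append(f"NDI {record.ndi_points:g} > {max_ndi:g}")
    bad = {seg: k for seg, k in record.ks.items() if k > max_ks}
    if bad:
        reasons.append("KS > %d in %s" % (max_ks, ", ".join(sorted(bad))))
    return EligibilityResult(included=not reasons, reasons=reasons)
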