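"""Segmental angle series, SSC curves and range-of-motion summaries.

The sequence-of-segmental-contributions (SSC) curve plots each segment's
per-frame rotation against the cumulative C4-C7 block rotation during
extension. Segmental series are smoothed with a local-polynomial
(Savitzky-Golay) filter before differencing; the endpoints are pinned to the
raw values so that each curve's integral conserves the segment's net
rotation exactly. Frames where the block momentarily regresses are folded
onto the running maximum of cumulative rotation for grid placement while the
(possibly negative) contributions are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from cervikin.segments import SEGMENT_PAIRS, SEGMENTS, VERTEBRAE


@dataclass
class SegmentSeries:
    """Per-frame relative angle (degrees) of one motion segment."""

    segment: str
    angles: np.ndarray
    fps: float = 10.0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if not np.all(np.isfinite(self.angles)):
            raise ValueError(f"non-finite angles in segment {self.segment}")


@dataclass
class SmoothingConfig:
    """SSC construction parameters.

    window/polyorder configure the Savitzky-Golay filter on the angle series;
    grid_step is the cumulative-rotation resampling step (degrees);
    min_motion is the net block extension (degrees) below which the recording
    is flagged "insufficient motion" instead of producing a curve.
    """

    window: int = 5
    polyorder: int = 2
    grid_step: float = 0.1
    min_motion: float = 3.0


@dataclass
class SSCCurve:
    """Segmental contributions resampled on a uniform cumulative-rotation grid.

    Attributes
    ----------
    x : array
        Grid cell midpoints (degrees of cumulative block rotation), strictly
        increasing.
    y : dict segment -> array
        Contribution in degrees per frame interval: the rate scaled by the
        local per-frame block advance, so heights are the per-frame rotations
        the significance threshold (0.3 deg) refers to.
    y_rate : dict segment -> array
        Contribution rate in degrees per degree of cumulative rotation.
    grid_step : float
        Actual grid spacing (degrees).
    frame_step : float
        Mean per-frame block advance (degrees) used to scale ``y``.
    net : dict segment -> float
        Net rotation per segment (degrees) over the analysis window.
    block_net : float
        Net block extension (degrees).
    insufficient_motion : bool
        True when the block moved less than the configured minimum; the grid
        and curves are then empty.
    """

    x: np.ndarray
    y: dict[str, np.ndarray]
    y_rate: dict[str, np.ndarray]
    grid_step: float
    frame_step: float
    net: dict[str, float]
    block_net: float
    insufficient_motion: bool = False
    config: SmoothingConfig = field(default_factory=SmoothingConfig)

    @property
    def x_start(self) -> float:
        """Left edge of the analysis window on the cumulative-rotation axis."""
        return float(self.x[0] - self.grid_step / 2) if len(self.x) else 0.0

    def integral(self, segment: str) -> float:
        """Integral of the contribution rate over cumulative rotation (degrees)."""
        return float(np.sum(self.y_rate[segment]) * self.grid_step)


@dataclass
class RomSummary:
    """Segmental and total range of motion (degrees) for one recording."""

    srom: dict[str, float]
    trom: float
    method: str
    timepoint: str | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.srom.values()) or self.trom < 0:
            raise ValueError("ranges of motion must be non-negative")


def segmental_angles(poses) -> dict[str, SegmentSeries]:
    """Relative segment angles from tracked vertebral poses.

    The angle of segment (upper, lower) is ``theta_upper - theta_lower`` per
    frame, referenced to zero at frame 0. ``poses`` is a
    :class:`~cervikin.tracking.PoseSet` (or anything with ``theta(vertebra)``
    and ``n_frames``).

    Raises
    ------
    ValueError
        If a vertebra is missing or a track is incomplete, naming it.
    """
    thetas = {}
    for v in VERTEBRAE:
        try:
            th = poses.theta(v)
        except KeyError:
            raise ValueError(f"poses are missing vertebra {v}") from None
        if len(th) != poses.n_frames:
            raise ValueError(
                f"vertebra {v} has {len(th)} poses for {poses.n_frames} frames"
            )
        thetas[v] = np.asarray(th, dtype=float)

    fps = getattr(poses, "fps", 10.0)
    out = {}
    for seg, (upper, lower) in SEGMENT_PAIRS.items():
        rel = thetas[upper] - thetas[lower]
        out[seg] = SegmentSeries(segment=seg, angles=rel - rel[0], fps=fps)
    return out


def cumulative_block(series: dict[str, SegmentSeries]) -> np.ndarray:
    """Per-frame cumulative C4-C7 block rotation: the sum of the three segments.

    By additivity this equals ``theta_C4 - theta_C7`` exactly.
    """
    lengths = {seg: len(series[seg].angles) for seg in SEGMENTS}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"segment series lengths differ: {lengths}")
    return sum(series[seg].angles for seg in SEGMENTS)


def _smooth(values: np.ndarray, config: SmoothingConfig) -> np.ndarray:
    """Savitzky-Golay smoothing with endpoints pinned to the raw values."""
    n = len(values)
    window = min(config.window, n if n % 2 == 1 else n - 1)
    if window <= config.polyorder:
        return values.copy()
    out = savgol_filter(values, window_length=window, polyorder=config.polyorder,
                        mode="interp")
    out[0], out[-1] = values[0], values[-1]
    return out


def build_ssc(series: dict[str, SegmentSeries], block: np.ndarray | None = None,
              config: SmoothingConfig | None = None) -> SSCCurve:
    """Build the SSC curve: contributions vs cumulative block rotation.

    Contributions are resampled on a uniform cumulative-rotation grid (default
    0.1 deg). The x-axis is the running maximum of the smoothed block angle,
    so transient negative block excursions fold back while their (negative)
    segmental contributions are preserved, and each curve's integral equals
    its segment's net rotation exactly.

    Recordings whose net block extension is below ``config.min_motion``
    (default 3 deg) return a curve flagged ``insufficient_motion`` instead.
    """
    if config is None:
        config = SmoothingConfig()
    smoothed = {seg: _smooth(series[seg].angles, config) for seg in SEGMENTS}
    block_s = sum(smoothed[seg] for seg in SEGMENTS)  # keeps additivity
    if block is not None and len(block) != len(block_s):
        raise ValueError("block length does not match segment series")

    extension = float(np.max(block_s) - block_s[0])
    net = {seg: float(smoothed[seg][-1] - smoothed[seg][0]) for seg in SEGMENTS}
    if extension < config.min_motion:
        return SSCCurve(
            x=np.array([]), y={s: np.array([]) for s in SEGMENTS},
            y_rate={s: np.array([]) for s in SEGMENTS},
            grid_step=config.grid_step, frame_step=0.0, net=net,
            block_net=extension, insufficient_motion=True, config=config,
        )

    m = np.maximum.accumulate(block_s)
    # Strictly increasing breakpoints: the last frame at each cumulative-
    # rotation level, except the starting level which keeps frame 0 so the
    # integral spans the full recording (exact conservation).
    last = np.append(np.diff(m) > 0, True)
    keep = last & (m > m[0])
    keep[0] = True
    xs = m[keep]

    n_frames = len(block_s)
    span = float(m[-1] - m[0])
    n_cells = max(1, int(round(span / config.grid_step)))
    edges = np.linspace(m[0], m[-1], n_cells + 1)
    step = float(edges[1] - edges[0]) if n_cells > 0 else config.grid_step
    frame_step = span / (n_frames - 1)

    x_mid = (edges[:-1] + edges[1:]) / 2
    # Local per-frame block advance along the x-axis: converts the rate into
    # the per-frame rotation the paper's curves (and the 0.3 deg rule) use.
    if len(xs) > 1:
        interval_mid = (xs[:-1] + xs[1:]) / 2
        local_step = np.interp(x_mid, interval_mid, np.diff(xs))
    else:
        local_step = np.full_like(x_mid, frame_step)

    y, y_rate = {}, {}
    for seg in SEGMENTS:
        a_vals = smoothed[seg][keep]
        a_grid = np.interp(edges, xs, a_vals)
        rate = np.diff(a_grid) / step
        y_rate[seg] = rate
        y[seg] = rate * local_step
    return SSCCurve(x=x_mid, y=y, y_rate=y_rate, grid_step=step,
                    frame_step=frame_step, net=net, block_net=span,
                    insufficient_motion=False, config=config)


def rom_summary(series: dict[str, SegmentSeries], block: np.ndarray | None = None,
                method: str = "extremal", timepoint: str | None = None) -> RomSummary:
    """Range-of-motion summary per segment and for the C4-C7 block.

    ``method="endpoint"`` compares last to first frame; ``method="extremal"``
    (default) takes max minus min over the whole path — maximal segmental
    rotation is often reached away from the movement endpoints, so the
    extremal path value is the faithful range.
    """
    if method not in ("endpoint", "extremal"):
        raise ValueError("method must be 'endpoint' or 'extremal'")
    if block is None:
        block = cumulative_block(series)
    srom = {}
    for seg in SEGMENTS:
        a = series[seg].angles
        srom[seg] = float(abs(a[-1] - a[0])) if method == "endpoint" else float(a.max() - a.min())
    trom = float(abs(block[-1] - block[0])) if method == "endpoint" else float(block.max() - block.min())
    return RomSummary(srom=srom, trom=trom, method=method, timepoint=timepoint)
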