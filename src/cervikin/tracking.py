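"""Rigid 2D template tracking of vertebrae across a fluoroscopy sequence.

Each vertebra is annotated once, on the first frame, as a closed contour. The
tracker then follows it frame by frame with a planar rigid transform
(rotation about the contour centroid plus translation), scoring candidate
poses by normalized cross-correlation (NCC) of the image intensities under
the transformed contour against the reference frame. Inter-frame motion at
10 frames/s is small, so each frame's pose is found by a coarse grid search
around the previous frame's pose followed by Nelder-Mead refinement.

Frames where the best similarity falls below a configurable floor are marked
"lost" and reported — never silently interpolated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from cervikin.segments import VERTEBRAE
from cervikin.synthetic import rotation_matrix

logger = logging.getLogger(__name__)


@dataclass
class ContourTemplate:
    """A closed vertebral contour annotated on the reference frame.

    Attributes
    ----------
    label : str
        Vertebra label (C4..C7).
    vertices : (N, 2) array
        Polygon vertices, pixel (x, y) coordinates, N >= 3, simple polygon.
    center : (2,) array
        Polygon centroid; the rotation pivot for all poses of this vertebra.
    """

    label: str
    vertices: np.ndarray
    center: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("contour needs at least 3 (x, y) vertices")
        poly = Polygon(self.vertices)
        if not poly.is_simple or poly.area <= 0:
            raise ValueError(f"contour for {self.label} is not a simple polygon")
        if self.center is None:
            self.center = np.array(poly.centroid.coords[0])


@dataclass
class Pose:
    """Rigid pose of one vertebra in one frame, relative to the reference frame."""

    frame: int
    vertebra: str
    theta_deg: float
    tx_px: float
    ty_px: float
    score: float = math.nan
    lost: bool = False


@dataclass
class TrackConfig:
    """Search parameters for per-frame pose estimation.

    The coarse window (±2 deg, ±8 px) around the previous pose comfortably
    covers fluent inter-frame motion at 10 frames/s; the simplex refinement
    converges to ~0.01 deg and ~0.1 px.
    """

    search_theta: float = 2.0
    search_shift: float = 8.0
    coarse_theta_step: float = 0.5
    coarse_shift_step: float = 2.0
    xatol: float = 0.01
    min_score: float = 0.5
    #: dilation (px) of the contour when sampling: a uniform body interior has
    #: no intensity variance, so the template must include the edge region.
    band: float = 3.0


@dataclass
class PoseSet:
    """Tracked poses for all vertebrae, plus a manual-correction log."""

    poses: dict[str, list[Pose]]
    n_frames: int
    corrections: list[dict] = field(default_factory=list)

    def theta(self, vertebra: str) -> np.ndarray:
        return np.array([p.theta_deg for p in self.poses[vertebra]])

    def lost_frames(self) -> dict[str, list[int]]:
        return {v: [p.frame for p in ps if p.lost] for v, ps in self.poses.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"frame": p.frame, "vertebra": v, "theta_deg": p.theta_deg,
             "tx_px": p.tx_px, "ty_px": p.ty_px, "score": p.score, "lost": p.lost}
            for v, ps in self.poses.items() for p in ps
        ]
        return pd.DataFrame(rows).sort_values(["vertebra", "frame"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PoseSet":
        poses: dict[str, list[Pose]] = {}
        for v, g in df.groupby("vertebra"):
            g = g.sort_values("frame")
            poses[str(v)] = [
                Pose(int(r.frame), str(v), float(r.theta_deg), float(r.tx_px),
                     float(r.ty_px),
                     float(getattr(r, "score", math.nan)),
                     bool(getattr(r, "lost", False)))
                for r in g.itertuples()
            ]
        n = max(len(ps) for ps in poses.values())
        return cls(poses=poses, n_frames=n)


def transform_points(points: np.ndarray, center: np.ndarray, theta_deg: float,
                     tx: float, ty: float) -> np.ndarray:
    """Apply a rigid pose (rotation about ``center`` then translation) to points."""
    rot = rotation_matrix(theta_deg)
    return center + (np.asarray(points, float) - center) @ rot.T + np.array([tx, ty])


def _template_samples(template: ContourTemplate, frame0: np.ndarray, band: float = 3.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates under the (dilated) contour and reference intensities."""
    verts = template.vertices
    if band > 0:
        poly = Polygon(verts).buffer(band, join_style=2)
        verts = np.array(poly.exterior.coords[:-1])
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], frame0.shape)
    if len(rr) < 16:
        raise ValueError(f"contour for {template.label} covers too few pixels")
    coords = np.column_stack([cc, rr]).astype(float)  # (x, y)
    ref = frame0[rr, cc].astype(float)
    return coords, ref


def _ncc(ref_z: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """NCC of zero-mean/unit-norm reference against rows of ``samples``."""
    s = samples - samples.mean(axis=-1, keepdims=True)
    denom = np.linalg.norm(s, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (s @ ref_z) / denom
    return np.where(denom > 1e-12, out, -np.inf)


def _sample(frame: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear image samples at (x, y) points (last axis), any leading shape."""
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])
    vals = map_coordinates(frame, coords, order=1, mode="nearest")
    return vals.reshape(pts.shape[:-1])


def _score_pose(frame, coords, center, ref_z, pose_vec):
    pts = transform_points(coords, center, pose_vec[0], pose_vec[1], pose_vec[2])
    return float(_ncc(ref_z, _sample(frame, pts)[None, :])[0])


def track_sequence(frames: np.ndarray, templates: list[ContourTemplate] | dict,
                   config: TrackConfig | None = None) -> PoseSet:
    """Track every template across the stack; pose of frame 0 is the identity.

    Parameters
    ----------
    frames : (F, H, W) array
        Image stack, F >= 2.
    templates : list or dict of ContourTemplate
        Contours annotated on frame 0.

    Returns
    -------
    PoseSet
        One pose per vertebra per frame. Frames whose best NCC is below
        ``config.min_score`` (or whose template region has no intensity
        variance) are flagged ``lost`` and logged; the previous pose is
        carried so downstream indexing stays aligned.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need an image stack with at least 2 frames")
    if config is None:
        config = TrackConfig()
    if isinstance(templates, dict):
        templates = list(templates.values())

    thetas = np.arange(-config.search_theta, config.search_theta + 1e-9,
                       config.coarse_theta_step)
    shifts = np.arange(-config.search_shift, config.search_shift + 1e-9,
                       config.coarse_shift_step)
    dxy = np.array([[dx, dy] for dx in shifts for dy in shifts])

    all_poses: dict[str, list[Pose]] = {}
    for tpl in templates:
        coords, ref = _template_samples(tpl, frames[0], band=config.band)
        ref_z = ref - ref.mean()
        nrm = np.linalg.norm(ref_z)
        degenerate = nrm < 1e-9
        if not degenerate:
            ref_z = ref_z / nrm
        poses = [Pose(0, tpl.label, 0.0, 0.0, 0.0, score=1.0)]
        prev = np.zeros(3)
        for f in range(1, len(frames)):
            if degenerate:
                logger.warning("template %s has no intensity variance; frame %d lost",
                               tpl.label, f)
                poses.append(Pose(f, tpl.label, *prev, score=-math.inf, lost=True))
                continue
            frame = frames[f]
            best_score, best = -np.inf, prev
            for dth in thetas:
                th = prev[0] + dth
                pts = transform_points(coords, tpl.center, th, prev[1], prev[2])
                cand = pts[None, :, :] + dxy[:, None, :]
                scores = _ncc(ref_z, _sample(frame, cand))
                k = int(np.argmax(scores))
                if scores[k] > best_score:
                    best_score = scores[k]
                    best = np.array([th, prev[1] + dxy[k, 0], prev[2] + dxy[k, 1]])
            res = minimize(
                lambda v: -_score_pose(frame, coords, tpl.center, ref_z, v),
                best, method="Nelder-Mead",
                options={"xatol": config.xatol, "fatol": 1e-8, "maxiter": 400},
            )
            score = -res.fun
            lost = bool(score < config.min_score)
            if lost:
                logger.warning("vertebra %s lost at frame %d (NCC %.3f < %.3f)",
                               tpl.label, f, score, config.min_score)
                poses.append(Pose(f, tpl.label, *prev, score=score, lost=True))
            else:
                prev = res.x
                poses.append(Pose(f, tpl.label, float(res.x[0]), float(res.x[1]),
                                  float(res.x[2]), score=score))
        all_poses[tpl.label] = poses

    return PoseSet(poses=all_poses, n_frames=len(frames))


def manual_correction(poses: PoseSet, frame: int, vertebra: str,
                      corrected: Pose | tuple[float, float, float]) -> PoseSet:
    """Replace one pose with a manually verified one; the correction is logged.

    Returns a new PoseSet (the input is not mutated), so downstream kinematics
    recomputed from it reflect the corrected value.
    """
    if vertebra not in poses.poses:
        raise KeyError(f"no tracked vertebra {vertebra!r}")
    track = poses.poses[vertebra]
    if not 0 <= frame < len(track):
        raise IndexError(f"frame {frame} out of range for {vertebra} (0..{len(track) - 1})")
    if isinstance(corrected, Pose):
        new = replace(corrected, frame=frame, vertebra=vertebra, lost=False)
    else:
        th, tx, ty = corrected
        new = Pose(frame, vertebra, float(th), float(tx), float(ty), lost=False)
    new_tracks = {v: list(ps) for v, ps in poses.poses.items()}
    old = new_tracks[vertebra][frame]
    new_tracks[vertebra][frame] = new
    log = poses.corrections + [{
        "frame": frame, "vertebra": vertebra,
        "old": (old.theta_deg, old.tx_px, old.ty_px),
        "new": (new.theta_deg, new.tx_px, new.ty_px),
    }]
    logger.info("manual correction: %s frame %d -> theta=%.3f tx=%.2f ty=%.2f",
                vertebra, frame, new.theta_deg, new.tx_px, new.ty_px)
    return PoseSet(poses=new_tracks, n_frames=poses.n_frames, corrections=log)


def templates_from_phantom(phantom) -> list[ContourTemplate]:
    """Frame-0 contour templates matching a phantom's neutral-body geometry."""
    return [
        ContourTemplate(label=v, vertices=phantom.centers[v] + phantom.geometry[v])
        for v in VERTEBRAE
    ]
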