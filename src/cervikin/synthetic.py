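"""Ground-truth cervical kinematics and lateral-view phantom rendering.

The generator produces per-frame segmental extension angles for C4-C5, C5-C6
and C6-C7 whose contribution pattern along cumulative block rotation is fully
controlled: each segment contributes a broad baseline plus a Gaussian bump
centred at a chosen cumulative-rotation coordinate, optionally with a smaller
trailing C4-C5 bump late in extension. Bump centres are recentred by a
fixed-point iteration so the contribution maxima fall at the requested
coordinates of the *measured* cumulative block rotation. Each segment's
increments sum exactly to its requested total rotation, and the block angle
is defined as the sum of the segmental angles, so additivity holds exactly at
every frame. The block advances approximately uniformly over frames — faster
while a segment is at its contribution peak, as in real recordings.

A recording emulates a 10 frames/s extension acquisition (default 52 frames,
about 5 s of extension out of a 10 s flexion-extension cycle). Optionally,
recordings are rendered as lateral-view phantom image stacks (stacked
quadrilateral vertebral bodies, Gaussian blur, additive noise) with the true
per-frame rigid pose of every vertebra stored alongside, so the tracker can be
benchmarked against known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from cervikin.records import CohortRecord
from cervikin.segments import (
    SEGMENTS,
    VERTEBRAE,
    FrameOutOfViewError,
    PeakOverlapError,
)

logger = logging.getLogger(__name__)

#: Fractions of total block rotation at which the young-pattern bumps sit,
#: cranial to caudal — ordered within the terminal half of extension.
_YOUNG_CENTER_FRACTIONS = (0.55, 0.72, 0.88)

#: Segment totals (degrees) used for the default "young_consistent" profile;
#: subaxial extension on the scale of an asymptomatic cohort's first session.
_YOUNG_TOTALS = (11.1, 7.9, 6.8)

#: Reduced totals (degrees) for the "elderly_inconsistent" profile.
_ELDERLY_TOTALS = (9.3, 7.1, 5.9)


@dataclass(frozen=True)
class MotionProfileSpec:
    """Specification of one synthetic extension recording.

    Parameters
    ----------
    segment_total_rotation : 3 floats
        Net extension (degrees) of C4-C5, C5-C6, C6-C7; must sum to ``trom``.
    peak_centers : 3 floats
        Cumulative-rotation coordinate (degrees) of each segment's main
        contribution bump.
    peak_widths : 3 floats
        Gaussian sigma (degrees) of each bump.
    trom : float
        Total C4-C7 extension (degrees).
    trailing_c45_fraction : float
        Height of a late C4-C5 bump relative to its main bump, in [0, 1).
    trailing_c45_center : float, optional
        Cumulative-rotation coordinate of the trailing bump; defaults to
        ``0.97 * trom``.
    peak_mass_fraction : float
        Fraction of each segment's total rotation carried by its bump(s); the
        remainder is the shared baseline contribution over the movement.
        0 gives baseline-only (with a flat baseline: constant-rate) curves.
    early_phase_center_frac, early_phase_width_frac : float, optional
        Shape of the shared baseline as fractions of ``trom``. When the width
        is None the baseline is flat; otherwise it is a broad Gaussian "early
        phase" in which all segments rotate together — terminal contribution
        peaks can only sit late on the cumulative-rotation axis if most of
        the rotation mass precedes them.
    negative_excursion : float
        If positive, depth (degrees) of a brief negative-motion dip injected
        into C5-C6 early in the movement (compensated within the segment so
        its total is preserved) — emulates the excursions seen in low-motion
        recordings.
    noise_sd : float
        SD (degrees) of i.i.d. Gaussian noise added to each per-frame
        segmental increment.
    n_frames : int
        Number of frames (>= 10).
    fps : float
        Acquisition rate, frames per second.
    seed : int
        Seed for the noise stream.
    label : str
        "young_consistent" | "elderly_inconsistent" | "custom".
    """

    segment_total_rotation: tuple[float, float, float]
    peak_centers: tuple[float, float, float]
    peak_widths: tuple[float, float, float]
    trom: float
    trailing_c45_fraction: float = 0.0
    trailing_c45_center: float | None = None
    peak_mass_fraction: float = 0.7
    early_phase_center_frac: float = 0.25
    early_phase_width_frac: float | None = None
    negative_excursion: float = 0.0
    noise_sd: float = 0.0
    n_frames: int = 52
    fps: float = 10.0
    seed: int = 0
    label: str = "custom"

    def __post_init__(self):
        totals = np.asarray(self.segment_total_rotation, dtype=float)
        if totals.shape != (3,):
            raise ValueError("segment_total_rotation must have three entries")
        if abs(float(totals.sum()) - self.trom) > 1e-9:
            raise ValueError(
                f"segment totals {totals.tolist()} must sum to trom={self.trom} within 1e-9"
            )
        if np.any(np.asarray(self.peak_widths, dtype=float) <= 0):
            raise ValueError("peak_widths must be positive")
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.trailing_c45_fraction < 1.0:
            raise ValueError("trailing_c45_fraction must be in [0, 1)")
        if not 0.0 <= self.peak_mass_fraction <= 1.0:
            raise ValueError("peak_mass_fraction must be in [0, 1]")
        if self.negative_excursion < 0:
            raise ValueError("negative_excursion must be >= 0")

    @property
    def grid_resolution(self) -> float:
        """Cumulative-rotation spacing between successive frames (degrees)."""
        return self.trom / (self.n_frames - 1)


@dataclass
class GroundTruthRecording:
    """Per-frame ground-truth segmental angles for one recording.

    ``segment_angles`` carry the generated (possibly noisy) angles;
    ``clean_segment_angles`` the noiseless construction. The block C4-C7 angle
    is *defined* as the sum of the three segmental angles, so additivity holds
    exactly at every frame.
    """

    segment_angles: dict[str, np.ndarray]
    clean_segment_angles: dict[str, np.ndarray]
    fps: float
    label: str
    spec: MotionProfileSpec
    poses: "object | None" = None  # pandas DataFrame once rendered

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.segment_angles.values())))

    @property
    def block(self) -> np.ndarray:
        """Cumulative C4-C7 block angle, the exact sum of the segment angles."""
        return sum(self.segment_angles[s] for s in SEGMENTS)

    @property
    def clean_block(self) -> np.ndarray:
        return sum(self.clean_segment_angles[s] for s in SEGMENTS)

    def srom(self, method: str = "extremal", clean: bool = False) -> dict[str, float]:
        """Segmental range of motion (degrees) per segment."""
        angles = self.clean_segment_angles if clean else self.segment_angles
        out = {}
        for seg in SEGMENTS:
            a = angles[seg]
            out[seg] = float(abs(a[-1] - a[0])) if method == "endpoint" else float(a.max() - a.min())
        return out

    def trom(self, method: str = "extremal", clean: bool = False) -> float:
        b = self.clean_block if clean else self.block
        return float(abs(b[-1] - b[0])) if method == "endpoint" else float(b.max() - b.min())

    def vertebra_thetas(self) -> dict[str, np.ndarray]:
        """Absolute vertebral rotations with C7 held fixed (degrees)."""
        s45 = self.segment_angles["C4-C5"]
        s56 = self.segment_angles["C5-C6"]
        s67 = self.segment_angles["C6-C7"]
        return {
            "C4": s45 + s56 + s67,
            "C5": s56 + s67,
            "C6": s67,
            "C7": np.zeros_like(s67),
        }


def _gauss(u: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - center) / width) ** 2) / (width * np.sqrt(2 * np.pi))


def _increments(spec: MotionProfileSpec, centers: np.ndarray, c_tr: float) -> np.ndarray:
    """Per-frame segmental increments (n_frames-1, 3), columns exactly the totals."""
    totals = np.asarray(spec.segment_total_rotation, float)
    widths = np.asarray(spec.peak_widths, float)
    n_int = spec.n_frames - 1
    du = spec.trom / n_int
    u = (np.arange(n_int) + 0.5) * du
    mu = spec.peak_mass_fraction
    if spec.early_phase_width_frac is None:
        base = np.full(n_int, 1.0 / spec.trom)
    else:
        base = _gauss(u, spec.early_phase_center_frac * spec.trom,
                      spec.early_phase_width_frac * spec.trom)
        base /= base.sum() * du
    dens = np.empty((n_int, 3))
    for i in range(3):
        bump = _gauss(u, centers[i], widths[i])
        if i == 0 and spec.trailing_c45_fraction > 0:
            bump = (bump + spec.trailing_c45_fraction * _gauss(u, c_tr, widths[0]))
        dens[:, i] = (1.0 - mu) * base + mu * bump / max(bump.sum() * du, 1e-300)
    inc = dens * du
    # Exact conservation: each column sums to its segment's total rotation.
    inc *= totals / inc.sum(axis=0)
    return inc


def _apply_negative_excursion(spec: MotionProfileSpec, inc: np.ndarray) -> np.ndarray:
    """Brief negative-motion dip in C5-C6 early in the movement, compensated
    within the segment so its total rotation is unchanged."""
    n_int = len(inc)
    du = spec.trom / n_int
    u = (np.arange(n_int) + 0.5) * du
    dip = _gauss(u, 0.3 * spec.trom, 0.05 * spec.trom)
    at_center = inc[int(np.argmax(dip)), 1]
    dip *= (spec.negative_excursion + at_center) / dip.max()
    inc = inc.copy()
    inc[:, 1] += dip.sum() / n_int - dip
    return inc


def generate_profile(spec: MotionProfileSpec) -> GroundTruthRecording:
    """Generate one ground-truth recording from a motion-profile spec.

    The noiseless segmental-contribution curve has its maxima at the requested
    ``peak_centers`` on the measured cumulative-rotation axis (within the
    frame grid resolution; a fixed-point iteration recentres the latent bump
    positions), each segment's net rotation equals its requested total, and
    the block angle equals the sum of segment angles exactly at every frame.

    Raises
    ------
    PeakOverlapError
        If two peak centers are closer than the frame grid can resolve.
    """
    centers = np.asarray(spec.peak_centers, float)
    db = spec.grid_resolution
    d = np.abs(centers[:, None] - centers[None, :])
    if np.any(d[np.triu_indices(3, 1)] < db):
        raise PeakOverlapError(
            f"peak centers {centers.tolist()} closer than grid resolution {db:.3f} deg"
        )

    c_tr_target = (spec.trailing_c45_center if spec.trailing_c45_center is not None
                   else 0.97 * spec.trom)
    n_int = spec.n_frames - 1
    u_edges = np.linspace(0.0, spec.trom, spec.n_frames)
    c_u = centers.copy()
    c_tr = c_tr_target
    inc = _increments(spec, c_u, c_tr)
    if spec.peak_mass_fraction > 0:
        lo, hi = 0.02 * spec.trom, 0.995 * spec.trom
        for _ in range(20):
            b_edges = np.concatenate([[0.0], np.cumsum(inc.sum(axis=1))])
            # invert the monotone latent->measured map so each bump's latent
            # centre lands at the requested measured coordinate
            c_new = np.clip(np.interp(centers, b_edges, u_edges), lo, hi)
            c_tr_new = float(np.clip(np.interp(c_tr_target, b_edges, u_edges), lo, hi))
            if np.max(np.abs(c_new - c_u)) < 1e-6 and abs(c_tr_new - c_tr) < 1e-6:
                c_u, c_tr = c_new, c_tr_new
                break
            c_u, c_tr = c_new, c_tr_new
            inc = _increments(spec, c_u, c_tr)

    if spec.negative_excursion > 0:
        inc = _apply_negative_excursion(spec, inc)

    clean = {
        seg: np.concatenate([[0.0], np.cumsum(inc[:, i])]) for i, seg in enumerate(SEGMENTS)
    }
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy_inc = inc + rng.normal(0.0, spec.noise_sd, inc.shape)
        angles = {
            seg: np.concatenate([[0.0], np.cumsum(noisy_inc[:, i])])
            for i, seg in enumerate(SEGMENTS)
        }
    else:
        angles = {seg: a.copy() for seg, a in clean.items()}

    return GroundTruthRecording(
        segment_angles=angles,
        clean_segment_angles=clean,
        fps=spec.fps,
        label=spec.label,
        spec=spec,
    )


def young_profile(seed: int = 0, noise_sd: float = 0.05, n_frames: int = 52,
                  trailing_c45_fraction: float = 0.3) -> MotionProfileSpec:
    """Default profile with the consistent young-adult extension pattern.

    Bumps are ordered C4-C5 < C5-C6 < C6-C7 within the terminal half of
    extension, with an allowed small trailing C4-C5 bump at the very end.
    """
    trom = float(sum(_YOUNG_TOTALS))
    return MotionProfileSpec(
        segment_total_rotation=_YOUNG_TOTALS,
        peak_centers=tuple(round(f * trom, 3) for f in _YOUNG_CENTER_FRACTIONS),
        peak_widths=(1.6, 1.6, 1.6),
        trom=trom,
        trailing_c45_fraction=trailing_c45_fraction,
        peak_mass_fraction=0.55,
        early_phase_width_frac=0.18,
        noise_sd=noise_sd,
        n_frames=n_frames,
        seed=seed,
        label="young_consistent",
    )


def elderly_profile(seed: int = 0, noise_sd: float = 0.15, n_frames: int = 52,
                    permutation: tuple[int, int, int] = (2, 0, 1)) -> MotionProfileSpec:
    """Profile with the aged pattern: permuted peak order and reduced totals.

    ``permutation[i]`` gives the rank position whose center coordinate segment
    ``i`` receives; any non-identity permutation breaks the normal ordering.
    """
    if tuple(sorted(permutation)) != (0, 1, 2) or permutation == (0, 1, 2):
        raise ValueError("permutation must be a non-identity permutation of (0, 1, 2)")
    trom = float(sum(_ELDERLY_TOTALS))
    ordered = [round(f * trom, 3) for f in _YOUNG_CENTER_FRACTIONS]
    centers = tuple(ordered[p] for p in permutation)
    return MotionProfileSpec(
        segment_total_rotation=_ELDERLY_TOTALS,
        peak_centers=centers,
        peak_widths=(1.5, 1.5, 1.5),
        trom=trom,
        trailing_c45_fraction=0.0,
        peak_mass_fraction=0.55,
        early_phase_width_frac=0.18,
        noise_sd=noise_sd,
        n_frames=n_frames,
        seed=seed,
        label="elderly_inconsistent",
    )


def generate_cohort(n: int, mix: float, seed: int,
                    noise_sd: float | None = None,
                    n_frames: int = 52) -> list[tuple[GroundTruthRecording, CohortRecord]]:
    """Generate a reproducible synthetic cohort.

    Exactly ``round(mix * n)`` individuals receive the young_consistent
    profile, the rest the elderly_inconsistent profile; order is shuffled.
    Peak centers and totals are jittered slightly per individual without
    breaking the label's ordering structure.

    Parameters
    ----------
    noise_sd : float, optional
        Override the per-label default frame noise (young 0.05, elderly 0.15);
        pass 0 for noiseless recordings.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must be in [0, 1]")
    n_young = int(round(mix * n))
    labels = ["young_consistent"] * n_young + ["elderly_inconsistent"] * (n - n_young)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    child_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)

    out = []
    perms = [(0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    for i, label in enumerate(labels):
        s = int(child_seeds[i])
        jit = np.random.default_rng(s)
        if label == "young_consistent":
            spec = young_profile(seed=s, noise_sd=0.05 if noise_sd is None else noise_sd,
                                 n_frames=n_frames)
        else:
            spec = elderly_profile(seed=s, noise_sd=0.15 if noise_sd is None else noise_sd,
                                   n_frames=n_frames,
                                   permutation=perms[jit.integers(len(perms))])
        scale = jit.uniform(0.9, 1.1, size=3)
        totals = tuple(float(t * c) for t, c in zip(spec.segment_total_rotation, scale))
        centers = tuple(float(c + jit.uniform(-0.3, 0.3)) for c in spec.peak_centers)
        spec = replace(spec, segment_total_rotation=totals, trom=float(sum(totals)),
                       peak_centers=centers)
        rec = generate_profile(spec)
        stub = CohortRecord(id=f"S{i + 1:02d}", label=label, seed=s)
        out.append((rec, stub))
    return out


# ---------------------------------------------------------------------------
# Phantom rendering
# ---------------------------------------------------------------------------

def default_geometry(image_size: tuple[int, int] = (1024, 1024)
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Default lateral-view geometry: four stacked trapezoidal bodies.

    Returns ``(corner_offsets, centers)`` keyed by vertebra, in pixels, scaled
    to the image size. Bodies sit on a mildly lordotic vertical arc with C4 at
    the top.
    """
    h, w = image_size
    bw, bh = 0.15 * w, 0.085 * h
    centers_y = np.array([0.24, 0.40, 0.56, 0.72]) * h
    centers_x = (0.5 + np.array([0.012, 0.0, 0.0, 0.012])) * w
    tilts = np.deg2rad([-6.0, -2.0, 2.0, 6.0])
    offsets, centers = {}, {}
    base = np.array([
        [-bw / 2, -bh / 2],
        [bw / 2 * 0.92, -bh / 2],
        [bw / 2, bh / 2],
        [-bw / 2 * 0.95, bh / 2],
    ])
    for v, cy, cx, t in zip(VERTEBRAE, centers_y, centers_x, tilts):
        c, s = np.cos(t), np.sin(t)
        rot = np.array([[c, s], [-s, c]])
        offsets[v] = base @ rot.T
        centers[v] = np.array([cx, cy])
    return offsets, centers


@dataclass
class PhantomSpec:
    """Rendering parameters for a lateral-view fluoroscopy phantom.

    The default 1024 x 1024 frame matches the acquisition protocol the
    generator emulates; smaller sizes scale the geometry proportionally.
    """

    image_size: tuple[int, int] = (1024, 1024)
    geometry: dict[str, np.ndarray] | None = None
    centers: dict[str, np.ndarray] | None = None
    background: float = 0.25
    contrast: float = 0.5
    blur_sigma: float = 1.5
    noise_sd: float = 0.01
    supersample: int = 4
    seed: int = 0

    def __post_init__(self):
        if min(self.image_size) < 128:
            raise ValueError("image size must be at least 128 pixels")
        if self.blur_sigma < 0:
            raise ValueError("blur sigma must be >= 0")
        if self.geometry is None or self.centers is None:
            geo, cen = default_geometry(self.image_size)
            if self.geometry is None:
                self.geometry = geo
            if self.centers is None:
                self.centers = cen
        polys = [
            Polygon(self.centers[v] + self.geometry[v]) for v in VERTEBRAE
        ]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersects(polys[j]):
                    raise ValueError(
                        f"vertebral bodies {VERTEBRAE[i]} and {VERTEBRAE[j]} overlap in neutral pose"
                    )


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """2D rotation, positive counter-clockwise in viewing (y-down pixel) coords."""
    c, s = np.cos(np.deg2rad(theta_deg)), np.sin(np.deg2rad(theta_deg))
    return np.array([[c, s], [-s, c]])


def vertebra_corners(phantom: PhantomSpec, vertebra: str,
                     theta_deg: float = 0.0, t: np.ndarray | None = None) -> np.ndarray:
    """Pixel corner coordinates of a vertebral body under a rigid pose."""
    rot = rotation_matrix(theta_deg)
    c = phantom.centers[vertebra]
    pts = c + phantom.geometry[vertebra] @ rot.T
    if t is not None:
        pts = pts + np.asarray(t, float)
    return pts


def render_frames(rec: GroundTruthRecording, phantom: PhantomSpec | None = None
                  ) -> tuple[np.ndarray, "object"]:
    """Render a recording as a phantom image stack with true poses.

    Each vertebra rotates rigidly about its own body centre by its absolute
    rotation (C7 held fixed). Returns ``(stack, poses)`` where ``stack`` is a
    float32 array of shape (n_frames, H, W) in [0, 1] and ``poses`` a
    DataFrame (frame, vertebra, theta_deg, tx_px, ty_px); the same DataFrame
    is attached to ``rec.poses``.

    Raises
    ------
    FrameOutOfViewError
        If any body corner leaves the image, naming frame and vertebra.
    """
    import pandas as pd
    from skimage.draw import polygon as draw_polygon
    from skimage.filters import gaussian
    from skimage.transform import downscale_local_mean

    if phantom is None:
        phantom = PhantomSpec()
    h, w = phantom.image_size
    ss = phantom.supersample
    thetas = rec.vertebra_thetas()
    rng = np.random.default_rng(phantom.seed)

    stack = np.empty((rec.n_frames, h, w), dtype=np.float32)
    rows = []
    for f in range(rec.n_frames):
        canvas = np.full((h * ss, w * ss), phantom.background, dtype=np.float64)
        for v in VERTEBRAE:
            theta = float(thetas[v][f])
            pts = vertebra_corners(phantom, v, theta)
            if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
                    or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
                raise FrameOutOfViewError(f, v)
            rr, cc = draw_polygon(pts[:, 1] * ss, pts[:, 0] * ss, canvas.shape)
            canvas[rr, cc] = phantom.background + phantom.contrast
            rows.append({"frame": f, "vertebra": v, "theta_deg": theta,
                         "tx_px": 0.0, "ty_px": 0.0})
        img = downscale_local_mean(canvas, (ss, ss))
        if phantom.blur_sigma > 0:
            img = gaussian(img, sigma=phantom.blur_sigma, preserve_range=True)
        if phantom.noise_sd > 0:
            img = img + rng.normal(0.0, phantom.noise_sd, img.shape)
        stack[f] = np.clip(img, 0.0, 1.0)

    poses = pd.DataFrame(rows)
    rec.poses = poses
    return stack, poses
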