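"""File formats: angle/pose/curve CSV, contour JSON, image stacks.

All CSV artifacts are UTF-8, comma-separated, '.' decimal, with a mandatory
header row; angles are degrees everywhere and say so in the header
(``angle_deg``). Values are written at full precision — rounding happens only
when rendering reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cervikin.kinematics import SegmentSeries, SSCCurve, SmoothingConfig
from cervikin.segments import SEGMENTS
from cervikin.synthetic import GroundTruthRecording, MotionProfileSpec
from cervikin.tracking import ContourTemplate, PoseSet


# ---------------------------------------------------------------------------
# Angle series
# ---------------------------------------------------------------------------

def write_angles_csv(path, series: dict[str, SegmentSeries] | GroundTruthRecording) -> None:
    """Write per-frame segmental angles as (frame, segment, angle_deg)."""
    if isinstance(series, GroundTruthRecording):
        series = {
            seg: SegmentSeries(seg, series.segment_angles[seg], fps=series.fps)
            for seg in SEGMENTS
        }
    rows = [
        {"frame": f, "segment": seg, "angle_deg": float(a)}
        for seg in SEGMENTS
        for f, a in enumerate(series[seg].angles)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_angles_csv(path, fps: float = 10.0) -> dict[str, SegmentSeries]:
    df = pd.read_csv(path)
    missing = {"frame", "segment", "angle_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for seg, g in df.groupby("segment"):
        g = g.sort_values("frame")
        out[str(seg)] = SegmentSeries(str(seg), g["angle_deg"].to_numpy(), fps=fps)
    lacking = set(SEGMENTS) - set(out)
    if lacking:
        raise ValueError(f"{path}: missing segments {sorted(lacking)}")
    return out


# ---------------------------------------------------------------------------
# Poses and contours
# ---------------------------------------------------------------------------

def write_poses_csv(path, poses: PoseSet | pd.DataFrame) -> None:
    df = poses.to_frame() if isinstance(poses, PoseSet) else poses
    df.to_csv(path, index=False)


def read_poses_csv(path) -> PoseSet:
    df = pd.read_csv(path)
    missing = {"frame", "vertebra", "theta_deg", "tx_px", "ty_px"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return PoseSet.from_frame(df)


def write_contours_json(path, templates: list[ContourTemplate]) -> None:
    data = {t.label: np.asarray(t.vertices).tolist() for t in templates}
    Path(path).write_text(json.dumps(data, indent=1))


def read_contours_json(path) -> list[ContourTemplate]:
    data = json.loads(Path(path).read_text())
    return [ContourTemplate(label=k, vertices=np.asarray(v, float)) for k, v in data.items()]


# ---------------------------------------------------------------------------
# Recordings and SSC curves
# ---------------------------------------------------------------------------

def write_recording(out_dir, rec: GroundTruthRecording) -> None:
    """Write a ground-truth recording: angles CSV plus a JSON sidecar with the
    generating spec and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_angles_csv(out / "angles.csv", rec)
    meta = {"label": rec.label, "fps": rec.fps, "spec": asdict(rec.spec)}
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    if rec.poses is not None:
        write_poses_csv(out / "true_poses.csv", rec.poses)


def read_recording_spec(rec_dir) -> MotionProfileSpec:
    meta = json.loads((Path(rec_dir) / "meta.json").read_text())
    spec = meta["spec"]
    for key in ("segment_total_rotation", "peak_centers", "peak_widths"):
        spec[key] = tuple(spec[key])
    return MotionProfileSpec(**spec)


def write_curve_csv(path, curve: SSCCurve) -> None:
    cols = {"cumulative_rotation_deg": curve.x}
    for seg in SEGMENTS:
        cols[f"contribution_deg_per_frame[{seg}]"] = curve.y[seg]
        cols[f"rate_deg_per_deg[{seg}]"] = curve.y_rate[seg]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_curve_csv(path, frame_step: float | None = None) -> SSCCurve:
    df = pd.read_csv(path)
    x = df["cumulative_rotation_deg"].to_numpy()
    y = {seg: df[f"contribution_deg_per_frame[{seg}]"].to_numpy() for seg in SEGMENTS}
    y_rate = {seg: df[f"rate_deg_per_deg[{seg}]"].to_numpy() for seg in SEGMENTS}
    step = float(x[1] - x[0]) if len(x) > 1 else 0.1
    if frame_step is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = [y[s] / y_rate[s] for s in SEGMENTS]
        vals = np.concatenate(ratios)
        vals = vals[np.isfinite(vals)]
        frame_step = float(np.median(vals)) if len(vals) else step
    net = {seg: float(np.sum(y_rate[seg]) * step) for seg in SEGMENTS}
    return SSCCurve(x=x, y=y, y_rate=y_rate, grid_step=step, frame_step=frame_step,
                    net=net, block_net=float(x[-1] + step / 2 - (x[0] - step / 2)),
                    insufficient_motion=False, config=SmoothingConfig(grid_step=step))


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def write_image_stack(path, stack: np.ndarray) -> None:
    """Write frames as a multi-page TIFF (float32 in [0, 1] saved as 16-bit)."""
    import tifffile

    arr = np.clip(np.asarray(stack), 0.0, 1.0)
    tifffile.imwrite(path, np.rint(arr * 65535).astype(np.uint16),
                     photometric="minisblack")


def read_image_stack(path) -> np.ndarray:
    """Read an image stack: multi-page TIFF, a directory of PNG/TIFF frames
    (sorted by name), or DICOM file(s)."""
    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff", ".dcm")
        )
        if not files:
            raise ValueError(f"{path}: no image frames found")
        return np.stack([_read_single(f) for f in files])
    frames = _read_single(p)
    if frames.ndim == 2:
        frames = frames[None]
    return frames


def _read_single(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".dcm":
        import pydicom

        raw = pydicom.dcmread(path).pixel_array
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    arr = np.asarray(raw).astype(float)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        arr = arr / np.iinfo(np.asarray(raw).dtype).max
    elif arr.max() > 1.0:
        arr = arr / arr.max()
    return arr
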