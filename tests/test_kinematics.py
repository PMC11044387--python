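"""Segment angles, cumulative block, SSC construction, ROM summaries."""

import numpy as np
import pytest

from cervikin import SEGMENTS
from cervikin.kinematics import (
    SegmentSeries,
    SmoothingConfig,
    build_ssc,
    cumulative_block,
    rom_summary,
    segmental_angles,
)
from cervikin.synthetic import MotionProfileSpec, generate_profile, young_profile
from cervikin.tracking import Pose, PoseSet
from cervikin import datasets
from conftest import series_from


def _poses_from_thetas(thetas: dict) -> PoseSet:
    n = len(next(iter(thetas.values())))
    return PoseSet(
        poses={v: [Pose(f, v, float(th[f]), 0.0, 0.0) for f in range(n)]
               for v, th in thetas.items()},
        n_frames=n,
    )


class TestSegmentalAngles:
    def test_equal_thetas_give_zero_segment(self):
        th = np.array([0.0, 1.0, 2.0, 3.0])
        poses = _poses_from_thetas({"C4": th, "C5": th, "C6": th * 0, "C7": th * 0})
        series = segmental_angles(poses)
        assert np.allclose(series["C4-C5"].angles, 0.0)

    def test_relative_angle_arithmetic(self):
        poses = _poses_from_thetas({
            "C4": np.array([0.0, 2.0]), "C5": np.array([0.0, 0.5]),
            "C6": np.array([0.0, 0.0]), "C7": np.array([0.0, 0.0]),
        })
        series = segmental_angles(poses)
        assert series["C4-C5"].angles[1] == pytest.approx(1.5)

    def test_missing_vertebra_named(self):
        poses = _poses_from_thetas({"C4": np.zeros(3), "C5": np.zeros(3), "C6": np.zeros(3)})
        with pytest.raises(ValueError, match="C7"):
            segmental_angles(poses)

    def test_phantom_angles_match_ground_truth(self, phantom_run):
        series = segmental_angles(phantom_run["poses"])
        rec = phantom_run["rec"]
        for seg in SEGMENTS:
            err = np.abs(series[seg].angles - rec.segment_angles[seg])
            assert err.mean() <= 0.2


class TestCumulativeBlock:
    def test_sums_segments(self):
        series = {s: SegmentSeries(s, np.array([0.0, v])) for s, v in
                  zip(SEGMENTS, (1.0, 2.0, 3.0))}
        assert cumulative_block(series)[1] == pytest.approx(6.0)

    def test_zero_series(self):
        series = {s: SegmentSeries(s, np.zeros(5)) for s in SEGMENTS}
        assert np.allclose(cumulative_block(series), 0.0)

    def test_equals_c4_minus_c7(self, phantom_run):
        poses = phantom_run["poses"]
        series = segmental_angles(poses)
        block = cumulative_block(series)
        direct = poses.theta("C4") - poses.theta("C7")
        assert np.allclose(block, direct - direct[0], atol=1e-9)

    def test_length_mismatch_rejected(self):
        series = {s: SegmentSeries(s, np.zeros(5)) for s in SEGMENTS}
        series["C5-C6"] = SegmentSeries("C5-C6", np.zeros(4))
        with pytest.raises(ValueError):
            cumulative_block(series)


class TestSSC:
    def test_conservation_noiseless(self, young_rec, young_curve):
        for seg, total in zip(SEGMENTS, young_rec.spec.segment_total_rotation):
            assert young_curve.integral(seg) == pytest.approx(total, abs=1e-6)

    def test_conservation_with_default_noise(self):
        rec = generate_profile(young_profile(seed=3, noise_sd=0.05))
        curve = build_ssc(series_from(rec))
        for seg in SEGMENTS:
            net = rec.segment_angles[seg][-1] - rec.segment_angles[seg][0]
            assert curve.integral(seg) == pytest.approx(net, abs=0.1)

    def test_constant_rate_profile_gives_flat_curves(self):
        spec = MotionProfileSpec(
            segment_total_rotation=(10.0, 8.0, 7.0),
            peak_centers=(8.0, 14.0, 20.0),
            peak_widths=(2.0, 2.0, 2.0),
            trom=25.0,
            peak_mass_fraction=0.0,  # baseline only, flat
        )
        curve = build_ssc(series_from(generate_profile(spec)))
        for seg, total in zip(SEGMENTS, spec.segment_total_rotation):
            interior = curve.y_rate[seg][2:-2]
            assert interior == pytest.approx(np.full_like(interior, total / spec.trom), abs=1e-3)

    def test_insufficient_motion_flag(self):
        spec = MotionProfileSpec(
            segment_total_rotation=(1.0, 0.9, 0.6),
            peak_centers=(1.2, 1.8, 2.3),
            peak_widths=(0.3, 0.3, 0.3),
            trom=2.5,
        )
        curve = build_ssc(series_from(generate_profile(spec)))
        assert curve.insufficient_motion
        assert len(curve.x) == 0

    def test_strictly_increasing_grid_despite_negative_excursions(self):
        rng = np.random.default_rng(5)
        angles = {s: np.cumsum(rng.normal(0.15, 0.3, 60)) for s in SEGMENTS}
        series = {s: SegmentSeries(s, a - a[0]) for s, a in angles.items()}
        curve = build_ssc(series)
        if not curve.insufficient_motion:
            assert np.all(np.diff(curve.x) > 0)
            for seg in SEGMENTS:
                sm = curve.config
                assert curve.integral(seg) == pytest.approx(
                    series[seg].angles[-1] - series[seg].angles[0], abs=1e-9)


class TestRomSummary:
    def test_monotone_path_both_methods_agree(self):
        a = np.linspace(0, 10, 20)
        series = {s: SegmentSeries(s, a) for s in SEGMENTS}
        for method in ("endpoint", "extremal"):
            rs = rom_summary(series, method=method)
            assert rs.srom["C4-C5"] == pytest.approx(10.0)

    def test_overshoot_path(self):
        a = np.array([0.0, 6.0, 12.0, 10.0, 8.0])
        series = {s: SegmentSeries(s, a) for s in SEGMENTS}
        assert rom_summary(series, method="extremal").srom["C4-C5"] == pytest.approx(12.0)
        assert rom_summary(series, method="endpoint").srom["C4-C5"] == pytest.approx(8.0)

    def test_extremal_never_below_endpoint(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            series = {s: SegmentSeries(s, np.cumsum(rng.normal(0.1, 0.5, 30)))
                      for s in SEGMENTS}
            for s in SEGMENTS:
                series[s] = SegmentSeries(s, series[s].angles - series[s].angles[0])
            ext = rom_summary(series, method="extremal")
            end = rom_summary(series, method="endpoint")
            for s in SEGMENTS:
                assert ext.srom[s] >= end.srom[s] - 1e-12
            assert ext.trom >= end.trom - 1e-12


def test_rom_table_rows_internally_consistent():
    """Printed sROM triplets sum to the printed tROM within 0.3 deg, for all
    10 individuals at both timepoints."""
    df = datasets.load_rom()
    assert len(df) == 20
    total = df["srom_c4c5"] + df["srom_c5c6"] + df["srom_c6c7"]
    assert np.all(np.abs(total - df["trom"]) <= 0.3 + 1e-9)
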