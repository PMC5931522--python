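"""Tests for the cardiac kinematics layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import cardiodic as cd
from cardiodic import metrics as met
from cardiodic.dic import DisplacementField, SubsetGrid
from cardiodic.metrics import (
    ExtensometerDef,
    InvalidDimensionError,
    InvalidWindowError,
    ROIDef,
    SegmentationError,
    StitchingGapError,
    Trace,
)


def make_field(u, grid, dt=0.1, mm_per_px=0.1, valid=None):
    nf, n = u.shape[:2]
    return DisplacementField(
        grid=grid, u=u,
        valid=np.ones((nf, n), bool) if valid is None else valid,
        zncc=np.ones((nf, n)), timestamps=np.arange(nf) * dt,
        units="px", mm_per_px=mm_per_px,
    )


@pytest.fixture(scope="module")
def lattice():
    return SubsetGrid.from_roi((20, 20, 200, 200), (256, 256),
                               subset_size=31, step=20)


class TestRoiTraces:
    def test_zero_field(self, lattice):
        u = np.zeros((3, lattice.n_points, 2))
        tr = met.roi_traces(make_field(u, lattice), ROIDef(20, 20, 200, 200))
        assert np.all(tr["V_l"].values == 0.0)
        assert np.all(tr["V_l"].dispersion == 0.0)

    def test_three_four_five(self, lattice):
        """Uniform u = (3, 4) mm -> V_x = 3, V_y = 4, V_l = 5, std = 0."""
        u = np.zeros((2, lattice.n_points, 2))
        u[1] = [30.0, 40.0]  # px at 0.1 mm/px -> (3, 4) mm
        tr = met.roi_traces(make_field(u, lattice), ROIDef(20, 20, 200, 200))
        assert tr["V_x"].values[1] == pytest.approx(3.0)
        assert tr["V_y"].values[1] == pytest.approx(4.0)
        assert tr["V_l"].values[1] == pytest.approx(5.0)
        assert tr["V_l"].dispersion[1] == pytest.approx(0.0)

    def test_vl_is_mean_of_lengths_not_length_of_mean(self, lattice):
        n = lattice.n_points
        u = np.zeros((2, n, 2))
        u[1, : n // 2, 0] = 10.0   # half the points move +x
        u[1, n // 2:, 0] = -10.0   # half move -x; mean vector ~ 0
        tr = met.roi_traces(make_field(u, lattice), ROIDef(20, 20, 200, 200))
        assert tr["V_l"].values[1] == pytest.approx(1.0, abs=1e-9)
        assert abs(tr["V_x"].values[1]) < 0.1

    def test_sparse_frame_marked_missing(self, lattice):
        n = lattice.n_points
        u = np.zeros((2, n, 2))
        valid = np.ones((2, n), bool)
        valid[1, : int(0.9 * n)] = False    # only 10% valid at frame 1
        tr = met.roi_traces(make_field(u, lattice, valid=valid),
                            ROIDef(20, 20, 200, 200))
        assert np.isnan(tr["V_l"].values[1])


class TestSegmentBeats:
    def test_sinusoid_interior_beats(self):
        """1 s period sampled at 20 Hz over 10 s: nine complete interior
        beats between the ten detected minima."""
        t = np.arange(0.0, 10.0, 0.05)
        vl = 0.5 * (1.0 - np.cos(2 * np.pi * (t - 0.5)))
        beats = met.segment_beats(Trace(vl, t), min_beat_s=0.5)
        assert beats.n_beats == 9
        for (s, e) in beats.intervals:
            assert e - s == pytest.approx(20, abs=1)

    def test_constant_trace_fails(self):
        t = np.arange(0.0, 5.0, 0.05)
        with pytest.raises(SegmentationError):
            met.segment_beats(Trace(np.ones_like(t), t))

    def test_synthetic_beats_at_ground_truth_boundaries(self, beat_sequence_2d):
        gt = beat_sequence_2d["gt"]
        vl = Trace(np.linalg.norm(gt.displacements, axis=2).mean(1), gt.timestamps)
        beats = met.segment_beats(vl)
        period_frames = 60.0 / 75.0 * 15.0   # 12 frames per beat
        assert beats.n_beats == 3
        for i, (s, e) in enumerate(beats.intervals):
            assert s == pytest.approx((i + 1) * period_frames, abs=1)


class TestStitchBeats:
    def test_single_beat_identity(self, lattice):
        u = np.cumsum(np.ones((4, lattice.n_points, 2)) * 0.1, axis=0)
        f = make_field(u, lattice)
        out = met.stitch_beats([f])
        assert out is f

    def test_beats_ending_at_zero_concatenate(self, lattice):
        n = lattice.n_points
        u = np.zeros((4, n, 2))
        u[1] = 1.0
        u[2] = 0.5
        u[3] = 0.0           # beat returns to zero displacement
        f1 = make_field(u, lattice)
        f2 = make_field(u, lattice)
        f2.timestamps = f2.timestamps + f1.timestamps[-1]   # shared boundary
        out = met.stitch_beats([f1, f2])
        assert out.n_frames == 7
        assert np.allclose(out.u[4], u[1])   # zero offset carried over

    def test_noncontiguous_rejected(self, lattice):
        u = np.zeros((3, lattice.n_points, 2))
        f1 = make_field(u, lattice)
        f2 = make_field(u, lattice)
        f2.timestamps = f2.timestamps + 10.0
        with pytest.raises(StitchingGapError):
            met.stitch_beats([f1, f2])

    def test_stitched_matches_direct_accumulation(self, beat_sequence_2d,
                                                  tracked_beat_2d):
        """Per-beat tracking + stitching agrees with whole-sequence tracking
        within 0.1 px at every frame."""
        gt = beat_sequence_2d["gt"]
        vl = Trace(np.linalg.norm(gt.displacements, axis=2).mean(1), gt.timestamps)
        beats = met.segment_beats(vl)
        seq = beat_sequence_2d["seq"]
        grid = beat_sequence_2d["grid"]
        pieces = []
        for (s, e) in beats.intervals:
            sub = cd.accumulate_sequence(
                cd.ImageSequence(frames=seq.frames[s:e + 1],
                                 frame_rate=seq.frame_rate,
                                 timestamps=seq.timestamps[s:e + 1]),
                grid, mm_per_px=0.1)
            pieces.append(sub)
        stitched = met.stitch_beats(pieces)
        s0 = beats.intervals[0][0]
        e0 = beats.intervals[-1][1]
        direct = tracked_beat_2d.u[s0:e0 + 1] - tracked_beat_2d.u[s0]
        assert np.abs(stitched.u - direct).max() < 0.1


class TestTissueVelocity:
    def test_constant_trace_zero_velocity(self):
        t = np.arange(0.0, 2.0, 0.05)
        tv = met.tissue_velocity(Trace(np.full_like(t, 7.0), t))
        assert np.allclose(tv.values, 0.0, atol=1e-9)

    def test_linear_growth_rate(self):
        """V_l growing 1 mm per frame at 20 Hz is 20 mm/s = 2 cm/s."""
        t = np.arange(40) * 0.05
        tv = met.tissue_velocity(Trace(np.arange(40, dtype=float), t))
        assert np.allclose(tv.values, 2.0, atol=1e-9)
        assert tv.units == "cm/s"

    def test_window_validation(self):
        t = np.arange(10) * 0.05
        tr = Trace(np.arange(10, dtype=float), t)
        with pytest.raises(InvalidWindowError):
            met.tissue_velocity(tr, smoothing_window=4)
        with pytest.raises(InvalidWindowError):
            met.tissue_velocity(tr, smoothing_window=11)


def _model_vl_trace(motion, n_frames=52, rate=15.0):
    model = cd.MotionModel(motion, center=(12.8, 12.8))
    pts = np.column_stack([np.linspace(6.4, 19.2, 9), np.linspace(6.4, 19.2, 9)])
    t = np.arange(n_frames) / rate
    disp = np.stack([model.displacement(pts, tk) for tk in t])
    return Trace(np.linalg.norm(disp, axis=2).mean(1), t, label="V_l", units="mm")


class TestDetectTvPoints:
    def test_noisy_detection_within_one_frame(self, beat_sequence_2d):
        """Detection on a lightly perturbed trace stays within +/-1 frame of
        the analytic extrema."""
        gt = beat_sequence_2d["gt"]
        vl = Trace(np.linalg.norm(gt.displacements, axis=2).mean(1), gt.timestamps)
        beats = met.segment_beats(vl)
        tv_ref = met.tissue_velocity(vl)
        cp_ref = met.detect_tv_points(tv_ref, beats)
        rng = np.random.default_rng(5)
        noisy = Trace(vl.values + rng.normal(0, 0.01, len(vl)), vl.timestamps)
        cp = met.detect_tv_points(met.tissue_velocity(noisy), beats)
        for a, b in zip(cp.tv_s + cp.tv_e + cp.tv_a,
                        cp_ref.tv_s + cp_ref.tv_e + cp_ref.tv_a):
            assert a is not None and b is not None
            assert abs(a.frame - b.frame) <= 1

    def test_atrial_point_between_e_and_s(self, beat_sequence_2d):
        gt = beat_sequence_2d["gt"]
        vl = Trace(np.linalg.norm(gt.displacements, axis=2).mean(1), gt.timestamps)
        beats = met.segment_beats(vl)
        cp = met.detect_tv_points(met.tissue_velocity(vl), beats)
        for tve, tva in zip(cp.tv_e, cp.tv_a):
            assert tva is not None
            assert tva.frame > tve.frame          # TV_e precedes TV_a
            assert tva.value < 0                  # negative-direction extremum

    def test_full_recovery_has_no_atrial_kick(self):
        motion = cd.MotionModelParams(heart_rate=75.0, early_recovery_ratio=1.0,
                                      translation_amplitude=(1.0, 0.5, 0.0),
                                      respiration_mod_depth=0.0)
        vl = _model_vl_trace(motion)
        beats = met.segment_beats(vl)
        cp = met.detect_tv_points(met.tissue_velocity(vl), beats)
        assert all(t is None for t in cp.tv_a)
        assert all(f == "no-atrial-kick" for f in cp.flags)

    def test_sign_flip_swaps_s_and_e(self):
        motion = cd.MotionModelParams(heart_rate=75.0,
                                      translation_amplitude=(1.0, 0.5, 0.0),
                                      respiration_mod_depth=0.0)
        vl = _model_vl_trace(motion)
        beats = met.segment_beats(vl)
        tv = met.tissue_velocity(vl)
        flipped = Trace(-tv.values, tv.timestamps)
        cp = met.detect_tv_points(tv, beats)
        cpf = met.detect_tv_points(flipped, beats)
        for a, b in zip(cp.tv_s, cpf.tv_e):
            assert a.frame == b.frame
            assert a.value == pytest.approx(-b.value)


class TestLocalStrainField:
    def test_rigid_translation_zero_strain(self, lattice):
        u = np.zeros((2, lattice.n_points, 2))
        u[1] = [12.3, -4.5]
        ss = met.local_strain_field(make_field(u, lattice), 5)
        assert abs(ss.e_max_mean[1]) < 1e-9
        assert abs(ss.e_min_mean[1]) < 1e-9

    def test_homogeneous_diagonal_deformation(self, lattice):
        """u_x = 0.10 x, u_y = -0.05 y -> principal strains +10% and -5%."""
        u = np.zeros((2, lattice.n_points, 2))
        u[1, :, 0] = 0.10 * lattice.centers[:, 0]
        u[1, :, 1] = -0.05 * lattice.centers[:, 1]
        ss = met.local_strain_field(make_field(u, lattice), 5)
        assert ss.e_max_mean[1] == pytest.approx(10.0, abs=0.2)
        assert ss.e_min_mean[1] == pytest.approx(-5.0, abs=0.2)

    def test_rigid_rotation_invariance(self, lattice):
        th = np.deg2rad(10.0)
        c0 = lattice.centers - lattice.centers.mean(axis=0)
        u = np.zeros((2, lattice.n_points, 2))
        u[1, :, 0] = c0[:, 0] * np.cos(th) - c0[:, 1] * np.sin(th) - c0[:, 0]
        u[1, :, 1] = c0[:, 0] * np.sin(th) + c0[:, 1] * np.cos(th) - c0[:, 1]
        ss = met.local_strain_field(make_field(u, lattice), 5)
        assert np.nanmax(np.abs(ss.point_e_max[1])) < 0.5
        assert np.nanmax(np.abs(ss.point_e_min[1])) < 0.5

    def test_e_max_dominates_and_reference_zero(self, beat_sequence_2d,
                                                tracked_beat_2d):
        ss = met.local_strain_field(tracked_beat_2d, 5)
        ok = ss.valid
        assert np.all(ss.point_e_max[ok] >= ss.point_e_min[ok] - 1e-12)
        assert np.allclose(ss.point_e_max[0][ss.valid[0]], 0.0, atol=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(exx=hst.floats(-0.2, 0.5), eyy=hst.floats(-0.2, 0.5),
           exy=hst.floats(-0.2, 0.2))
    def test_principal_order_property(self, exx, eyy, exy):
        from cardiodic.metrics import _principal_from_tensor
        e1, e2 = _principal_from_tensor(exx, eyy, exy)
        assert e1 >= e2 - 1e-12


class TestExtensometer:
    def test_zero_field_constant_length(self, lattice):
        u = np.zeros((3, lattice.n_points, 2))
        ext = ExtensometerDef((60.0, 120.0), (180.0, 120.0))
        tr = met.extensometer_length(make_field(u, lattice), ext)
        assert np.allclose(tr.values, tr.values[0])

    def test_uniform_translation_preserves_length(self, lattice):
        u = np.zeros((2, lattice.n_points, 2))
        u[1] = [7.0, -3.0]
        ext = ExtensometerDef((60.0, 120.0), (180.0, 120.0))
        tr = met.extensometer_length(make_field(u, lattice), ext)
        assert tr.values[1] == pytest.approx(tr.values[0], abs=1e-9)

    def test_pure_scaling_scales_length(self, lattice):
        u = np.zeros((2, lattice.n_points, 2))
        u[1] = (0.8 - 1.0) * (lattice.centers - np.array([111.0, 97.0]))
        ext = ExtensometerDef((60.0, 120.0), (180.0, 120.0))
        tr = met.extensometer_length(make_field(u, lattice), ext)
        assert tr.values[1] / tr.values[0] == pytest.approx(0.8, abs=1e-9)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(InvalidDimensionError):
            ExtensometerDef((10.0, 10.0), (10.0, 10.0))


class TestFractionalShortening:
    def _beats(self, n):
        return met.BeatSegmentation(intervals=[(0, n)])

    def test_constant_at_lmax_is_zero(self):
        t = np.arange(10) * 0.1
        l = Trace(np.full(10, 25.0), t)
        fs = met.fractional_shortening(l, self._beats(10))
        assert np.allclose(fs.values, 0.0)

    def test_eq1_arithmetic(self):
        t = np.arange(3) * 0.1
        l = Trace(np.array([25.0, 20.0, 25.0]), t)
        fs = met.fractional_shortening(l, self._beats(3))
        assert fs.values[1] == pytest.approx(20.0, abs=1e-12)

    def test_bounds_and_zero_attained(self, beat_sequence_2d):
        gt = beat_sequence_2d["gt"]
        l = Trace(gt.extensometer_length, gt.timestamps)
        vl = Trace(np.linalg.norm(gt.displacements, axis=2).mean(1), gt.timestamps)
        beats = met.segment_beats(vl)
        fs = met.fractional_shortening(l, beats)
        inside = ~np.isnan(fs.values)
        assert np.all(fs.values[inside] >= 0.0)
        assert np.all(fs.values[inside] < 100.0)
        for s, e in beats.intervals:
            assert np.nanmin(fs.values[s:e]) == pytest.approx(0.0, abs=1e-12)


class TestFsConventional:
    def test_equal_dimensions(self):
        assert met.fs_conventional(50.0, 50.0) == 0.0

    def test_total_collapse(self):
        assert met.fs_conventional(50.0, 0.0) == 100.0

    def test_m_mode_normal_lower_limit(self):
        assert met.fs_conventional(50.0, 37.5) == pytest.approx(25.0, abs=1e-12)

    def test_invalid_dimensions(self):
        with pytest.raises(InvalidDimensionError):
            met.fs_conventional(0.0, 0.0)
        with pytest.raises(InvalidDimensionError):
            met.fs_conventional(50.0, 60.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(lvedd=hst.floats(1.0, 100.0), frac=hst.floats(0.0, 1.0))
    def test_bounds_property(self, lvedd, frac):
        fs = met.fs_conventional(lvedd, frac * lvedd)
        assert 0.0 <= fs <= 100.0


class TestStrainAndRate:
    def _beats(self, n):
        return met.BeatSegmentation(intervals=[(0, n)])

    def test_constant_length_all_zero(self):
        t = np.arange(20) * 0.05
        l = Trace(np.full(20, 30.0), t)
        strain, rate, cp = met.strain_and_rate(l, self._beats(20))
        assert np.allclose(strain.values, 0.0)
        assert np.allclose(rate.values, 0.0, atol=1e-12)
        assert cp.s_s[0] == pytest.approx(0.0)

    def test_linear_shortening_rate(self):
        """L = L0 (1 - 0.2 t): strain rate ~ -0.2 1/s."""
        t = np.arange(21) * 0.05
        l = Trace(30.0 * (1.0 - 0.2 * t), t)
        _, rate, _ = met.strain_and_rate(l, self._beats(21))
        assert np.allclose(rate.values[3:-3], -0.2, atol=1e-3)

    def test_sr_points_ordering(self, beat_sequence_2d):
        gt = beat_sequence_2d["gt"]
        l = Trace(gt.extensometer_length, gt.timestamps)
        vl = Trace(np.linalg.norm(gt.displacements, axis=2).mean(1), gt.timestamps)
        beats = met.segment_beats(vl)
        _, _, cp = met.strain_and_rate(l, beats)
        for b in range(beats.n_beats):
            assert cp.sr_s[b].value < 0
            assert cp.sr_e[b] is not None and cp.sr_e[b].value > 0
            assert cp.sr_a[b] is not None
            assert cp.sr_e[b].frame < cp.sr_a[b].frame
            assert cp.sr_e[b].value > cp.sr_a[b].value   # E-peak dominates


class TestDirectionalStrains:
    def test_isotropic_scaling_both_directions(self, lattice):
        u = np.zeros((2, lattice.n_points, 2))
        u[1] = (0.9 - 1.0) * (lattice.centers - np.array([120.0, 120.0]))
        f = make_field(u, lattice)
        ext = ExtensometerDef((70.0, 120.0), (170.0, 120.0))
        lon, hor = met.directional_strains(f, ext)
        assert lon.values[1] == pytest.approx(-10.0, abs=1e-6)
        assert hor.values[1] == pytest.approx(-10.0, abs=1e-6)

    def test_uniaxial_stretch_no_horizontal(self, lattice):
        u = np.zeros((2, lattice.n_points, 2))
        u[1, :, 0] = 0.05 * (lattice.centers[:, 0] - 120.0)
        f = make_field(u, lattice)
        ext = ExtensometerDef((70.0, 120.0), (170.0, 120.0))
        lon, hor = met.directional_strains(f, ext)
        assert lon.values[1] == pytest.approx(5.0, abs=1e-6)
        assert hor.values[1] == pytest.approx(0.0, abs=1e-6)

    def test_rigid_rotation_small_strains(self, lattice):
        th = np.deg2rad(5.0)
        c0 = lattice.centers - np.array([120.0, 120.0])
        u = np.zeros((2, lattice.n_points, 2))
        u[1, :, 0] = c0[:, 0] * np.cos(th) - c0[:, 1] * np.sin(th) - c0[:, 0]
        u[1, :, 1] = c0[:, 0] * np.sin(th) + c0[:, 1] * np.cos(th) - c0[:, 1]
        f = make_field(u, lattice)
        ext = ExtensometerDef((80.0, 120.0), (160.0, 120.0))
        lon, hor = met.directional_strains(f, ext)
        assert abs(lon.values[1]) < 0.5
        assert abs(hor.values[1]) < 0.5
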