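"""Tests for Ewald-construction computations and centroid prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import edgeom as e
from edgeom.geometry import InvalidArgumentError, NoSolutionError, rotation_about_axis
from edgeom.prediction import (
    Flags,
    ReflectionTable,
    calibrate_crossing,
    ewald_crossing_angles,
    ewald_residual,
    map_to_reciprocal_space,
    predict_centroids,
    two_theta,
)
from edgeom.simulator import enumerate_hkl


def _models(lam, cell=(10, 10, 10, 90, 90, 90), U=None):
    beam = e.BeamModel([0, 0, 1.0], lam)
    gonio = e.GoniometerModel([1.0, 0, 0])
    U = rotation_about_axis([0, 0, 1.0], 90.0) if U is None else U  # a* -> +y, off the axis
    crystal = e.CrystalModel.from_cell(cell, U=U, lattice_constraint="cubic")
    return crystal, beam, gonio


class TestTwoTheta:
    def test_xray_1A_limit(self):
        assert two_theta(1.0, 1.0332) == pytest.approx(62.2, abs=0.05)

    def test_electron_1A_limit(self):
        assert two_theta(1.0, 0.02508) == pytest.approx(1.44, abs=0.005)

    def test_limits(self):
        assert two_theta(1.0, 1e-9) == pytest.approx(0.0, abs=1e-6)
        assert two_theta(1.0, 2.0) == pytest.approx(180.0)

    def test_beyond_limiting_sphere(self):
        with pytest.raises(NoSolutionError):
            two_theta(1.0, 2.0001)

    @settings(derandomize=True, max_examples=100)
    @given(d=st.floats(0.5, 50), lam=st.floats(0.01, 0.9))
    def test_monotone_in_resolution_and_wavelength(self, d, lam):
        assert two_theta(d, lam) < two_theta(d * 0.9, lam)
        assert two_theta(d, lam) < two_theta(d, lam * 1.1)


class TestCrossingAngles:
    def test_blind_region_gives_no_crossing(self):
        crystal, beam, gonio = _models(1.0332, U=np.eye(3))  # a* along the axis
        assert ewald_crossing_angles(crystal, beam, gonio, (1, 0, 0)) == []

    def test_zero_hkl_rejected(self):
        crystal, beam, gonio = _models(1.0332)
        with pytest.raises(InvalidArgumentError):
            ewald_crossing_angles(crystal, beam, gonio, (0, 0, 0))

    @pytest.mark.parametrize("hkl", [(1, 0, 0), (3, 2, 0), (0, 1, 4), (-2, 3, 1)])
    def test_brute_force_bracketing_oracle(self, hkl):
        """Each closed-form crossing is bracketed by a sign change of the
        Ewald residual scanned in 0.001 degree steps."""
        crystal, beam, gonio = _models(1.0332)
        sols = ewald_crossing_angles(crystal, beam, gonio, hkl)
        r0 = crystal.U @ crystal.B @ np.asarray(hkl, float)
        phi = np.arange(0.0, 360.0, 0.001)
        from edgeom.prediction import _rotate_about

        f = np.linalg.norm(_rotate_about(gonio.rotation_axis, phi, np.tile(r0, (len(phi), 1))) + beam.s0, axis=1) - 1.0 / beam.wavelength
        sign_changes = phi[np.where(np.diff(np.sign(f)) != 0)[0]]
        assert len(sols) == len(sign_changes)
        for s in sols:
            assert np.min(np.abs(((sign_changes - s) + 180) % 360 - 180)) < 0.002

    @pytest.mark.parametrize(
        "lam,phi1,phi5",
        [(1.0332, 15.0, 27.0), (0.02508, 12.1, 12.4)],
        ids=["xray", "electron"],
    )
    def test_collinear_row_crossing_angles(self, lam, phi1, phi5):
        """With the (1,0,0) crossing calibrated, the (5,0,0) crossing lands at
        the printed angle for both geometries."""
        crystal, beam, gonio = _models(lam)
        crystal = calibrate_crossing(crystal, beam, gonio, (1, 0, 0), phi1)
        sols = ewald_crossing_angles(crystal, beam, gonio, (5, 0, 0), entering_only=True)
        assert sols, "entering crossing must exist"
        assert sols[0] == pytest.approx(phi5, abs=0.05)

    def test_differences_invariant_under_axial_pre_rotation(self):
        crystal, beam, gonio = _models(1.0332)
        crystal = calibrate_crossing(crystal, beam, gonio, (1, 0, 0), 15.0)
        base1 = ewald_crossing_angles(crystal, beam, gonio, (1, 0, 0), entering_only=True)[0]
        base5 = ewald_crossing_angles(crystal, beam, gonio, (5, 0, 0), entering_only=True)[0]
        rng = np.random.default_rng(0)
        for delta in rng.uniform(0, 360, 10):
            U2 = rotation_about_axis(gonio.rotation_axis, delta) @ crystal.U
            cr2 = e.CrystalModel(U=U2, g_star=crystal.g_star, lattice_constraint=crystal.lattice_constraint)
            p1 = ewald_crossing_angles(cr2, beam, gonio, (1, 0, 0), entering_only=True)[0]
            p5 = ewald_crossing_angles(cr2, beam, gonio, (5, 0, 0), entering_only=True)[0]
            d0 = (base5 - base1) % 360
            d1 = (p5 - p1) % 360
            assert d1 == pytest.approx(d0, abs=1e-8)


class TestPredictCentroids:
    def test_all_predictions_satisfy_ewald_condition(self, ed_sim):
        spec, exp, obs = ed_sim
        table = predict_centroids(exp, enumerate_hkl(exp.crystal, spec.d_min))
        assert len(table) > 500
        assert np.max(ewald_residual(exp, table)) < 1e-8

    def test_direct_beam_hits_calibrated_beam_centre(self, ed_sim):
        _, exp, _ = ed_sim
        from edgeom.prediction import _intersect_panel

        panel = exp.detector[0]
        mm_f, mm_s, ok = _intersect_panel(panel, exp.beam.s0[None, :])
        assert ok[0]
        X, Y = mm_f[0] / panel.pixel_size[0], mm_s[0] / panel.pixel_size[1]
        # the preset puts the beam centre at the panel centre
        assert X == pytest.approx(panel.n_pixels[0] / 2, abs=1e-9)
        assert Y == pytest.approx(panel.n_pixels[1] / 2, abs=1e-9)

    def test_doubling_distance_doubles_offsets_in_small_angle_limit(self, small_ed_sim):
        spec, exp, _ = small_ed_sim
        hkl = enumerate_hkl(exp.crystal, spec.d_min)
        t1 = predict_centroids(exp, hkl)
        p = exp.detector[0]
        far = e.PanelModel(
            origin=p.origin + p.normal * float(p.origin @ p.normal),
            fast_axis=p.fast_axis,
            slow_axis=p.slow_axis,
            pixel_size=p.pixel_size,
            n_pixels=(2 * p.n_pixels[0], 2 * p.n_pixels[1]),
        )
        # recentre the larger panel so the beam centre stays in the middle
        far = e.PanelModel(
            origin=far.origin - 0.5 * p.n_pixels[0] * p.pixel_size[0] * p.fast_axis
            - 0.5 * p.n_pixels[1] * p.pixel_size[1] * p.slow_axis,
            fast_axis=far.fast_axis,
            slow_axis=far.slow_axis,
            pixel_size=far.pixel_size,
            n_pixels=far.n_pixels,
        )
        exp2 = e.ExperimentModel(
            beam=exp.beam,
            detector=e.DetectorModel([far]),
            goniometer=exp.goniometer,
            scan=exp.scan,
            crystal=exp.crystal,
        )
        t2 = predict_centroids(exp2, hkl)
        m = t1.df.merge(t2.df, on=["h", "k", "l", "phi_c"], suffixes=("_1", "_2"))
        assert len(m) > 50
        c1 = np.array([512.0, 512.0])
        c2 = np.array([1024.0, 1024.0])
        r1 = np.hypot(m.X_c_1 - c1[0], m.Y_c_1 - c1[1])
        r2 = np.hypot(m.X_c_2 - c2[0], m.Y_c_2 - c2[1])
        ratio = (r2 / r1)[r1 > 10]
        assert np.all(np.abs(ratio / 2.0 - 1.0) < 0.002)


def _collinear_observations(lam, dist, seed, sigma_px=0.3, sigma_phi=0.02):
    crystal, beam, gonio = _models(lam)
    crystal = calibrate_crossing(crystal, beam, gonio, (1, 0, 0), 15.0)
    panel = e.PanelModel(
        origin=[-20.0, -20.0, dist], fast_axis=[1, 0, 0], slow_axis=[0, 1, 0], pixel_size=(0.1, 0.1), n_pixels=(400, 400)
    )
    exp = e.ExperimentModel(
        beam=beam,
        detector=e.DetectorModel([panel]),
        goniometer=gonio,
        scan=e.ScanModel((1, 40), (0.0, 1.0)),
        crystal=crystal,
    )
    tab = predict_centroids(exp, np.array([[h, 0, 0] for h in range(1, 6)]))
    df = tab.df.sort_values(["h", "phi_c"]).groupby("h").first().reset_index()
    tab = ReflectionTable(df)
    rng = np.random.default_rng(seed)
    n = len(tab)
    tab.df["X_o"] = tab.df["X_c"] + rng.normal(0, sigma_px, n)
    tab.df["Y_o"] = tab.df["Y_c"] + rng.normal(0, sigma_px, n)
    tab.df["phi_o"] = tab.df["phi_c"] + rng.normal(0, sigma_phi, n)
    return exp, tab


def _rms_from_line(points):
    d = points - points.mean(axis=0)
    direction = np.linalg.svd(d, full_matrices=False)[2][0]
    perp = d - np.outer(d @ direction, direction)
    return float(np.sqrt((perp**2).sum(axis=1).mean()))


class TestMapToReciprocalSpace:
    def test_zero_phi_observations_unrotated(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        sub = obs.copy()
        sub.df["phi_o"] = 0.0
        pts = map_to_reciprocal_space(sub, exp)
        # recompute without the rotation step: identical
        from edgeom import image_prep

        panel = exp.detector[0]
        mm_f, mm_s = image_prep.px_to_mm(panel, sub.df["X_o"].to_numpy(), sub.df["Y_o"].to_numpy())
        lab = panel.lab_coord_mm(mm_f, mm_s)
        s1 = lab / np.linalg.norm(lab, axis=1, keepdims=True) / exp.beam.wavelength
        assert np.allclose(pts, s1 - exp.beam.s0, atol=1e-14)

    def test_inverted_axis_curves_xray_lattice(self):
        exp, tab = _collinear_observations(1.0332, 30.0, seed=3)
        fwd = _rms_from_line(map_to_reciprocal_space(tab, exp, invert_axis=False))
        inv = _rms_from_line(map_to_reciprocal_space(tab, exp, invert_axis=True))
        assert inv > 10 * fwd

    def test_inverted_axis_harmless_for_electron_lattice(self):
        exp, tab = _collinear_observations(0.02508, 1000.0, seed=3)
        fwd = _rms_from_line(map_to_reciprocal_space(tab, exp, invert_axis=False))
        inv = _rms_from_line(map_to_reciprocal_space(tab, exp, invert_axis=True))
        assert inv < 2 * fwd


class TestAssignIndices:
    def test_reassignment_recovers_known_indices(self, small_ed_sim):
        from edgeom.prediction import assign_indices

        _, exp, obs = small_ed_sim
        stripped = obs.copy()
        truth = stripped.df[["h", "k", "l"]].to_numpy().copy()
        stripped.df[["h", "k", "l"]] = 0
        stripped.unset_flag(Flags.INDEXED)
        out = assign_indices(stripped, exp)
        idx = out.has_flag(Flags.INDEXED)
        assert idx.mean() > 0.99
        assert np.array_equal(out.df.loc[idx, ["h", "k", "l"]].to_numpy(), truth[idx])

    def test_wrong_cell_indexes_nothing(self, small_ed_sim):
        from edgeom.prediction import assign_indices

        _, exp, obs = small_ed_sim
        bad = e.ExperimentModel(
            beam=exp.beam,
            detector=exp.detector,
            goniometer=exp.goniometer,
            scan=exp.scan,
            crystal=e.CrystalModel.from_cell((11.7, 23.9, 41.3, 90, 90, 90), U=exp.crystal.U),
        )
        out = assign_indices(obs, bad, tolerance=0.05)
        assert out.has_flag(Flags.INDEXED).mean() < 0.5


class TestReflectionTable:
    def test_negative_variances_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ReflectionTable(pd.DataFrame({"h": [1], "k": [0], "l": [0], "var_X": [-1.0]}))

    def test_flag_round_trip(self):
        from edgeom.prediction import Flags

        t = ReflectionTable(pd.DataFrame({"h": [1, 2], "k": [0, 0], "l": [0, 0]}))
        t.set_flag(Flags.OBSERVED, [True, False])
        assert list(t.has_flag(Flags.OBSERVED)) == [True, False]
        t.unset_flag(Flags.OBSERVED)
        assert not t.has_flag(Flags.OBSERVED).any()
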