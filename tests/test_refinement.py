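"""Tests for the least-squares refinement engine: parameterisation,
Jacobians, restraints, the LM optimizer, the Gaussian smoother and the full
protocol driver."""

import numpy as np
import pytest

import edgeom as e
from edgeom.geometry import InvalidArgumentError, UnsupportedError, metrical_from_cell
from edgeom.prediction import Flags
from edgeom.refinement import (
    GSTAR_PARAM_SCALE,
    GaussianSmoother,
    Parameterisation,
    RefinementProtocol,
    RestraintSpec,
    add_restraints,
    build_parameterisation,
    levenberg_marquardt,
    refine,
    reject_outliers,
    residuals_and_jacobian,
    smoother_value,
)
from edgeom.simulator import ed_preset, simulate_reflections


class TestParameterisation:
    def test_default_static_count_is_13(self, ed_sim):
        _, exp, _ = ed_sim
        assert build_parameterisation(exp).n_free == 13

    def test_fixing_detector_distance_and_tilts(self, ed_sim):
        _, exp, _ = ed_sim
        assert build_parameterisation(exp, fix=("dist", "tau2", "tau3")).n_free == 10

    def test_scan_varying_beam_adds_one_sample_per_angle(self, ed_sim):
        _, exp, _ = ed_sim
        base = build_parameterisation(exp, free=("mu1",)).n_free  # both beam angles static
        sv = build_parameterisation(exp, scan_varying={"mu1": 2, "mu2": 2}).n_free
        assert base == 14
        assert sv == base + 2  # each angle: 2 samples replacing 1 static value

    def test_unknown_label_lists_valid_labels(self, ed_sim):
        _, exp, _ = ed_sim
        with pytest.raises(InvalidArgumentError, match="phi1"):
            build_parameterisation(exp, fix=("bogus",))

    def test_build_experiment_at_start_reproduces_models(self, ed_sim):
        _, exp, _ = ed_sim
        param = build_parameterisation(exp)
        exp2 = param.build_experiment(param.start_values())
        assert np.allclose(exp2.crystal.U, exp.crystal.U, atol=1e-12)
        assert np.allclose(exp2.crystal.g_star, exp.crystal.g_star, rtol=1e-12)
        assert np.allclose(exp2.beam.direction, exp.beam.direction, atol=1e-12)
        assert np.allclose(exp2.detector[0].origin, exp.detector[0].origin, atol=1e-12)


class TestResidualsAndJacobian:
    def test_zero_residuals_at_simulation_truth(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        param = build_parameterisation(exp)
        bundle = residuals_and_jacobian(param, obs)
        assert np.max(np.abs(bundle.delta_r)) < 1e-8

    def test_block_structure(self, ed_bundle):
        param, bundle = ed_bundle
        n = len(bundle.delta_r) // 3
        sx, sy, sphi = bundle.block_bounds
        assert (sx, sy, sphi) == (slice(0, n), slice(n, 2 * n), slice(2 * n, 3 * n))
        assert bundle.J.shape == (3 * n, 13)

    def test_jacobian_matches_five_point_stencil(self, small_ed_sim):
        """Independent 5-point finite-difference oracle with its own step."""
        _, exp, obs = small_ed_sim
        sub = obs.select(np.arange(len(obs)) % 5 == 0)
        param = build_parameterisation(exp)
        v = param.start_values()
        bundle = residuals_and_jacobian(param, sub, v)

        from edgeom.refinement import _residual_arrays

        def resid(vv):
            rx, ry, rphi = _residual_arrays(param, sub, vv)
            return np.concatenate([rx, ry, rphi]) * bundle.weights

        for col, lbl in enumerate(param.labels):
            h = 5e-4 * (0.1 if lbl.startswith("g") else 1.0 if lbl not in ("dist", "shift1", "shift2") else 0.01)
            vals = []
            for m in (-2, -1, 1, 2):
                vv = v.copy()
                vv[col] += m * h
                vals.append(resid(vv))
            fd = (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h)
            scale = max(np.abs(fd).max(), 1e-12)
            assert np.abs(bundle.J[:, col] - fd).max() / scale < 1e-5, lbl

    def test_detector_columns_zero_in_phi_block(self, ed_bundle):
        param, bundle = ed_bundle
        phi_rows = bundle.J[bundle.block_bounds[2]]
        det_cols = [i for i, l in enumerate(param.labels) if l in ("dist", "shift1", "shift2", "tau1", "tau2", "tau3")]
        col_norms = np.linalg.norm(bundle.J, axis=0)
        for c in det_cols:
            assert np.linalg.norm(phi_rows[:, c]) < 1e-8 * col_norms.max()

    def test_no_usable_reflections(self, ed_sim):
        _, exp, obs = ed_sim
        param = build_parameterisation(exp)
        from edgeom.geometry import RefinementError

        with pytest.raises(RefinementError):
            residuals_and_jacobian(param, obs.select(np.zeros(len(obs), dtype=bool)))


class TestRestraints:
    def test_on_target_restraint_is_inert(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        param = build_parameterisation(exp)
        v = param.start_values()
        bundle = residuals_and_jacobian(param, obs.select(np.arange(len(obs)) < 50), v)
        spec = RestraintSpec({"a": (exp.crystal.cell[0], 0.1)})
        b2 = add_restraints(bundle, param, v, spec)
        assert b2.n_restraint == 1
        assert abs(b2.delta_r[-1]) < 1e-9

    def test_contributed_squared_residual(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        param = build_parameterisation(exp)
        v = param.start_values()
        bundle = residuals_and_jacobian(param, obs.select(np.arange(len(obs)) < 50), v)
        a_t = exp.crystal.cell[0] - 0.2
        b2 = add_restraints(bundle, param, v, RestraintSpec({"a": (a_t, 0.1)}))
        assert b2.delta_r[-1] ** 2 == pytest.approx(4.0, rel=1e-9)

    def test_symmetry_constrained_restraints_dropped(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        param = build_parameterisation(exp)
        v = param.start_values()
        bundle = residuals_and_jacobian(param, obs.select(np.arange(len(obs)) < 50), v)
        spec = RestraintSpec.from_cell(exp.crystal.cell, 0.1)  # all six requested
        b2 = add_restraints(bundle, param, v, spec)
        assert b2.n_restraint == 3  # angle restraints excluded for orthorhombic

    def test_gradient_rows_match_finite_differences(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        param = build_parameterisation(exp)
        v = param.start_values()
        bundle = residuals_and_jacobian(param, obs.select(np.arange(len(obs)) < 50), v)
        a_t = exp.crystal.cell[0] - 0.2
        sigma = 0.1
        b2 = add_restraints(bundle, param, v, RestraintSpec({"a": (a_t, sigma)}))
        row, res = b2.J[-1], b2.delta_r[-1]

        def R_a(vv):
            return ((param.cell_of(vv)[0] - a_t) / sigma) ** 2

        for col in range(len(v)):
            h = 1e-5 * max(abs(v[col]), 0.1)
            vp, vm = v.copy(), v.copy()
            vp[col] += h
            vm[col] -= h
            fd = (R_a(vp) - R_a(vm)) / (2 * h)
            assert 2 * res * row[col] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_scan_varying_cell_restraint_unsupported(self, ed_sim):
        _, exp, obs = ed_sim
        param = build_parameterisation(exp, scan_varying={"g11": 2})
        v = param.start_values()
        with pytest.raises(UnsupportedError):
            add_restraints(
                residuals_and_jacobian(param, obs.select(np.arange(len(obs)) < 30), v),
                param,
                v,
                RestraintSpec({"a": (32.0, 0.1)}),
            )


class TestLevenbergMarquardt:
    def test_zero_residual_start_terminates_immediately(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        param = build_parameterisation(exp)
        v0 = param.start_values()
        v, report, _ = levenberg_marquardt(lambda v: residuals_and_jacobian(param, obs, v), v0)
        assert report.status == "converged"
        assert np.array_equal(v, v0)

    def test_default_iteration_cap_is_100(self):
        import inspect

        assert inspect.signature(levenberg_marquardt).parameters["max_iterations"].default == 100

    def test_noise_free_parameter_recovery(self, small_ed_sim):
        """Perturbed start (missets +2 mrad, beam +1 mrad, cell x1.002) with
        dist/tau2/tau3 fixed recovers every parameter to 1e-4 of its
        characteristic scale."""
        _, exp, obs = small_ed_sim
        param = build_parameterisation(exp, fix=("dist", "tau2", "tau3"))
        truth = param.start_values()
        start = truth.copy()
        for i, lbl in enumerate(param.labels):
            if lbl.startswith("phi"):
                start[i] += 2.0
            elif lbl == "mu2":
                start[i] += 1.0
            elif lbl.startswith("g"):
                start[i] /= 1.002**2
        v, report, bundle = levenberg_marquardt(lambda v: residuals_and_jacobian(param, obs, v), start)
        char = {lbl: (0.1 if lbl.startswith("g") else 0.01 if lbl in ("shift1", "shift2") else 1.0) for lbl in param.labels}
        for i, lbl in enumerate(param.labels):
            assert abs(v[i] - truth[i]) < 1e-4 * char[lbl], lbl

    def test_cost_never_increases_on_accepted_steps(self, ed_sim):
        _, exp, obs = ed_sim
        sub = obs.select(np.arange(len(obs)) % 3 == 0)
        param = build_parameterisation(exp, fix=("dist", "tau2", "tau3"))
        start = param.start_values().copy()
        start[param.labels.index("phi2")] += 1.5
        v, report, bundle = levenberg_marquardt(
            lambda v: residuals_and_jacobian(param, sub, v), start
        )
        assert report.status in ("converged", "max_iterations")
        # the rmsd history holds accepted steps only; with uniform per-dimension
        # variances the weighted cost is reconstructible from it and must be
        # non-increasing
        hist = np.array(report.rmsd_history)
        w = np.array([1 / 0.3**2, 1 / 0.3**2, 1 / 0.02**2])
        cost = (hist**2) @ w
        assert np.all(np.diff(cost) <= 1e-9 * cost[0])


class TestRecoveryStatistics:
    def test_static_refinement_unbiased_over_noise_realizations(self):
        """Over 20 seeded noise realizations (0.3 px / 0.02 deg), every
        refined static parameter is unbiased within 2 standard errors of the
        mean."""
        errs = []
        for seed in range(100, 120):
            spec = ed_preset(seed=seed, d_min=8.0)
            exp, obs = simulate_reflections(spec)
            obs.set_flag(Flags.USED_IN_REFINEMENT)
            param = build_parameterisation(exp, fix=("dist", "tau2", "tau3"))
            truth = param.start_values()
            start = truth.copy()
            start[param.labels.index("phi1")] += 0.5
            v, _, _ = levenberg_marquardt(lambda v: residuals_and_jacobian(param, obs, v), start)
            errs.append(v - truth)
        errs = np.array(errs)
        mean = errs.mean(axis=0)
        se = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
        for i, lbl in enumerate(param.labels):
            assert abs(mean[i]) < 2 * se[i], lbl


class TestGaussianSmoother:
    def test_constant_values_reproduced_everywhere(self):
        sm = GaussianSmoother(4)
        x = np.linspace(0, 1, 57)
        assert np.allclose(smoother_value(sm, [3.3] * 4, x), 3.3)

    def test_two_samples_monotone(self):
        sm = GaussianSmoother(2)
        vals = smoother_value(sm, [0.0, 1.0], np.linspace(0, 1, 101))
        assert np.all(np.diff(vals) > 0)

    def test_weights_normalized_and_non_negative(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 5, 8):
            sm = GaussianSmoother(n)
            w = sm.weights(rng.uniform(-0.05, 1.05, 100))
            assert np.all(w >= 0)
            assert np.allclose(w.sum(axis=1), 1.0)

    def test_requires_two_samples(self):
        with pytest.raises(InvalidArgumentError):
            GaussianSmoother(1)


class TestOutlierRejection:
    def test_gaussian_residuals_rarely_flagged(self, ed_sim):
        _, _, obs = ed_sim
        sub = obs.select(np.arange(len(obs)) < 1000).copy()
        rng = np.random.default_rng(0)
        res = tuple(rng.normal(0, 1, len(sub)) for _ in range(3))
        n = reject_outliers(sub, res)
        assert n / len(sub) < 0.02

    def test_gross_outlier_always_flagged_and_idempotent(self, ed_sim):
        _, _, obs = ed_sim
        sub = obs.select(np.arange(len(obs)) < 200).copy()
        rng = np.random.default_rng(1)
        rx = rng.normal(0, 0.3, len(sub))
        rx[17] = 6.0  # 20 sigma
        res = (rx, rng.normal(0, 0.3, len(sub)), rng.normal(0, 0.02, len(sub)))
        n1 = reject_outliers(sub, res)
        assert sub.has_flag(Flags.OUTLIER)[17]
        flags1 = sub.df["flags"].to_numpy().copy()
        reject_outliers(sub, res)
        assert np.array_equal(sub.df["flags"].to_numpy(), flags1)


class TestRefineProtocol:
    def test_restrained_refinement_recovers_cell_with_distance_free(self, small_ed_sim):
        _, exp, obs = small_ed_sim
        target = exp.crystal.cell
        g_perturbed = metrical_from_cell(tuple(np.array(target[:3]) * 1.003) + (90.0, 90.0, 90.0))
        exp_p = e.ExperimentModel(
            beam=exp.beam,
            detector=exp.detector,
            goniometer=exp.goniometer,
            scan=exp.scan,
            crystal=e.CrystalModel(U=exp.crystal.U, g_star=g_perturbed, lattice_constraint=exp.crystal.lattice_constraint),
        )
        proto = RefinementProtocol(fix=("tau2", "tau3"), restraints=RestraintSpec.from_cell(target, 0.1))
        result = refine(exp_p, obs, proto)
        cell = result.experiment.crystal.cell
        for got, want in zip(cell[:3], target[:3]):
            assert abs(got - want) < 0.01

    def test_beam_drift_track_recovery(self):
        """Scan-varying beam refinement (2 samples/angle) recovers a 0.5 mrad
        half-cosine drift to < 0.05 mrad RMS with a calibrated detector."""
        spec = ed_preset(seed=5, beam_drift_mrad=0.5)
        exp_true, obs = simulate_reflections(spec)
        true_dirs = exp_true.scan_varying.beam_direction
        proto = RefinementProtocol(fix=("detector",), scan_varying=True, beam_samples=2)
        result = refine(ed_preset(seed=5).experiment, obs, proto)
        got = result.experiment.scan_varying.beam_direction
        ang_mrad = np.arccos(np.clip(np.einsum("ni,ni->n", got, true_dirs), -1, 1)) * 1e3
        assert np.sqrt((ang_mrad**2).mean()) < 0.05

    def test_static_experiment_gives_constant_tracks(self):
        """Scan-varying refinement of data without drift must not invent one:
        the recovered beam track stays constant within the static standard
        error."""
        spec = ed_preset(seed=11)
        exp, obs = simulate_reflections(spec)
        proto = RefinementProtocol(fix=("detector",), scan_varying=True, beam_samples=2)
        result = refine(spec.experiment, obs, proto)
        dirs = result.experiment.scan_varying.beam_direction
        mean = dirs.mean(axis=0)
        mean /= np.linalg.norm(mean)
        spread = np.arccos(np.clip(dirs @ mean, -1, 1)) * 1e3
        # static standard error of the beam angle from the normal matrix
        b = result.static_bundle
        JtJ = b.J.T @ b.J
        cov = np.linalg.inv(JtJ)
        i = b.labels.index("mu2")
        se_mu2 = np.sqrt(cov[i, i])
        assert spread.max() - spread.min() < 3 * max(se_mu2, 1e-3)
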