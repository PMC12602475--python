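"""Equilibrium solver, slack-length initialization and the flexion sweep."""

import numpy as np
import pandas as pd
import pytest

from tibfem import geometry, simulate, tissue_forces
from tibfem.jcs import decompose_joint
from tibfem.simulate import (EquilibriumSettings, TrajectorySet, femur_state_at,
                             read_trajectory_csv, relax_to_equilibrium, seat_pose,
                             solve_at, write_trajectory_csv, TRAJECTORY_COLUMNS)


class TestSettingsAndFrames:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumSettings(tol_force=0.0)
        with pytest.raises(ValueError):
            EquilibriumSettings(mode="dynamic")

    def test_hinged_femur_realizes_prescribed_flexion(self):
        from tibfem.jcs import RigidState
        for a in (0.1, 0.5, 1.2):
            femur = femur_state_at(a)
            jc = decompose_joint(femur, RigidState.identity())
            assert jc.alpha == pytest.approx(a, abs=1e-12)
            assert abs(jc.adduction) < 1e-12


class TestFullExtension:
    def test_le_table_and_contact_at_full_extension(self, coarse_knee):
        model, _ = coarse_knee
        femur, tibia, Le = simulate.estimate_full_extension(model,
                                                            start_alpha_deg=10.0)
        assert set(Le) == {l.name for l in model.ligaments}
        assert all(v > 0 for v in Le.values())
        cs = geometry.penetration_query(model.femur_cartilage, femur,
                                        model.tibia_cartilage, tibia)
        xs = model.tibia_cartilage.vertices[cs.vertex_ids, 0]
        assert (xs < 0).sum() >= 1 and (xs > 0).sum() >= 1

    def test_le_step_size_invariance(self, coarse_knee):
        """Le within 0.1 mm between 0.5 and 0.25 deg continuation steps."""
        model, _ = coarse_knee
        _, _, Le1 = simulate.estimate_full_extension(
            model, 10.0, EquilibriumSettings(step_deg=0.5))
        _, _, Le2 = simulate.estimate_full_extension(
            model, 10.0, EquilibriumSettings(step_deg=0.25))
        for name in Le1:
            assert abs(Le1[name] - Le2[name]) < 0.1

    def test_starting_at_zero_measures_lengths_directly(self, coarse_knee):
        model, _ = coarse_knee
        femur, tibia, Le = simulate.estimate_full_extension(model,
                                                            start_alpha_deg=0.0)
        states = tissue_forces.ligament_states(model, femur, tibia,
                                               require_initialized=False)
        for st in states:
            assert Le[st.name] == pytest.approx(st.L, abs=1e-12)

    def test_initialize_slack_lengths(self, coarse_knee):
        import copy
        model = copy.copy(coarse_knee[0])
        model.ligaments = copy.deepcopy(coarse_knee[0].ligaments)
        Le = {l.name: 40.0 + i for i, l in enumerate(model.ligaments)}
        simulate.initialize_slack_lengths(model, Le)
        for lig in model.ligaments:
            assert lig.L0 == pytest.approx(lig.e * Le[lig.name])
            assert lig.epsilon1 == pytest.approx(
                tissue_forces.transition_strain(lig.K_Q, lig.K_L, lig.L0))
        # locality: changing one element's e rescales only that element
        target = model.ligament("LCL")
        old = {l.name: l.L0 for l in model.ligaments}
        target.e *= 0.9
        simulate.initialize_slack_lengths(model, Le)
        for lig in model.ligaments:
            if lig.name == "LCL":
                assert lig.L0 == pytest.approx(0.9 * old["LCL"])
            else:
                assert lig.L0 == pytest.approx(old[lig.name])
        target.e /= 0.9
        simulate.initialize_slack_lengths(model, Le)

    def test_missing_element_in_le_table(self, coarse_knee):
        model, _ = coarse_knee
        with pytest.raises(KeyError, match="aACL"):
            simulate.initialize_slack_lengths(model, {"pACL": 30.0})


class TestEquilibrium:
    def test_fixed_point_returns_immediately(self, initialized_coarse_knee,
                                              coarse_settings):
        model, _ = initialized_coarse_knee
        a = np.radians(15.0)
        tibia, rep = solve_at(model, a, coarse_settings)
        assert rep.converged
        tibia2, rep2 = relax_to_equilibrium(model, femur_state_at(a), rep.x, a,
                                            coarse_settings)
        assert rep2.converged
        assert rep2.iterations == 0
        assert np.allclose(rep2.x, rep.x)

    def test_perturb_and_recover(self, initialized_coarse_knee, coarse_settings):
        """Perturbing the equilibrium by 0.5 mm / 0.5 deg and re-relaxing
        recovers the same pose within 10x the residual tolerance."""
        model, _ = initialized_coarse_knee
        settings = coarse_settings
        a = np.radians(16.0)
        _, rep = solve_at(model, a, settings)
        assert rep.converged
        rng = np.random.default_rng(6)
        for _ in range(3):
            pert = np.concatenate([np.radians(0.5) * rng.choice([-1, 1], 2),
                                   0.5 * rng.choice([-1, 1], 3)])
            _, rep2 = relax_to_equilibrium(model, femur_state_at(a), rep.x + pert,
                                           a, settings)
            assert rep2.converged
            assert np.max(np.abs(rep2.x - rep.x)) < 10 * settings.tol_force

    def test_residual_below_tolerance_at_solution(self, initialized_coarse_knee,
                                                   coarse_settings):
        model, _ = initialized_coarse_knee
        settings = coarse_settings
        _, rep = solve_at(model, np.radians(18.0), settings)
        assert rep.converged
        assert rep.residual_force < settings.tol_force
        assert rep.residual_torque < settings.tol_torque

    def test_energy_decreases_over_accepted_iterations(self, initialized_coarse_knee):
        model, _ = initialized_coarse_knee
        settings = EquilibriumSettings(trace_energy=True, tol_force=0.02,
                                       tol_torque=0.02)
        a = np.radians(25.0)
        x0 = seat_pose(model, a) + np.array([0.05, 0.02, 1.0, -1.0, 0.3])
        _, rep = relax_to_equilibrium(model, femur_state_at(a), x0, a, settings)
        trace = rep.energy_trace
        if len(trace) >= 2:  # the L-BFGS stage ran
            assert np.all(np.diff(trace) <= 1e-9)

    def test_history_free_direct_equals_continuation(self, initialized_coarse_knee,
                                                      coarse_settings):
        model, _ = initialized_coarse_knee
        settings = coarse_settings
        a_target = np.radians(18.0)
        # continuation from 10 deg
        x = seat_pose(model, np.radians(10.0))
        cache = {}
        for a_deg in np.arange(10.0, 18.01, settings.step_deg):
            a = np.radians(a_deg)
            _, rep = relax_to_equilibrium(model, femur_state_at(a), x, a, settings,
                                          _cache=cache)
            x = rep.x
        _, rep_direct = solve_at(model, a_target, settings)
        assert rep_direct.converged and rep.converged
        assert np.max(np.abs(rep_direct.x - x)) < 10 * settings.tol_force


class TestPassiveFlexion:
    def test_constant_profile_constant_outputs(self, initialized_coarse_knee,
                                                coarse_settings):
        model, _ = initialized_coarse_knee
        traj = simulate.run_passive_flexion(model, [np.full(5, 18.0)],
                                            coarse_settings)
        df = traj.frame
        for col in ("adduction_deg", "internal_rotation_deg", "S2_mm", "S3_mm"):
            assert np.ptp(df[col].to_numpy()) < 1e-6

    def test_deterministic_repeat(self, initialized_coarse_knee, coarse_settings):
        model, _ = initialized_coarse_knee
        prof = np.arange(10.0, 14.1, 0.5)
        t1 = simulate.run_passive_flexion(model, [prof], coarse_settings)
        t2 = simulate.run_passive_flexion(model, [prof], coarse_settings)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_no_hysteresis_between_sweep_limbs(self, initialized_coarse_knee,
                                               coarse_settings):
        """Quasi-static solves are history-free: the up and down limbs of a
        cycle agree at equal flexion within solver slack."""
        model, _ = initialized_coarse_knee
        up = np.arange(10.0, 20.1, 0.5)
        prof = np.concatenate([up, up[::-1]])
        traj = simulate.run_passive_flexion(model, [prof], coarse_settings)
        df = traj.frame[traj.frame.converged]
        for a in (12.0, 16.0, 19.0):
            rows = df[np.isclose(df.flexion_deg, a)]
            assert len(rows) == 2
            assert np.ptp(rows["S2_mm"].to_numpy()) < 0.05
            assert np.ptp(rows["S3_mm"].to_numpy()) < 0.05

    def test_accepted_samples_satisfy_tolerance(self, initialized_coarse_knee,
                                                 coarse_settings):
        model, _ = initialized_coarse_knee
        settings = coarse_settings
        traj = simulate.run_passive_flexion(model, [np.arange(8.0, 16.1, 0.5)],
                                            settings)
        ok = traj.frame[traj.frame.converged]
        assert len(ok) > 0
        assert (ok["residual_force_N"] < settings.tol_force).all()
        assert (ok["residual_torque_Nmm"] < settings.tol_torque).all()

    def test_trajectoryset_rejects_overtolerance_accepted_sample(self):
        df = pd.DataFrame([{c: 0.0 for c in TRAJECTORY_COLUMNS}])
        df["converged"] = True
        df["residual_force_N"] = 1.0
        with pytest.raises(AssertionError):
            TrajectorySet(frame=df, settings=EquilibriumSettings())

    def test_trajectory_csv_round_trip(self, tmp_path, initialized_coarse_knee,
                                       coarse_settings):
        model, _ = initialized_coarse_knee
        traj = simulate.run_passive_flexion(model, [np.arange(12.0, 14.1, 0.5)],
                                            coarse_settings)
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path, seed=5, config_hash="abc")
        first = path.read_text().splitlines()[0]
        assert first.startswith("#") and "seed=5" in first and "abc" in first
        back = read_trajectory_csv(path)
        assert list(back.columns) == list(traj.frame.columns)
        assert np.allclose(back["S2_mm"], traj.frame["S2_mm"])
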