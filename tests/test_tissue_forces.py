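"""Ligament and contact constitutive laws, and wrench assembly."""

import numpy as np
import pytest
from scipy.optimize import brentq

from tibfem import tissue_forces as tf
from tibfem.jcs import RigidState
from tibfem.model import ContactParams, LigamentSpec
from tibfem.tissue_forces import DEFAULT_LIGAMENT_PARAMS


def _spec(K_Q=30.0, K_L=60.0, L0=35.0, name="aACL"):
    s = LigamentSpec(name=name, femoral_mm=[0, 0, 0], tibial_mm=[0, 0, -L0],
                     K_Q=K_Q, K_L=K_L, e=1.0)
    s.L0 = L0
    s.epsilon1 = tf.transition_strain(K_Q, K_L, L0)
    return s


class TestScalarLaws:
    @pytest.mark.parametrize("L,L0,expected", [(100, 100, 0.0), (103, 100, 0.03),
                                               (95, 100, -0.05)])
    def test_strain(self, L, L0, expected):
        assert tf.strain(L, L0) == pytest.approx(expected, abs=1e-15)

    def test_strain_rejects_nonpositive_slack_length(self):
        with pytest.raises(ValueError):
            tf.strain(10.0, 0.0)

    @pytest.mark.parametrize("e,Le,expected", [(1.0, 40, 40.0), (0.95, 40, 38.0),
                                               (1.05, 40, 42.0)])
    def test_slack_length(self, e, Le, expected):
        assert tf.slack_length(e, Le) == pytest.approx(expected)

    def test_transition_strain_against_numeric_continuity_solve(self):
        """eps1 from the closed form matches solving the two continuity
        equations (value and slope agree at the branch switch) numerically."""
        K_Q, K_L, L0 = 10.0, 2.0, 10.0

        def slope_gap(eps1):
            # at the switch L* = L0(1+2*eps1): quadratic slope 2K_Q(L*-L0)
            Lstar = L0 * (1 + 2 * eps1)
            return 2 * K_Q * (Lstar - L0) - K_L

        eps1_num = brentq(slope_gap, 1e-9, 1.0)
        Lstar = L0 * (1 + 2 * eps1_num)
        value_gap = K_Q * (Lstar - L0) ** 2 - K_L * (Lstar - L0 * (1 + eps1_num))
        assert abs(value_gap) < 1e-12  # both continuity equations hold
        assert tf.transition_strain(K_Q, K_L, L0) == pytest.approx(eps1_num, abs=1e-12)
        assert tf.transition_strain(2 * K_Q, K_L, L0) == pytest.approx(eps1_num / 2)

    def test_tension_zero_when_slack_or_unstretched(self):
        s = _spec()
        assert tf.ligament_tension(s, 0.9 * s.L0) == 0.0
        assert tf.ligament_tension(s, s.L0) == 0.0

    def test_tension_c1_at_transition_and_linear_slope(self):
        """Value and slope jumps at 2*eps1 below 1e-6*K_L; far slope = K_L."""
        for name, (K_Q, K_L, _) in DEFAULT_LIGAMENT_PARAMS.items():
            s = _spec(K_Q=K_Q, K_L=K_L, L0=42.0, name=name)
            Lstar = s.L0 * (1 + 2 * s.epsilon1)
            h = 1e-8
            jump = abs(tf.ligament_tension(s, Lstar + h) - tf.ligament_tension(s, Lstar - h))
            slope_lo = (tf.ligament_tension(s, Lstar) - tf.ligament_tension(s, Lstar - h)) / h
            slope_hi = (tf.ligament_tension(s, Lstar + h) - tf.ligament_tension(s, Lstar)) / h
            assert jump < 1e-6 * K_L
            assert abs(slope_hi - slope_lo) < 1e-6 * K_L
            # asymptotic slope in the linear region
            L = s.L0 * 1.2
            fd = (tf.ligament_tension(s, L + 1e-6) - tf.ligament_tension(s, L - 1e-6)) / 2e-6
            assert fd == pytest.approx(K_L, abs=1e-6 * K_L)

    def test_tension_monotone_nondecreasing(self):
        s = _spec()
        L = np.linspace(0.8 * s.L0, 1.3 * s.L0, 2000)
        F = tf.ligament_tension(s, L)
        assert np.all(np.diff(F) >= -1e-12)
        assert np.all(F >= 0)

    def test_literal_mode_is_discontinuous_at_eps1(self):
        s = _spec()
        Lswitch = s.L0 * (1 + s.epsilon1)
        lo = tf.ligament_tension(s, Lswitch - 1e-9, mode="literal")
        hi = tf.ligament_tension(s, Lswitch + 1e-9, mode="literal")
        assert abs(hi - lo) > 0.1 * lo  # the printed form jumps here

    def test_energy_derivative_matches_tension(self):
        s = _spec()
        for L in (s.L0 * 1.0005, s.L0 * (1 + 2 * s.epsilon1), s.L0 * 1.15):
            fd = (tf.ligament_energy(s, L + 1e-6) - tf.ligament_energy(s, L - 1e-6)) / 2e-6
            assert fd == pytest.approx(tf.ligament_tension(s, L), rel=1e-5, abs=1e-6)

    @pytest.mark.parametrize("delta,expected", [(0.0, 0.0), (0.01, 1.0), (0.005, 0.5)])
    def test_smooth_step_values(self, delta, expected):
        assert tf.smooth_step(delta, 0.01) == pytest.approx(expected)

    def test_contact_force_matches_k_delta_p(self):
        p = ContactParams()
        assert tf.contact_force(-0.5, 0.0, p) == 0.0
        # k*delta^p at the published constants: 500 * 0.01^1.5 = 0.5 N
        assert tf.contact_force(0.01, 0.0, p) == pytest.approx(0.5, abs=1e-12)
        deltas = np.linspace(0, 0.2, 50)
        assert np.allclose(tf.contact_force(deltas, 0.0, p), p.k * deltas ** p.p)

    def test_contact_force_never_adhesive(self):
        p = ContactParams()
        # large opening rate at small penetration would pull: clamped at zero
        assert tf.contact_force(0.001, -1e5, p) == 0.0
        assert tf.contact_force(0.001, 1.0, p) >= tf.contact_force(0.001, 0.0, p)


class TestWrenchAssembly:
    @staticmethod
    def _own_copy(model):
        # these tests rewrite slack lengths; never mutate the shared fixture
        import copy
        m = copy.copy(model)
        m.ligaments = copy.deepcopy(model.ligaments)
        return m

    def _slacken_all(self, model):
        for lig in model.ligaments:
            lig.L0 = 200.0
            lig.epsilon1 = tf.transition_strain(lig.K_Q, lig.K_L, lig.L0)

    def test_all_slack_no_contact_zero_wrench(self, coarse_knee):
        model = self._own_copy(coarse_knee[0])
        self._slacken_all(model)
        femur = RigidState.identity()
        from tibfem.jcs import compose_joint, joint_coordinates
        tibia = compose_joint(joint_coordinates(S3=-80.0), femur)  # far apart
        F, T, states, contacts = tf.assemble_wrench(model, femur, tibia)
        assert np.allclose(F, 0) and np.allclose(T, 0)
        assert len(contacts) == 0
        assert all(s.tension == 0 for s in states)

    def test_single_taut_ligament_against_hand_calculation(self, coarse_knee):
        model = self._own_copy(coarse_knee[0])
        self._slacken_all(model)
        femur = RigidState.identity()
        from tibfem.jcs import compose_joint, joint_coordinates
        tibia = compose_joint(joint_coordinates(S3=-80.0), femur)
        lig = model.ligament("sMCL")
        f_pt = femur.frame.to_parent(lig.femoral_mm)
        t_pt = tibia.frame.to_parent(lig.tibial_mm)
        L = np.linalg.norm(f_pt - t_pt)
        lig.L0 = 0.97 * L
        lig.epsilon1 = tf.transition_strain(lig.K_Q, lig.K_L, lig.L0)

        F, T, _, _ = tf.assemble_wrench(model, femur, tibia)
        # independent hand assembly of the one taut element
        direction = (f_pt - t_pt) / L
        tension = tf.ligament_tension(lig, float(L))
        assert tension > 0
        assert np.allclose(F, tension * direction, atol=1e-9)
        expected_T = np.cross(t_pt - tibia.frame.origin, tension * direction)
        assert np.allclose(T, expected_T, atol=1e-9)

    def test_assembly_additive_over_elements(self, coarse_knee):
        """Wrench of the model equals the sum of single-element wrenches."""
        model, _ = coarse_knee
        rng = np.random.default_rng(11)
        femur = RigidState.identity()
        from tibfem.jcs import compose_joint, joint_coordinates
        tibia = compose_joint(joint_coordinates(S3=-80.0), femur)
        # randomly pre-tension every element at this (contact-free) pose
        for lig in model.ligaments:
            f_pt = femur.frame.to_parent(lig.femoral_mm)
            t_pt = tibia.frame.to_parent(lig.tibial_mm)
            L = float(np.linalg.norm(f_pt - t_pt))
            lig.L0 = L * rng.uniform(0.95, 1.05)
            lig.epsilon1 = tf.transition_strain(lig.K_Q, lig.K_L, lig.L0)
        F_all, T_all, _, _ = tf.assemble_wrench(model, femur, tibia)
        F_sum, T_sum = np.zeros(3), np.zeros(3)
        saved = [(l.L0, l.epsilon1) for l in model.ligaments]
        for i, lig in enumerate(model.ligaments):
            for j, other in enumerate(model.ligaments):
                other.L0 = 500.0 if j != i else saved[j][0]
                other.epsilon1 = tf.transition_strain(other.K_Q, other.K_L, other.L0) \
                    if j != i else saved[j][1]
            F, T, _, _ = tf.assemble_wrench(model, femur, tibia)
            F_sum += F
            T_sum += T
        for lig, (L0, e1) in zip(model.ligaments, saved):
            lig.L0, lig.epsilon1 = L0, e1
        assert np.allclose(F_all, F_sum, atol=1e-8)
        assert np.allclose(T_all, T_sum, atol=1e-8)

    def test_newtons_third_law_wrench_transport(self, coarse_knee):
        model = self._own_copy(coarse_knee[0])
        self._slacken_all(model)
        femur = RigidState.identity()
        from tibfem.jcs import compose_joint, joint_coordinates
        tibia = compose_joint(joint_coordinates(S3=-80.0), femur)
        lig = model.ligament("LCL")
        t_pt = tibia.frame.to_parent(lig.tibial_mm)
        L = np.linalg.norm(femur.frame.to_parent(lig.femoral_mm) - t_pt)
        lig.L0 = 0.95 * L
        lig.epsilon1 = tf.transition_strain(lig.K_Q, lig.K_L, lig.L0)
        F, T, _, _ = tf.assemble_wrench(model, femur, tibia)
        T_fem = tf.transport_torque(-F, -T, tibia.frame.origin, femur.frame.origin)
        # femoral wrench assembled directly about the femoral origin
        f_pt = femur.frame.to_parent(lig.femoral_mm)
        tension = tf.ligament_tension(lig, float(L))
        dirn = (t_pt - f_pt) / L
        assert np.allclose(-F, tension * dirn, atol=1e-9)
        assert np.allclose(T_fem, np.cross(f_pt - femur.frame.origin, tension * dirn),
                           atol=1e-8)


class TestLawProperties:
    """Property-based checks of the constitutive laws."""

    from hypothesis import given, settings, strategies as st

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(K_Q=st.floats(1.0, 200.0), K_L=st.floats(5.0, 300.0),
           L0=st.floats(10.0, 120.0),
           eps=st.floats(-0.2, 0.4))
    def test_tension_nonnegative_zero_when_slack_continuous(self, K_Q, K_L, L0, eps):
        s = _spec(K_Q=K_Q, K_L=K_L, L0=L0)
        L = L0 * (1 + eps)
        F = tf.ligament_tension(s, L)
        assert F >= 0.0
        if eps <= 0:
            assert F == 0.0
        # local continuity in L
        h = 1e-7 * L0
        assert abs(tf.ligament_tension(s, L + h) - F) < max(10 * K_L * h, 1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(delta=st.floats(-1.0, 1.0), delta_c=st.floats(1e-4, 1.0))
    def test_smooth_step_bounded_and_monotone(self, delta, delta_c):
        h = tf.smooth_step(delta, delta_c)
        assert 0.0 <= h <= 1.0
        assert tf.smooth_step(delta + 1e-6, delta_c) >= h - 1e-12
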