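"""Reference signals, the substitute arm, and closed-loop plumbing."""

import numpy as np
import pytest

from cereblearn.loop import (
    ArmModel,
    LoopDelayLine,
    ReferenceCurveConfig,
    TrajectoryConfig,
    calibrate_decoder_gain,
    crude_inverse_dynamics,
    desired_joint_state,
    plant_energy,
    reference_variable,
    step_plant,
)
from cereblearn._fast import arm_inverse_dynamics


class TestReferenceCurve:
    def test_zero_at_half_period(self):
        assert reference_variable(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_positive_lobe_peak_value(self):
        cfg = ReferenceCurveConfig(sigma_ref=0.1, period=1.0)
        assert reference_variable(0.25, cfg) == pytest.approx(1.0 - np.exp(-25), rel=1e-9)

    def test_antisymmetric_about_midpoint(self):
        t = np.linspace(0, 1, 201)
        cfg = ReferenceCurveConfig()
        assert np.allclose(reference_variable(t, cfg),
                           -reference_variable(1.0 - t, cfg), atol=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReferenceCurveConfig(sigma_ref=2.0, period=1.0)


class TestTrajectory:
    def test_initial_positions(self):
        cfg = TrajectoryConfig(amplitudes=(0.5, 0.3, 0.2))
        q, qd, _ = desired_joint_state(0.0, cfg)
        assert q[0] == pytest.approx(0.5 * np.sin(np.pi / 4))
        assert q[0] == pytest.approx(0.5 * 0.70710678, rel=1e-6)

    def test_trajectory_closes_after_full_phase(self):
        # phi(1) = -4 pi + 6 pi = 2 pi, so the curve returns to its start
        cfg = TrajectoryConfig()
        q0, _, _ = desired_joint_state(0.0, cfg)
        q1, _, _ = desired_joint_state(1.0, cfg)
        assert np.allclose(q0, q1, atol=1e-9)

    def test_zero_boundary_velocities(self):
        cfg = TrajectoryConfig()
        for t in (0.0, 1.0):
            _, qd, _ = desired_joint_state(t, cfg)
            assert np.allclose(qd, 0.0, atol=1e-9)

    def test_derivatives_match_finite_differences(self):
        cfg = TrajectoryConfig()
        h = 1e-6
        for t in (0.2, 0.5, 0.83):
            qm, _, _ = desired_joint_state(t - h, cfg)
            qp, _, _ = desired_joint_state(t + h, cfg)
            _, qd, qdd = desired_joint_state(t, cfg)
            assert np.allclose((qp - qm) / (2 * h), qd, atol=1e-5)
            vm = desired_joint_state(t - h, cfg)[1]
            vp = desired_joint_state(t + h, cfg)[1]
            assert np.allclose((vp - vm) / (2 * h), qdd, atol=1e-4)


class TestArm:
    def test_horizontal_statics_match_closed_form(self):
        arm = ArmModel(payload=0.0)
        tau = crude_inverse_dynamics(np.zeros(3), np.zeros(3), np.zeros(3), arm)
        L, m, g = arm.lengths, arm.masses, arm.gravity
        x = np.cumsum(L)
        expected = [
            sum(m[k] * g * x[k] for k in range(3)),
            sum(m[k] * g * (x[k] - x[0]) for k in range(1, 3)),
            m[2] * g * (x[2] - x[1]),
        ]
        assert np.allclose(tau, expected, rtol=1e-12)

    def test_crude_model_ignores_payload(self):
        loaded = ArmModel(payload=6.0)
        unloaded = ArmModel(payload=0.0)
        q = np.array([0.3, -0.2, 0.5])
        t1 = crude_inverse_dynamics(q, np.zeros(3), np.zeros(3), loaded)
        t2 = crude_inverse_dynamics(q, np.zeros(3), np.zeros(3), unloaded)
        assert np.allclose(t1, t2)

    def test_torque_linear_in_masses(self, rng):
        q, qd, qdd = rng.normal(0, 0.5, (3, 3))
        L = np.array([0.4, 0.4, 0.3])
        m1 = np.array([2.0, 1.5, 1.0])
        t1 = arm_inverse_dynamics(q, qd, qdd, L, m1, 0.0, 9.81, 0.0)
        t2 = arm_inverse_dynamics(q, qd, qdd, L, 2 * m1, 0.0, 9.81, 0.0)
        assert np.allclose(t2, 2 * t1, rtol=1e-10)

    def test_payload_increases_holding_torque_monotonically(self):
        q = np.array([0.2, 0.3, -0.1])
        taus = [
            arm_inverse_dynamics(q, np.zeros(3), np.zeros(3),
                                 np.array([0.4, 0.4, 0.3]),
                                 np.array([2.0, 1.5, 1.0]), p, 9.81, 0.0)[1]
            for p in (0.0, 2.0, 4.0, 6.0)
        ]
        assert all(b > a for a, b in zip(taus, taus[1:]))

    def test_rest_state_unchanged_without_forces(self):
        arm = ArmModel(gravity=0.0, friction=0.0)
        q, qd = step_plant(np.array([0.1, 0.2, 0.3]), np.zeros(3), np.zeros(3), arm)
        assert np.allclose(q, [0.1, 0.2, 0.3]) and np.allclose(qd, 0.0)

    def test_passive_energy_conserved(self):
        # frictionless swing from rest; semi-implicit Euler at a fine substep
        arm = ArmModel(friction=0.0, payload=0.0)
        q = np.array([0.3, -0.5, 0.2])
        qd = np.zeros(3)
        e0 = plant_energy(q, qd, arm)
        for _ in range(500):
            q, qd = step_plant(q, qd, np.zeros(3), arm, 0.002, 200)
        drift = abs(plant_energy(q, qd, arm) - e0) / abs(e0)
        assert drift < 1e-3

    def test_inverse_then_forward_is_consistent(self):
        # torques from inverse dynamics reproduce the demanded acceleration
        arm = ArmModel(payload=3.0)
        L = np.asarray(arm.lengths)
        m = np.asarray(arm.masses)
        q = np.array([0.4, -0.3, 0.25])
        qd = np.array([0.5, -0.2, 0.1])
        qdd_target = np.array([1.0, -0.5, 0.3])
        tau = arm_inverse_dynamics(q, qd, qdd_target, L, m, arm.payload,
                                   arm.gravity, arm.friction)
        q2, qd2 = step_plant(q, qd, tau, arm, 1e-5, 1)
        qdd_obs = (qd2 - qd) / 1e-5
        assert np.allclose(qdd_obs, qdd_target, atol=1e-6)


class TestDelayLine:
    def test_hundred_ms_delay(self):
        line = LoopDelayLine(delay=0.1, dt=0.002)
        outs = [line.push(float(i))[0] for i in range(60)]
        assert outs[:50] == [0.0] * 50
        assert outs[50:] == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]

    def test_reset_clears(self):
        line = LoopDelayLine(delay=0.01, dt=0.002)
        for i in range(9):
            line.push(float(i + 1))
        line.reset()
        assert line.push(0.0)[0] == 0.0


def test_decoder_gain_calibration_spans_full_scale():
    gain = calibrate_decoder_gain(1.3, max_rate_hz=250.0, tau_taps=16.0, dt=0.002)
    # steady firing at 250 Hz (0.5 spikes/step) must decode to full scale
    decay = np.exp(-1 / 16.0)
    y = 0.0
    for _ in range(1000):
        y = decay * y + gain * 0.5
    assert y == pytest.approx(1.3, rel=1e-6)
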