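"""Closed-loop benchmark definitions: reference signals, delay line, and
the substitute robotic plant.

Case A: set-point tracking. The cerebellar output itself is the controlled
variable and must match a 1 s reference made of two opposite-signed
Gaussians (an agonist/antagonist demand). Case B: feed-forward torque
control of a simulated 3-link arm following a 1 s "eight-shaped"
joint-space trajectory while holding a payload; a crude inverse-dynamics
model (computed *without* the payload) provides baseline torques and the
cerebellum must learn the corrective difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fast import arm_energy, arm_forward_step, arm_inverse_dynamics
from .lif import DT

__all__ = [
    "ReferenceCurveConfig",
    "TrajectoryConfig",
    "ArmModel",
    "LoopDelayLine",
    "reference_variable",
    "desired_joint_state",
    "crude_inverse_dynamics",
    "step_plant",
    "plant_energy",
    "calibrate_decoder_gain",
]


@dataclass(frozen=True)
class ReferenceCurveConfig:
    """Case A reference: difference of two Gaussians at T/4 and 3T/4."""

    sigma_ref: float = 0.1  # s (T/10)
    period: float = 1.0  # s

    def __post_init__(self):
        if not 0 < self.sigma_ref < self.period:
            raise ValueError("need 0 < sigma_ref < period")


def reference_variable(t, config: ReferenceCurveConfig = ReferenceCurveConfig()):
    """Two-lobed set-point curve, antisymmetric about T/2."""
    t = np.asarray(t, dtype=float)
    T, s2 = config.period, config.sigma_ref**2
    out = np.exp(-((t - T / 4) ** 2) / s2) - np.exp(-((t - 3 * T / 4) ** 2) / s2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Case B eight-shaped joint trajectory.

    ``Q_n(t) = A_n sin(phi(s) + C_n)`` with ``phi(s) = -4 pi s^3 + 6 pi s^2``,
    ``s = t/duration`` and phases ``C_n = n pi / 4``. ``phi`` runs 0 -> 2 pi
    with zero slope at both ends, giving zero initial/final joint velocity.
    """

    amplitudes: tuple = (0.5, 0.3, 0.2)  # rad
    duration: float = 1.0  # s

    @property
    def phases(self) -> np.ndarray:
        return np.arange(1, len(self.amplitudes) + 1) * np.pi / 4


def desired_joint_state(t, config: TrajectoryConfig = TrajectoryConfig()):
    """Desired (Q, Qdot, Qddot) per joint at time ``t``."""
    A = np.asarray(config.amplitudes, dtype=float)
    C = config.phases
    s = np.asarray(t, dtype=float) / config.duration
    phi = -4 * np.pi * s**3 + 6 * np.pi * s**2
    dphi = (-12 * np.pi * s**2 + 12 * np.pi * s) / config.duration
    ddphi = (-24 * np.pi * s + 12 * np.pi) / config.duration**2
    phase = np.multiply.outer(phi, np.ones_like(C)) + C if np.ndim(s) else phi + C
    q = A * np.sin(phase)
    qd = A * np.cos(phase) * np.expand_dims(dphi, -1) if np.ndim(s) else A * np.cos(phase) * dphi
    qdd = (
        A * (-np.sin(phase)) * np.expand_dims(dphi, -1) ** 2
        + A * np.cos(phase) * np.expand_dims(ddphi, -1)
        if np.ndim(s)
        else A * (-np.sin(phase)) * dphi**2 + A * np.cos(phase) * ddphi
    )
    return q, qd, qdd


@dataclass(frozen=True)
class ArmModel:
    """Documented substitute plant: a planar 3-link arm with distal point
    masses, viscous joint friction, and the payload as an end-effector
    point mass. The crude controller model is the same chain with
    ``payload = 0``."""

    lengths: tuple = (0.4, 0.4, 0.3)  # m
    masses: tuple = (2.0, 1.5, 1.0)  # kg
    friction: float = 0.1  # N*m*s per joint
    gravity: float = 9.81  # m/s^2
    payload: float = 0.0  # kg at the end effector

    def _arr(self):
        return (
            np.asarray(self.lengths, dtype=float),
            np.asarray(self.masses, dtype=float),
        )


def crude_inverse_dynamics(q, qd, qdd, arm: ArmModel) -> np.ndarray:
    """Feed-forward torques of the *unloaded* arm (payload ignored): the
    deliberate model mismatch the cerebellum must compensate."""
    lengths, masses = arm._arr()
    return arm_inverse_dynamics(
        np.asarray(q, float), np.asarray(qd, float), np.asarray(qdd, float),
        lengths, masses, 0.0, arm.gravity, arm.friction,
    )


def step_plant(q, qd, torque, arm: ArmModel, dt: float = DT, n_substeps: int = 10):
    """Advance the true (loaded) plant by one clock step; returns new (q, qd).

    Semi-implicit Euler with internal substeps; raises on numerical
    blow-up.
    """
    lengths, masses = arm._arr()
    q = np.asarray(q, dtype=float).copy()
    qd = np.asarray(qd, dtype=float).copy()
    bad = arm_forward_step(
        q, qd, np.asarray(torque, float), lengths, masses,
        arm.payload, arm.gravity, arm.friction, dt, n_substeps,
    )
    if bad:
        raise RuntimeError("plant integration blew up")
    return q, qd


def plant_energy(q, qd, arm: ArmModel) -> float:
    """Mechanical energy audit of the loaded plant."""
    lengths, masses = arm._arr()
    return float(
        arm_energy(np.asarray(q, float), np.asarray(qd, float), lengths, masses,
                   arm.payload, arm.gravity)
    )


class LoopDelayLine:
    """FIFO modelling the ~100 ms sensorimotor delay of the error pathway."""

    def __init__(self, delay: float = 0.100, dt: float = DT, n_channels: int = 1):
        self.n = max(1, int(round(delay / dt)))
        self.buf = np.zeros((self.n, n_channels))
        self.ptr = 0

    def push(self, x) -> np.ndarray:
        out = self.buf[self.ptr].copy()
        self.buf[self.ptr] = x
        self.ptr = (self.ptr + 1) % self.n
        return out

    def reset(self) -> None:
        self.buf[:] = 0.0
        self.ptr = 0


def calibrate_decoder_gain(
    full_scale: float,
    max_rate_hz: float = 250.0,
    tau_taps: float = 25.0,
    dt: float = DT,
) -> float:
    """Per-spike decoder gain such that a channel firing steadily at
    ``max_rate_hz`` decodes to ``full_scale`` output units."""
    decay = np.exp(-1.0 / tau_taps)
    return float(full_scale * (1.0 - decay) / (max_rate_hz * dt))
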