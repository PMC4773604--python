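"""Numba-jitted numerical kernels: LIF integration and 3-link arm dynamics.

These are the hot inner loops of the clock-driven simulator. They operate on
bare float64 arrays; all unit handling and validation lives in the calling
modules. Units here: potentials mV, conductances nS, capacitance pF, time s
(note nS*mV = pA and pA/pF = mV/ms, hence the 1e3 factor on dV/dt).
"""

import numpy as np
from numba import njit

__all__ = [
    "lif_step",
    "arm_inverse_dynamics",
    "arm_forward_step",
    "arm_forward_step_servo",
    "arm_energy",
]


@njit(cache=True)
def lif_step(
    v, g_e, g_i, refr_until,
    exc_in, inh_in,
    t, dt, n_sub,
    c_m, g_leak, e_leak, v_thresh, v_reset, t_refr, e_exc, e_inh, tau_e, tau_i,
    spikes,
):
    """Advance one population by one clock step of length ``dt``.

    Synaptic input increments (``exc_in``/``inh_in``, nS per neuron) are
    applied at the start of the step; the membrane is then integrated over
    ``n_sub`` substeps with the exponential-Euler update (exact for the
    conductances held at their substep-start values, unconditionally
    stable for arbitrarily large conductance), while conductances decay
    exponentially (exact per-substep factor). ``spikes`` (int64 out) counts
    threshold crossings per neuron. Returns the number of non-finite
    membrane values (0 in healthy operation; caller aborts otherwise).
    """
    n = v.shape[0]
    h = dt / n_sub
    decay_e = np.exp(-h / tau_e)
    decay_i = np.exp(-h / tau_i)
    for i in range(n):
        g_e[i] += exc_in[i]
        g_i[i] += inh_in[i]
        spikes[i] = 0
    bad = 0
    for k in range(n_sub):
        t_sub = t + k * h
        for i in range(n):
            if t_sub < refr_until[i]:
                v[i] = v_reset
            else:
                g_tot = g_leak + g_e[i] + g_i[i]
                v_inf = (
                    g_leak * e_leak + g_e[i] * e_exc + g_i[i] * e_inh
                ) / g_tot
                # h in s, c_m/g_tot in pF/nS = ms
                v[i] = v_inf + (v[i] - v_inf) * np.exp(-1e3 * h * g_tot / c_m)
                if v[i] >= v_thresh:
                    spikes[i] += 1
                    v[i] = v_reset
                    refr_until[i] = t_sub + t_refr
            g_e[i] *= decay_e
            g_i[i] *= decay_i
            if not np.isfinite(v[i]):
                bad += 1
    return bad


# --------------------------------------------------------------------------
# planar 3-link arm (point masses at the distal end of each link)


@njit(cache=True)
def arm_inverse_dynamics(q, qd, qdd, lengths, masses, payload, gravity, friction):
    """Joint torques of a planar 3-link chain with distal point masses.

    The payload is a point mass added at the end effector (i.e. to link 3's
    mass). Gravity acts along -y; ``friction`` is a viscous coefficient per
    joint (N*m*s). Newton-Euler for point masses via explicit link
    kinematics; torque at joint j is the moment of every distal mass's
    inertial+gravity force about joint j's pivot.
    """
    n = 3
    m = np.empty(n)
    for i in range(n):
        m[i] = masses[i]
    m[n - 1] += payload

    theta = np.empty(n)
    omega = np.empty(n)
    alpha = np.empty(n)
    acc = 0.0
    w = 0.0
    a = 0.0
    for i in range(n):
        acc += q[i]
        w += qd[i]
        a += qdd[i]
        theta[i] = acc
        omega[i] = w
        alpha[i] = a

    # pivot positions and point-mass positions / accelerations
    px = np.empty(n + 1)
    py = np.empty(n + 1)
    px[0] = 0.0
    py[0] = 0.0
    ax = np.empty(n)
    ay = np.empty(n)
    ax_c = 0.0
    ay_c = 0.0
    for i in range(n):
        ct = np.cos(theta[i])
        st = np.sin(theta[i])
        px[i + 1] = px[i] + lengths[i] * ct
        py[i + 1] = py[i] + lengths[i] * st
        ax_c += lengths[i] * (-alpha[i] * st - omega[i] * omega[i] * ct)
        ay_c += lengths[i] * (alpha[i] * ct - omega[i] * omega[i] * st)
        ax[i] = ax_c
        ay[i] = ay_c

    tau = np.zeros(n)
    for j in range(n):
        for k in range(j, n):
            fx = m[k] * ax[k]
            fy = m[k] * (ay[k] + gravity)
            rx = px[k + 1] - px[j]
            ry = py[k + 1] - py[j]
            tau[j] += rx * fy - ry * fx
        tau[j] += friction * qd[j]
    return tau


@njit(cache=True)
def _arm_mass_matrix(q, lengths, masses, payload):
    zero = np.zeros(3)
    g0 = arm_inverse_dynamics(q, zero, zero, lengths, masses, payload, 0.0, 0.0)
    mm = np.empty((3, 3))
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        col = arm_inverse_dynamics(q, zero, e, lengths, masses, payload, 0.0, 0.0)
        for r in range(3):
            mm[r, i] = col[r] - g0[r]
    return mm


@njit(cache=True)
def arm_forward_step(q, qd, torque, lengths, masses, payload, gravity, friction, dt, n_sub):
    """Semi-implicit Euler forward dynamics over one clock step.

    Solves ``M(q) qdd = torque - h(q, qd)`` (``h`` = Coriolis + gravity +
    friction, obtained as inverse dynamics at zero acceleration) on each of
    ``n_sub`` substeps; velocity is updated before position. Returns 1 on
    numerical blow-up, else 0. ``q``/``qd`` are updated in place.
    """
    zero3 = np.zeros(3)
    return arm_forward_step_servo(
        q, qd, torque, lengths, masses, payload, gravity, friction,
        zero3, zero3, zero3, zero3, dt, n_sub,
    )


@njit(cache=True)
def arm_forward_step_servo(
    q, qd, torque, lengths, masses, payload, gravity, friction,
    kp, kd, q_des, qd_des, dt, n_sub,
):
    """Forward dynamics with the joint servo evaluated at substep rate.

    The low-level stiffness/damping controller of the robot runs far
    faster than the 2 ms network clock; evaluating it against the held
    clock-rate state would introduce an artificial zero-order-hold limit
    cycle, so its torque ``kp (q_des - q) + kd (qd_des - qd)`` is
    recomputed on every substep. ``torque`` holds the clock-rate part
    (feed-forward plus cerebellar correction).
    """
    h_sub = dt / n_sub
    zero = np.zeros(3)
    tau = np.empty(3)
    for _ in range(n_sub):
        for i in range(3):
            tau[i] = torque[i] + kp[i] * (q_des[i] - q[i]) + kd[i] * (qd_des[i] - qd[i])
        bias = arm_inverse_dynamics(q, qd, zero, lengths, masses, payload, gravity, friction)
        mm = _arm_mass_matrix(q, lengths, masses, payload)
        qdd = np.linalg.solve(mm, tau - bias)
        for i in range(3):
            qd[i] += qdd[i] * h_sub
            q[i] += qd[i] * h_sub
            if not np.isfinite(q[i]) or abs(qd[i]) > 1e4:
                return 1
    return 0


@njit(cache=True)
def arm_energy(q, qd, lengths, masses, payload, gravity):
    """Total mechanical energy (kinetic + potential) of the chain."""
    n = 3
    m = np.empty(n)
    for i in range(n):
        m[i] = masses[i]
    m[n - 1] += payload
    theta = 0.0
    omega = 0.0
    x = 0.0
    y = 0.0
    vx = 0.0
    vy = 0.0
    e = 0.0
    for i in range(n):
        theta += q[i]
        omega += qd[i]
        x += lengths[i] * np.cos(theta)
        y += lengths[i] * np.sin(theta)
        vx += lengths[i] * (-np.sin(theta)) * omega
        vy += lengths[i] * np.cos(theta) * omega
        e += 0.5 * m[i] * (vx * vx + vy * vy) + m[i] * gravity * y
    return e
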