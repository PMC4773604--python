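"""Jitted closed-loop trial kernel shared by Case A and Case B.

One call advances the whole loop by one 1 s trial (500 clock steps of
2 ms): state-generator spikes -> PC/DCN LIF integration -> exponential
decoding of DCN output -> plant (Case B) -> delayed error -> probabilistic
CF encoding -> the three plasticity rules. Neuron state, traces and the
delay line are freshly reset each trial; synaptic weights persist across
calls and are updated in place.

The granule/mossy schedules are deterministic, which lets the MF-DCN LTD
window (a two-sided kernel over MF spikes around each PC spike) be folded
into a precomputed per-step kernel table ``kmf``; the per-event reference
implementations in :mod:`cereblearn.plasticity` define the semantics and
the test-suite checks this engine against them on short runs.
"""

import numpy as np
from numba import njit

from ._fast import arm_forward_step_servo, lif_step

__all__ = ["run_trial"]


@njit(cache=True)
def run_trial(
    # plastic weights (updated in place)
    w_pfpc, w_mfdcn, w_pcdcn,
    # schedules
    gc_sched, mf_ids, mf_fire, kmf,
    # targets: Case A -> ref (n_steps, 1); Case B -> desired joint angles
    ref, ref_d, vel_weight,
    # Case B feed-forward torques (n_steps, n_joints); ignored for Case A
    tau_ff, use_plant,
    lengths, masses, payload, gravity, friction, plant_sub,
    servo_kp, servo_kd, q0, qd0,
    # random stream for the CF encoder, (n_steps, n_cf)
    u_cf,
    # LIF parameter tuples (pc then dcn)
    pc_par, dcn_par,
    dt, n_sub,
    w_cf,
    # decoder
    dec_decay, dec_gain,
    # error pathway
    delay_steps, err_norm, p_cf_max,
    # PF-PC rule
    en_pfpc, alpha_pfpc, ltd_scale_pfpc, w_max_pfpc, ltd_kern,
    # MF-DCN rule
    en_mfdcn, alpha_mfdcn, ltd_scale_mfdcn, w_max_mfdcn,
    # PC-DCN rule
    en_pcdcn, pcdcn_kind, hebb_scale, hebb_tau1, hebb_tau2,
    sym_ltp, sym_ltd, sym_kern,
    # outputs
    y_rec, cf_count, pc_sp_mat, dcn_sp_mat,
):
    n_steps = gc_sched.shape[0]
    n_gc, n_pc = w_pfpc.shape
    n_mf, n_dcn = w_mfdcn.shape
    n_cf = n_dcn
    n_joints = ref.shape[1]
    n_per = n_pc // n_dcn  # PCs per microcomplex

    # fresh neuron / trace / loop state
    v_pc = np.full(n_pc, pc_par[2])
    ge_pc = np.zeros(n_pc)
    gi_pc = np.zeros(n_pc)
    rf_pc = np.full(n_pc, -1.0e9)
    v_dcn = np.full(n_dcn, dcn_par[2])
    ge_dcn = np.zeros(n_dcn)
    gi_dcn = np.zeros(n_dcn)
    rf_dcn = np.full(n_dcn, -1.0e9)
    sp_pc = np.zeros(n_pc, dtype=np.int64)
    sp_dcn = np.zeros(n_dcn, dtype=np.int64)
    prev_pc = np.zeros(n_pc, dtype=np.int64)
    prev_cf = np.zeros(n_cf, dtype=np.int64)
    y_dec = np.zeros(n_dcn)
    dbuf = np.zeros((delay_steps, n_joints))
    dptr = 0
    last_pc = np.full(n_pc, -(10**9), dtype=np.int64)
    last_dcn = np.full(n_dcn, -(10**9), dtype=np.int64)
    exc_pc = np.zeros(n_pc)
    inh_pc = np.zeros(n_pc)
    exc_dcn = np.zeros(n_dcn)
    inh_dcn = np.zeros(n_dcn)
    cf_now = np.zeros(n_cf, dtype=np.int64)
    grp_cnt = np.zeros(n_dcn, dtype=np.int64)
    q = q0.copy()
    qd = qd0.copy()
    torque = np.zeros(n_joints)
    err = np.zeros(n_joints)
    mae = np.zeros(n_joints)
    w_ltd = ltd_kern.shape[0] - 1
    w_sym = sym_kern.shape[0] - 1
    for c in range(n_cf):
        cf_count[c] = 0

    for s in range(n_steps):
        t = s * dt
        # --- synaptic drive assembled from last step's spikes/schedules
        for p in range(n_pc):
            exc_pc[p] = 0.0
            inh_pc[p] = 0.0
        for a in range(gc_sched.shape[1]):
            g = gc_sched[s, a]
            for p in range(n_pc):
                exc_pc[p] += w_pfpc[g, p]
        for c in range(n_cf):
            if prev_cf[c]:
                for p in range(c * n_per, (c + 1) * n_per):
                    exc_pc[p] += w_cf
        for d in range(n_dcn):
            exc_dcn[d] = 0.0
            inh_dcn[d] = 0.0
        if mf_fire[s]:
            for a in range(mf_ids.shape[1]):
                j = mf_ids[s, a]
                for d in range(n_dcn):
                    exc_dcn[d] += w_mfdcn[j, d]
        for p in range(n_pc):
            if prev_pc[p]:
                inh_dcn[p // n_per] += w_pcdcn[p] * prev_pc[p]

        # --- integrate membrane dynamics
        bad = lif_step(
            v_pc, ge_pc, gi_pc, rf_pc, exc_pc, inh_pc, t, dt, n_sub,
            pc_par[0], pc_par[1], pc_par[2], pc_par[3], pc_par[4],
            pc_par[5], pc_par[6], pc_par[7], pc_par[8], pc_par[9],
            sp_pc,
        )
        bad += lif_step(
            v_dcn, ge_dcn, gi_dcn, rf_dcn, exc_dcn, inh_dcn, t, dt, n_sub,
            dcn_par[0], dcn_par[1], dcn_par[2], dcn_par[3], dcn_par[4],
            dcn_par[5], dcn_par[6], dcn_par[7], dcn_par[8], dcn_par[9],
            sp_dcn,
        )
        if bad:
            return -(s + 1)  # caller raises with the step index

        for p in range(n_pc):
            pc_sp_mat[s, p] = sp_pc[p]
        for d in range(n_dcn):
            dcn_sp_mat[s, d] = sp_dcn[d]

        # --- decode DCN output; agonist minus antagonist per joint
        for d in range(n_dcn):
            y_dec[d] = dec_decay * y_dec[d] + dec_gain[d] * sp_dcn[d]
        for j in range(n_joints):
            y_rec[s, j] = y_dec[2 * j] - y_dec[2 * j + 1]

        # --- plant / error
        if use_plant:
            for j in range(n_joints):
                torque[j] = tau_ff[s, j] + y_rec[s, j]
            blow = arm_forward_step_servo(
                q, qd, torque, lengths, masses, payload, gravity, friction,
                servo_kp, servo_kd, ref[s], ref_d[s],
                dt, plant_sub,
            )
            if blow:
                return -(s + 1)
            for j in range(n_joints):
                err[j] = ref[s, j] - q[j] + vel_weight * (ref_d[s, j] - qd[j])
        else:
            for j in range(n_joints):
                err[j] = ref[s, j] - y_rec[s, j]
        for j in range(n_joints):
            mae[j] += abs(ref[s, j] - q[j]) if use_plant else abs(err[j])

        # --- sensorimotor delay then probabilistic CF encoding
        for c in range(n_cf):
            j = c // 2
            e_d = dbuf[dptr, j]
            eps = e_d / err_norm[j] if c % 2 == 0 else -e_d / err_norm[j]
            if eps < 0.0:
                eps = 0.0
            elif eps > 1.0:
                eps = 1.0
            cf_now[c] = 1 if u_cf[s, c] < eps * p_cf_max else 0
            if cf_now[c]:
                cf_count[c] += 1
        for j in range(n_joints):
            dbuf[dptr, j] = err[j]
        dptr += 1
        if dptr == delay_steps:
            dptr = 0

        # --- PF-PC plasticity
        if en_pfpc:
            for a in range(gc_sched.shape[1]):
                g = gc_sched[s, a]
                for p in range(n_pc):
                    w = w_pfpc[g, p] + alpha_pfpc
                    w_pfpc[g, p] = w if w < w_max_pfpc else w_max_pfpc
            for c in range(n_cf):
                if cf_now[c]:
                    for k in range(1, w_ltd + 1):
                        s2 = s - k
                        if s2 < 0:
                            break
                        dec = ltd_scale_pfpc * ltd_kern[k]
                        if dec == 0.0:
                            continue
                        for a in range(gc_sched.shape[1]):
                            g = gc_sched[s2, a]
                            for p in range(c * n_per, (c + 1) * n_per):
                                w = w_pfpc[g, p] - dec
                                w_pfpc[g, p] = w if w > 0.0 else 0.0

        # --- MF-DCN plasticity
        if en_mfdcn:
            if mf_fire[s]:
                for a in range(mf_ids.shape[1]):
                    jmf = mf_ids[s, a]
                    for d in range(n_dcn):
                        w = w_mfdcn[jmf, d] + alpha_mfdcn
                        w_mfdcn[jmf, d] = w if w < w_max_mfdcn else w_max_mfdcn
            for d in range(n_dcn):
                grp_cnt[d] = 0
            for p in range(n_pc):
                if sp_pc[p]:
                    grp_cnt[p // n_per] += sp_pc[p]
            for d in range(n_dcn):
                if grp_cnt[d]:
                    f = ltd_scale_mfdcn * grp_cnt[d]
                    for jmf in range(n_mf):
                        w = w_mfdcn[jmf, d] - f * kmf[s, jmf]
                        w_mfdcn[jmf, d] = w if w > 0.0 else 0.0

        # --- PC-DCN plasticity
        if en_pcdcn:
            if pcdcn_kind == 0:  # Hebbian pair rule, nearest neighbour
                for p in range(n_pc):
                    if sp_pc[p]:
                        last_pc[p] = s
                for d in range(n_dcn):
                    if sp_dcn[d]:
                        for p in range(d * n_per, (d + 1) * n_per):
                            dk = s - last_pc[p]
                            if dk * dt <= hebb_tau1 * 20.0:
                                w_pcdcn[p] += hebb_scale * np.exp(-dk * dt / hebb_tau1)
                for p in range(n_pc):
                    if sp_pc[p]:
                        d = p // n_per
                        dk = s - last_dcn[d]
                        if dk > 0 and dk * dt <= hebb_tau2 * 20.0:
                            w = w_pcdcn[p] - hebb_scale * np.exp(-dk * dt / hebb_tau2)
                            w_pcdcn[p] = w if w > 0.0 else 0.0
                for d in range(n_dcn):
                    if sp_dcn[d]:
                        last_dcn[d] = s
            else:  # symmetric: per-pre depression + coincidence LTP
                for p in range(n_pc):
                    if sp_pc[p]:
                        d = p // n_per
                        dw = -sym_ltd
                        dw += sym_ltp * sym_kern[0] * sp_dcn[d]
                        for k in range(1, w_sym + 1):
                            s2 = s - k
                            if s2 < 0:
                                break
                            if dcn_sp_mat[s2, d]:
                                dw += sym_ltp * sym_kern[k] * dcn_sp_mat[s2, d]
                        w = w_pcdcn[p] + dw * sp_pc[p]
                        w_pcdcn[p] = w if w > 0.0 else 0.0
                for d in range(n_dcn):
                    if sp_dcn[d]:
                        for p in range(d * n_per, (d + 1) * n_per):
                            dw = 0.0
                            for k in range(1, w_sym + 1):
                                s2 = s - k
                                if s2 < 0:
                                    break
                                if pc_sp_mat[s2, p]:
                                    dw += sym_ltp * sym_kern[k] * pc_sp_mat[s2, p]
                            if dw != 0.0:
                                w_pcdcn[p] += dw * sp_dcn[d]

        for p in range(n_pc):
            prev_pc[p] = sp_pc[p]
        for c in range(n_cf):
            prev_cf[c] = cf_now[c]

    total = 0.0
    for j in range(n_joints):
        total += mae[j] / n_steps
    return total / n_joints
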