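"""Transparent single-trial reference implementation of the Case A loop.

This path is assembled step by step from the public module operations
(:func:`step_population`, the per-event plasticity functions, the decoder,
delay line and CF encoder) with no performance tricks. It defines the
semantics the jitted engine must reproduce; the test-suite runs both on
identical inputs and compares weights, spikes and errors.

Slow by design - use only for short runs.
"""

from __future__ import annotations

import numpy as np

from .coding import encode_error, split_error
from .lif import PopulationState, step_population
from .plasticity import (
    mfdcn_deferred_on_mf_spike,
    mfdcn_on_mf_spike,
    mfdcn_on_pc_spike,
    pfpc_on_cf_spike,
    pfpc_on_pf_spike,
    pcdcn_symmetric_on_dcn_spike,
    pcdcn_symmetric_on_pc_spike,
)

__all__ = ["reference_trial"]


def reference_trial(sim, u_cf: np.ndarray):
    """Run one Case A trial on ``sim``'s current weights (updated in place).

    Returns ``(mae, y_rec, pc_spikes, dcn_spikes)``. ``u_cf`` is the
    pre-drawn uniform stream for the CF encoder, shape (n_steps, n_cf).
    """
    cfg = sim.config
    cc = sim.topology.config
    if sim.use_plant:
        raise ValueError("reference loop implements the plant-free case only")
    n_steps = cfg.n_steps
    n_pc, n_dcn, n_cf = cc.n_pc, cc.n_dcn, cc.n_cf
    n_per = n_pc // n_dcn
    dt = cfg.dt

    pc_params = sim.topology.populations["PC"][1]
    dcn_params = sim.topology.populations["DCN"][1]
    pc_state = PopulationState.resting(n_pc, pc_params)
    dcn_state = PopulationState.resting(n_dcn, dcn_params)

    y_dec = np.zeros(n_dcn)
    delay_steps = max(1, int(round(cfg.delay / dt)))
    dbuf = np.zeros(delay_steps)
    dptr = 0
    prev_pc = np.zeros(n_pc, dtype=int)
    prev_cf = np.zeros(n_cf, dtype=int)

    # spike-time logs used as eligibility buffers
    gc_spike_time = np.full(cc.n_gc, -np.inf)  # each GC fires once per trial
    mf_spikes: list[list[float]] = [[] for _ in range(cc.n_mf)]
    pc_spike_times: list[list[float]] = [[] for _ in range(n_pc)]
    dcn_spike_times: list[list[float]] = [[] for _ in range(n_dcn)]
    last_pc = np.full(n_pc, -np.inf)
    last_dcn = np.full(n_dcn, -np.inf)

    y_rec = np.zeros(n_steps)
    pc_mat = np.zeros((n_steps, n_pc), dtype=int)
    dcn_mat = np.zeros((n_steps, n_dcn), dtype=int)
    mae = 0.0
    hebb = cfg.pcdcn.kernel_choice == "hebbian"

    for s in range(n_steps):
        t = s * dt
        active_gcs = sim.gc_sched[s]
        mf_now = sim.mf_ids[s] if sim.mf_fire[s] else np.empty(0, dtype=int)

        exc_pc = sim.w_pfpc[active_gcs].sum(axis=0)
        for c in np.flatnonzero(prev_cf):
            exc_pc[c * n_per:(c + 1) * n_per] += cc.cfpc_weight
        exc_dcn = sim.w_mfdcn[mf_now].sum(axis=0) if mf_now.size else np.zeros(n_dcn)
        inh_dcn = np.zeros(n_dcn)
        for p in np.flatnonzero(prev_pc):
            inh_dcn[p // n_per] += sim.w_pcdcn[p] * prev_pc[p]

        _, pc_events = step_population(
            pc_state, pc_params, dt, exc_pc, None, t, cfg.n_substeps
        )
        _, dcn_events = step_population(
            dcn_state, dcn_params, dt, exc_dcn, inh_dcn, t, cfg.n_substeps
        )
        sp_pc = np.zeros(n_pc, dtype=int)
        for ev in pc_events:
            sp_pc[ev.neuron_id] += 1
        sp_dcn = np.zeros(n_dcn, dtype=int)
        for ev in dcn_events:
            sp_dcn[ev.neuron_id] += 1
        pc_mat[s] = sp_pc
        dcn_mat[s] = sp_dcn

        y_dec = sim.dec_decay * y_dec + sim.dec_gain * sp_dcn
        y = y_dec[0] - y_dec[1]
        y_rec[s] = y
        err = float(sim.ref[s, 0]) - y
        mae += abs(err)

        e_delayed = dbuf[dptr]
        dbuf[dptr] = err
        dptr = (dptr + 1) % delay_steps
        eps_pos, eps_neg = split_error(e_delayed, cfg.error_norm[0])
        cf_now = np.array(
            [
                int(encode_error(e, dt, cfg.r_max_hz, u=u_cf[s, c]))
                for c, e in enumerate((eps_pos, eps_neg))
            ]
        )

        # eligibility bookkeeping for this step's presynaptic spikes
        gc_spike_time[active_gcs] = t
        for j in mf_now:
            mf_spikes[j].append(t)

        if cfg.enable_pfpc:
            sim.w_pfpc[active_gcs, :] = np.minimum(
                sim.w_pfpc[active_gcs, :] + pfpc_on_pf_spike(cfg.pfpc),
                cfg.pfpc.w_max,
            )
            for c in np.flatnonzero(cf_now):
                buffers = [
                    [gc_spike_time[g]]
                    if t - gc_spike_time[g] <= cfg.pfpc.truncation_window
                    else []
                    for g in range(cc.n_gc)
                ]
                dw = pfpc_on_cf_spike(buffers, t, cfg.pfpc)
                cols = slice(c * n_per, (c + 1) * n_per)
                sim.w_pfpc[:, cols] = np.maximum(
                    sim.w_pfpc[:, cols] + dw[:, None], 0.0
                )

        if cfg.enable_mfdcn:
            if mf_now.size:
                sim.w_mfdcn[mf_now, :] = np.minimum(
                    sim.w_mfdcn[mf_now, :] + mfdcn_on_mf_spike(cfg.mfdcn),
                    cfg.mfdcn.w_max,
                )
                for j in mf_now:
                    for d in range(n_dcn):
                        dw = mfdcn_deferred_on_mf_spike(
                            [tt for tt in pc_spike_buffer_times(pc_spike_times, d, n_per)],
                            t, cfg.mfdcn,
                        )
                        sim.w_mfdcn[j, d] = max(sim.w_mfdcn[j, d] + dw, 0.0)
            for p in np.flatnonzero(sp_pc):
                d = p // n_per
                # past MF spikes only; the future half arrives deferred
                bufs = [
                    [tt for tt in mf_spikes[j] if t - tt <= cfg.mfdcn.truncation_window]
                    for j in range(cc.n_mf)
                ]
                dw = mfdcn_on_pc_spike(bufs, t, cfg.mfdcn) * sp_pc[p]
                sim.w_mfdcn[:, d] = np.maximum(sim.w_mfdcn[:, d] + dw, 0.0)

        if cfg.enable_pcdcn:
            if hebb:
                for p in np.flatnonzero(sp_pc):
                    last_pc[p] = t
                for d in np.flatnonzero(sp_dcn):
                    for p in range(d * n_per, (d + 1) * n_per):
                        dtau = t - last_pc[p]
                        if dtau <= cfg.pcdcn.tau1 * 20.0:
                            sim.w_pcdcn[p] += cfg.pcdcn.scale * np.exp(
                                -dtau / cfg.pcdcn.tau1
                            )
                for p in np.flatnonzero(sp_pc):
                    d = p // n_per
                    dtau = t - last_dcn[d]
                    if 0.0 < dtau <= cfg.pcdcn.tau2 * 20.0:
                        sim.w_pcdcn[p] = max(
                            sim.w_pcdcn[p]
                            - cfg.pcdcn.scale * np.exp(-dtau / cfg.pcdcn.tau2),
                            0.0,
                        )
                for d in np.flatnonzero(sp_dcn):
                    last_dcn[d] = t
            else:
                for p in np.flatnonzero(sp_pc):
                    d = p // n_per
                    posts = list(dcn_spike_times[d]) + [t] * sp_dcn[d]
                    dw = sp_pc[p] * pcdcn_symmetric_on_pc_spike(posts, t, cfg.pcdcn)
                    sim.w_pcdcn[p] = max(sim.w_pcdcn[p] + dw, 0.0)
                for d in np.flatnonzero(sp_dcn):
                    for p in range(d * n_per, (d + 1) * n_per):
                        dw = sp_dcn[d] * pcdcn_symmetric_on_dcn_spike(
                            pc_spike_times[p], t, cfg.pcdcn
                        )
                        sim.w_pcdcn[p] += dw

            for p in np.flatnonzero(sp_pc):
                pc_spike_times[p].extend([t] * sp_pc[p])
            for d in np.flatnonzero(sp_dcn):
                dcn_spike_times[d].extend([t] * sp_dcn[d])
        else:
            for p in np.flatnonzero(sp_pc):
                pc_spike_times[p].extend([t] * sp_pc[p])
            for d in np.flatnonzero(sp_dcn):
                dcn_spike_times[d].extend([t] * sp_dcn[d])

        prev_pc = sp_pc
        prev_cf = cf_now

    return mae / n_steps, y_rec, pc_mat, dcn_mat


def pc_spike_buffer_times(pc_spike_times, d, n_per):
    out = []
    for p in range(d * n_per, (d + 1) * n_per):
        out.extend(pc_spike_times[p])
    return out
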