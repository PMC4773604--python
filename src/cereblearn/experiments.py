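"""Canonical experiment configurations and runners.

These functions reproduce the package's headline experiments end to end:
learning consolidation, adaptive gain control, two-timescale convergence,
the inhibitory-kernel comparison, and the robotic manipulation task. Each
returns a plain dict of the quantities the experiment is about, computed
from a fresh simulation.
"""

from __future__ import annotations

import numpy as np

from .analysis import (
    convergence_trial,
    counter_phase_score,
    error_reduction_pct,
    reverse_cross_correlation,
    weight_profile,
)
from .loop import ArmModel, TrajectoryConfig
from .network import CaseConfig, build_network
from .plasticity import (
    PCDCNRuleConfig,
    PFPCRuleConfig,
    calibrate_tau_ltd,
    normalize_istdp_rates,
)
from .runner import RunConfig, Simulation

__all__ = [
    "case_a_config",
    "case_b_config",
    "consolidation_experiment",
    "gain_control_experiment",
    "kernel_comparison_experiment",
    "manipulation_experiment",
]

# the two candidate nuclear kernels at the package's reference constants
HEBBIAN = PCDCNRuleConfig(kernel_choice="hebbian", tau1=0.020, tau2=0.015, scale=0.01)
SYMMETRIC = PCDCNRuleConfig(
    kernel_choice="symmetric", sigma=0.020, ltp_max=0.025, ltd_max=0.005
)


def case_a_config(**overrides) -> RunConfig:
    """Loop constants of the set-point benchmark."""
    base = RunConfig(output_full_scale=(1.3,), error_norm=(1.0,))
    return base.with_(**overrides)


def case_b_config(payload: float = 6.0, **overrides) -> RunConfig:
    """Loop constants of the manipulation benchmark (substitute arm)."""
    base = RunConfig(
        output_full_scale=(330.0, 220.0, 100.0),
        error_norm=(0.3, 0.3, 0.3),
        velocity_error_weight=0.1,
        arm=ArmModel(payload=payload),
        trajectory=TrajectoryConfig(amplitudes=(0.3, 0.2, 0.15)),
        # teaching eligibility compensates the 100 ms sensorimotor delay
        # plus the ~160 ms torque-to-error response of the servo-held arm
        pfpc=PFPCRuleConfig(tau_ltd=calibrate_tau_ltd(0.26)),
        pcdcn=SYMMETRIC,
    )
    return base.with_(**overrides)


def _gains(table):
    pc = table[["mean_w_pcdcn_pos", "mean_w_pcdcn_neg"]].mean(axis=1).values
    mf = table[["mean_w_mfdcn_pos", "mean_w_mfdcn_neg"]].mean(axis=1).values
    return pc, mf


def consolidation_experiment(seed: int, trials: int = 2500) -> dict:
    """Case A with PF-PC and MF-DCN learning; PC-DCN frozen pre-calculated.

    Returns trial-1 and final MAE plus the per-microcomplex counter-phase
    score between the learned PF-PC and MF-DCN weight profiles.
    """
    topo = build_network(CaseConfig(case="A", pcdcn_init_mode="fixed"), seed=seed)
    sim = Simulation(topo, case_a_config(enable_pcdcn=False), seed=seed)
    log = sim.run(trials)
    scores = []
    for m in range(2):
        pf = weight_profile(sim.w_pfpc, sim.gc_schedule,
                            columns=range(m * 10, (m + 1) * 10))
        mf = weight_profile(sim.w_mfdcn, sim.mf_schedule, columns=[m])
        scores.append(counter_phase_score(pf, mf))
    return {
        "mae_first": float(log.table.mae.iloc[0]),
        "mae_final": float(log.table.mae.iloc[-100:].mean()),
        "counter_phase": scores,
        "log": log,
        "sim": sim,
    }


def gain_control_experiment(seed: int, init: str, trials: int = 5000) -> dict:
    """Case A with all three rules (symmetric nuclear kernel), PC-DCN
    weights started from ``init`` in {'zero','random','high'}."""
    topo = build_network(
        CaseConfig(case="A", pcdcn_init_mode=init, pcdcn_high_weight=10.0), seed=seed
    )
    sim = Simulation(topo, case_a_config(pcdcn=SYMMETRIC), seed=seed)
    log = sim.run(trials)
    pc, mf = _gains(log.table)
    return {
        "final_pcdcn_gain": float(pc[-500:].mean()),
        "conv_pfpc": convergence_trial(log.table.mean_w_pfpc.values),
        "conv_mfdcn": convergence_trial(mf),
        "conv_pcdcn": convergence_trial(pc),
        "mae_final": float(log.table.mae.iloc[-100:].mean()),
        "log": log,
    }


def kernel_comparison_experiment(seed: int, kernel: str, trials: int = 5000) -> dict:
    """Case A from zero nuclear weights with one iSTDP kernel, the two
    kernels normalized to equal mean |dW| on a common calibration train.

    Reports the early-phase gain advance (mean averaged gain over the
    first 1000 trials), the final-trial reverse-correlation summary, and
    the plateau variance of the gain series.
    """
    hebb, sym, _ = normalize_istdp_rates(
        HEBBIAN, SYMMETRIC, np.random.default_rng(7)
    )
    pcdcn = hebb if kernel == "hebbian" else sym
    topo = build_network(CaseConfig(case="A", pcdcn_init_mode="zero"), seed=seed)
    sim = Simulation(topo, case_a_config(pcdcn=pcdcn), seed=seed)
    log = sim.run(trials, record_trials=[trials - 1])
    pc, _ = _gains(log.table)
    pc_mat, dcn_mat = log.spikes[trials - 1]
    rs = []
    for m in range(2):
        pct = np.flatnonzero(pc_mat[:, m * 10:(m + 1) * 10].sum(1)) * 0.002
        dct = np.flatnonzero(dcn_mat[:, m]) * 0.002
        if len(pct) and len(dct):
            rs.append(reverse_cross_correlation(pct, dct).summary)
    return {
        "early_gain": float(pc[:1000].mean()),
        "reverse_correlation": float(np.mean(rs)),
        "plateau_variance": float(np.var(pc[-500:])),
        "final_gain": float(pc[-500:].mean()),
        "log": log,
    }


def manipulation_experiment(
    seed: int,
    trials: int = 4000,
    payload: float = 6.0,
    baseline_trials: int = 20,
) -> dict:
    """Case B: frozen-cerebellum baseline vs. full distributed learning.

    Returns the baseline MAE (crude controller + joint servo only), the
    final learned MAE, and the error-reduction percentage.
    """
    cfg = case_b_config(payload=payload)
    topo0 = build_network(CaseConfig(case="B", pcdcn_init_mode="zero"), seed=seed)
    frozen = Simulation(
        topo0,
        cfg.with_(enable_pfpc=False, enable_mfdcn=False, enable_pcdcn=False),
        seed=seed,
    )
    base_log = frozen.run(baseline_trials)
    baseline = float(base_log.table.mae.mean())

    topo = build_network(CaseConfig(case="B", pcdcn_init_mode="zero"), seed=seed)
    sim = Simulation(topo, cfg, seed=seed)
    log = sim.run(trials)
    series = np.concatenate([base_log.table.mae.values, log.table.mae.values])
    final = float(log.table.mae.iloc[-200:].mean())
    return {
        "baseline_mae": baseline,
        "final_mae": final,
        "reduction_pct": error_reduction_pct(
            series, (0, baseline_trials), (len(series) - 200, len(series))
        ),
        "log": log,
    }
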