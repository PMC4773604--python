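"""Experiment orchestration: configure, run and log closed-loop trials.

:class:`Simulation` owns a built network topology plus a :class:`RunConfig`
and repeatedly calls the jitted trial kernel, collecting a per-trial log
(mean absolute error, averaged gains per projection, CF spike counts) and,
on request, spike rasters, decoded outputs and weight snapshots for
selected trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine
from .coding import build_state_schedule
from .loop import (
    ArmModel,
    ReferenceCurveConfig,
    TrajectoryConfig,
    calibrate_decoder_gain,
    crude_inverse_dynamics,
    desired_joint_state,
    reference_variable,
)
from .network import PC_PER_MICROCOMPLEX, NetworkTopology
from .plasticity import MFDCNRuleConfig, PCDCNRuleConfig, PFPCRuleConfig, mfdcn_kernel

__all__ = ["RunConfig", "Simulation", "TrialLog"]


@dataclass(frozen=True)
class RunConfig:
    """All loop-level constants of one experiment."""

    dt: float = 0.002  # s, clock step
    trial_duration: float = 1.0  # s
    delay: float = 0.100  # s, sensorimotor delay on the error pathway
    r_max_hz: float = 10.0  # CF rate cap
    mf_rate_hz: float = 100.0  # MF comb rate inside the active window
    n_substeps: int = 10
    plant_substeps: int = 10
    decoder_tau_taps: float = 16.0
    max_dcn_rate_hz: float = 250.0  # rate mapped to full-scale output
    output_full_scale: tuple = (1.3,)  # per joint, output units (Nm for Case B)
    error_norm: tuple = (1.0,)  # per joint, raw-error units mapped to eps=1
    velocity_error_weight: float = 0.0  # s; phase-lead term on the taught error
    # low-level joint servo of the robot plant (Case B): the arm always runs
    # under this stiffness/damping (evaluated at substep rate), with and
    # without cerebellar correction; near-critically damped for the loaded arm
    servo_kp: tuple = (400.0, 250.0, 80.0)  # N*m/rad
    servo_kd: tuple = (120.0, 64.0, 13.0)  # N*m*s/rad
    enable_pfpc: bool = True
    enable_mfdcn: bool = True
    enable_pcdcn: bool = True
    pfpc: PFPCRuleConfig = field(default_factory=PFPCRuleConfig)
    mfdcn: MFDCNRuleConfig = field(default_factory=MFDCNRuleConfig)
    pcdcn: PCDCNRuleConfig = field(default_factory=PCDCNRuleConfig)
    reference: ReferenceCurveConfig = field(default_factory=ReferenceCurveConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    arm: ArmModel = field(default_factory=lambda: ArmModel(payload=6.0))

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.dt))


@dataclass
class TrialLog:
    """Per-trial metrics plus optional per-trial extras."""

    table: pd.DataFrame
    gains: dict  # name -> (n_trials, n_microcomplexes) mean-weight arrays
    spikes: dict  # trial -> (pc_mat, dcn_mat) int8 step x neuron
    outputs: dict  # trial -> (n_steps, n_joints) decoded output
    snapshots: dict  # trial -> {projection: weight matrix copy}


def _lif_tuple(p):
    return (
        p.membrane_capacitance, p.leak_conductance, p.resting_potential,
        p.threshold, p.reset_potential, p.refractory_period,
        p.excitatory_reversal, p.inhibitory_reversal, p.tau_exc, p.tau_inh,
    )


class Simulation:
    """Closed-loop simulation of one case study on one topology."""

    def __init__(self, topology: NetworkTopology, config: RunConfig, seed: int = 0):
        self.topology = topology
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        cc = topology.config
        n_steps = config.n_steps
        self.n_joints = cc.n_joints
        if len(config.output_full_scale) != self.n_joints:
            raise ValueError("output_full_scale must have one entry per joint")
        if len(config.error_norm) != self.n_joints:
            raise ValueError("error_norm must have one entry per joint")

        # deterministic state schedules
        gc_sched_obj = build_state_schedule(cc.n_gc, 4, config.trial_duration, config.dt)
        mf_sched_obj = build_state_schedule(cc.n_mf, 4, config.trial_duration, config.dt)
        self.gc_schedule = gc_sched_obj
        self.mf_schedule = mf_sched_obj
        gc_span = n_steps // gc_sched_obj.n_states
        mf_span = n_steps // mf_sched_obj.n_states
        self.gc_sched = np.ascontiguousarray(
            gc_sched_obj.assignment[np.arange(n_steps) // gc_span]
        )
        self.mf_ids = np.ascontiguousarray(
            mf_sched_obj.assignment[np.arange(n_steps) // mf_span]
        )
        period = max(1, int(round(1.0 / (config.mf_rate_hz * config.dt))))
        self.mf_fire = (np.arange(n_steps) % period == 0).astype(np.uint8)

        # two-sided MF-spike kernel table for MF-DCN LTD
        w_mf = int(round(config.mfdcn.truncation_window / config.dt))
        kmf = np.zeros((n_steps, cc.n_mf))
        fire_steps = np.flatnonzero(self.mf_fire)
        for s2 in fire_steps:
            lo, hi = max(0, s2 - w_mf), min(n_steps, s2 + w_mf + 1)
            lags = (s2 - np.arange(lo, hi)) * config.dt
            vals = mfdcn_kernel(lags / config.mfdcn.sigma, config.mfdcn.beta)
            for a in self.mf_ids[s2]:
                kmf[lo:hi, a] += vals
        self.kmf = kmf

        # eligibility kernels tabulated per integer step lag
        w_ltd = int(round(config.pfpc.truncation_window / config.dt))
        lags = np.arange(w_ltd + 1) * config.dt
        from .plasticity import pfpc_ltd_kernel

        self.ltd_kern = pfpc_ltd_kernel(lags / config.pfpc.tau_ltd)
        w_sym = int(round(config.pcdcn.truncation_window / config.dt))
        u = np.arange(w_sym + 1) * config.dt / config.pcdcn.sigma
        self.sym_kern = np.exp(-np.abs(u)) * np.cos(u) ** 2

        # targets and feed-forward commands
        tgrid = np.arange(n_steps) * config.dt
        if cc.case == "A":
            self.ref = reference_variable(tgrid, config.reference)[:, None]
            self.ref_d = np.zeros((n_steps, 1))
            self.tau_ff = np.zeros((n_steps, 1))
            self.q0 = np.zeros(3)
            self.qd0 = np.zeros(3)
            self.use_plant = 0
        else:
            qdes, qddes, qdddes = desired_joint_state(tgrid, config.trajectory)
            self.ref = np.ascontiguousarray(qdes)
            self.ref_d = np.ascontiguousarray(qddes)
            self.tau_ff = np.stack(
                [crude_inverse_dynamics(qdes[s], qddes[s], qdddes[s], config.arm)
                 for s in range(n_steps)]
            )
            self.q0 = qdes[0].copy()
            self.qd0 = qddes[0].copy()
            self.use_plant = 1

        # decoder gains per DCN channel (both channels of a joint share one)
        gains = [
            calibrate_decoder_gain(
                config.output_full_scale[d // 2], config.max_dcn_rate_hz,
                config.decoder_tau_taps, config.dt,
            )
            for d in range(cc.n_dcn)
        ]
        self.dec_gain = np.asarray(gains)
        self.dec_decay = float(np.exp(-1.0 / config.decoder_tau_taps))

        self.pc_par = _lif_tuple(topology.populations["PC"][1])
        self.dcn_par = _lif_tuple(topology.populations["DCN"][1])

        # live weight matrices (views of the learning state)
        self.w_pfpc = topology.projections["GC->PC"].as_matrix(cc.n_gc, cc.n_pc)
        self.w_mfdcn = topology.projections["MF->DCN"].as_matrix(cc.n_mf, cc.n_dcn)
        self.w_pcdcn = topology.projections["PC->DCN"].weights.astype(float).copy()
        self.trials_done = 0

        arm = config.arm
        self._arm_arrays = (
            np.asarray(arm.lengths, float), np.asarray(arm.masses, float),
        )

    # ------------------------------------------------------------------
    def run_trial(self, u_cf: np.ndarray | None = None):
        """One trial; returns (mae, cf_counts, pc_mat, dcn_mat, y_rec).

        ``u_cf`` optionally injects the CF encoder's uniform stream (used by
        the engine-equivalence tests); by default it is drawn from the
        simulation's seeded generator.
        """
        cfg = self.config
        cc = self.topology.config
        n_steps = cfg.n_steps
        if u_cf is None:
            u_cf = self.rng.random((n_steps, cc.n_cf))
        y_rec = np.zeros((n_steps, self.n_joints))
        cf_count = np.zeros(cc.n_cf, dtype=np.int64)
        pc_mat = np.zeros((n_steps, cc.n_pc), dtype=np.int8)
        dcn_mat = np.zeros((n_steps, cc.n_dcn), dtype=np.int8)
        lengths, masses = self._arm_arrays
        mae = engine.run_trial(
            self.w_pfpc, self.w_mfdcn, self.w_pcdcn,
            self.gc_sched, self.mf_ids, self.mf_fire, self.kmf,
            self.ref, self.ref_d, cfg.velocity_error_weight,
            self.tau_ff, self.use_plant,
            lengths, masses, cfg.arm.payload, cfg.arm.gravity, cfg.arm.friction,
            cfg.plant_substeps,
            np.asarray(cfg.servo_kp, float), np.asarray(cfg.servo_kd, float),
            self.q0, self.qd0,
            u_cf, self.pc_par, self.dcn_par, cfg.dt, cfg.n_substeps,
            cc.cfpc_weight, self.dec_decay, self.dec_gain,
            max(1, int(round(cfg.delay / cfg.dt))),
            np.asarray(cfg.error_norm, float), cfg.r_max_hz * cfg.dt,
            int(cfg.enable_pfpc), cfg.pfpc.alpha_ltp, cfg.pfpc.ltd_scale,
            cfg.pfpc.w_max, self.ltd_kern,
            int(cfg.enable_mfdcn), cfg.mfdcn.alpha_ltp, cfg.mfdcn.ltd_scale,
            cfg.mfdcn.w_max,
            int(cfg.enable_pcdcn),
            0 if cfg.pcdcn.kernel_choice == "hebbian" else 1,
            cfg.pcdcn.scale, cfg.pcdcn.tau1, cfg.pcdcn.tau2,
            cfg.pcdcn.ltp_max, cfg.pcdcn.ltd_max, self.sym_kern,
            y_rec, cf_count, pc_mat, dcn_mat,
        )
        if mae < 0:
            raise RuntimeError(
                f"non-finite loop state at trial {self.trials_done}, "
                f"step {int(-mae) - 1}"
            )
        self.trials_done += 1
        return mae, cf_count, pc_mat, dcn_mat, y_rec

    # ------------------------------------------------------------------
    def run(
        self,
        n_trials: int,
        record_trials=(),
        snapshot_trials=(),
    ) -> TrialLog:
        """Run ``n_trials`` and collect the per-trial log.

        ``record_trials`` / ``snapshot_trials`` are trial indices (0-based,
        relative to this call) whose spike rasters, decoded outputs and
        weight matrices are kept.
        """
        cc = self.topology.config
        record_trials = set(record_trials)
        snapshot_trials = set(snapshot_trials)
        n_mc = cc.n_microcomplexes
        pcs_of = [list(mc.pcs) for mc in self.topology.microcomplexes]
        rows = []
        gains = {
            "pfpc": np.zeros((n_trials, n_mc)),
            "mfdcn": np.zeros((n_trials, n_mc)),
            "pcdcn": np.zeros((n_trials, n_mc)),
        }
        spikes, outputs, snapshots = {}, {}, {}
        for i in range(n_trials):
            mae, cf_count, pc_mat, dcn_mat, y_rec = self.run_trial()
            for m in range(n_mc):
                gains["pfpc"][i, m] = self.w_pfpc[:, pcs_of[m]].mean()
                gains["mfdcn"][i, m] = self.w_mfdcn[:, m].mean()
                gains["pcdcn"][i, m] = self.w_pcdcn[pcs_of[m]].mean()
            rows.append(
                {
                    "trial": i,
                    "mae": mae,
                    "mean_w_pfpc": gains["pfpc"][i].mean(),
                    "mean_w_mfdcn_pos": gains["mfdcn"][i, 0::2].mean(),
                    "mean_w_mfdcn_neg": gains["mfdcn"][i, 1::2].mean(),
                    "mean_w_pcdcn_pos": gains["pcdcn"][i, 0::2].mean(),
                    "mean_w_pcdcn_neg": gains["pcdcn"][i, 1::2].mean(),
                    "cf_spikes": int(cf_count.sum()),
                }
            )
            if i in record_trials:
                spikes[i] = (pc_mat, dcn_mat)
                outputs[i] = y_rec
            if i in snapshot_trials:
                snapshots[i] = {
                    "GC->PC": self.w_pfpc.copy(),
                    "MF->DCN": self.w_mfdcn.copy(),
                    "PC->DCN": self.w_pcdcn.copy(),
                }
        self.sync_topology()
        return TrialLog(
            table=pd.DataFrame(rows), gains=gains,
            spikes=spikes, outputs=outputs, snapshots=snapshots,
        )

    def sync_topology(self) -> None:
        """Write the live weight matrices back into the topology tables."""
        self.topology.projections["GC->PC"].set_from_matrix(self.w_pfpc)
        self.topology.projections["MF->DCN"].set_from_matrix(self.w_mfdcn)
        self.topology.projections["PC->DCN"].weights = self.w_pcdcn.copy()
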