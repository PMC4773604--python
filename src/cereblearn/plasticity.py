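"""Spike-timing-dependent plasticity rules of the distributed cerebellar model.

Four rules are implemented, one excitatory pair at each of the two main
learning sites plus two alternative inhibitory kernels at the nuclear site:

* **PF-PC** (parallel fibre -> Purkinje cell): LTD driven by climbing-fibre
  (teaching) spikes, weighted by an eligibility kernel
  ``k(x) = exp(-x) * sin(x)**20`` that peaks ~100 ms in the past so the rule
  compensates the sensorimotor pathway delay; LTP is a fixed increment per
  presynaptic PF spike.
* **MF-DCN** (mossy fibre -> deep cerebellar nuclei): LTD driven by Purkinje
  spikes, weighted by the symmetric window kernel
  ``k(x) = exp(-|x*beta|) * cos(x)**2``; LTP is a fixed increment per
  presynaptic MF spike.
* **PC-DCN** (inhibitory): either a classical Hebbian exponential STDP pair
  (post-after-pre potentiates the inhibitory weight, pre-after-post
  depresses it), or a symmetric rule in which every presynaptic spike
  depresses and near-coincident pre/post pairs potentiate.

All weight-changing functions return increments; clipping at zero is the
caller's contract (weights are non-negative conductances; inhibition is a
projection property, not a sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PFPCRuleConfig",
    "MFDCNRuleConfig",
    "PCDCNRuleConfig",
    "EligibilityBuffer",
    "pfpc_ltd_kernel",
    "pfpc_on_cf_spike",
    "pfpc_on_pf_spike",
    "mfdcn_kernel",
    "mfdcn_on_pc_spike",
    "mfdcn_on_mf_spike",
    "pcdcn_hebbian",
    "pcdcn_symmetric",
    "pcdcn_symmetric_on_pc_spike",
    "pcdcn_symmetric_on_dcn_spike",
    "calibrate_tau_ltd",
    "ltd_kernel_argmax",
    "normalize_istdp_rates",
]


# --------------------------------------------------------------------------
# kernels


def pfpc_ltd_kernel(x):
    """Eligibility kernel ``k(x) = exp(-x) * sin(x)**20`` for PF-PC LTD.

    Defined for ``x >= 0`` (elapsed time between a PF spike and the later
    teaching spike, in units of ``tau_ltd``); zero for negative arguments.
    The high sine power makes the kernel a narrow bump peaking at
    ``x* = arctan(20) ~ 1.5208`` with a secondary lobe < 5 % of the peak.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, np.exp(-x) * np.sin(x) ** 20, 0.0)
    return out if out.ndim else float(out)


def mfdcn_kernel(x, beta):
    """Window kernel ``k(x) = exp(-|x*beta|) * cos(x)**2`` for MF-DCN LTD.

    Even in ``x`` (MF spikes before and after the triggering PC spike count
    alike); ``beta`` damps the secondary lobes at ``|x| ~ pi``.
    """
    x = np.asarray(x, dtype=float)
    out = np.exp(-np.abs(x * beta)) * np.cos(x) ** 2
    return out if out.ndim else float(out)


def ltd_kernel_argmax() -> float:
    """Location of the main peak of the PF-PC LTD kernel, ``arctan(20)``.

    The stationarity condition of ``exp(-x) sin(x)**20`` is
    ``tan(x) = 20``; the closed form is cross-checked numerically.
    """
    x_closed = float(np.arctan(20.0))
    res = minimize_scalar(
        lambda x: -pfpc_ltd_kernel(x), bounds=(1.0, 2.0), method="bounded",
        options={"xatol": 1e-12},
    )
    assert abs(res.x - x_closed) < 1e-6
    return x_closed


def calibrate_tau_ltd(target_delay: float) -> float:
    """Kernel time constant that places peak depression ``target_delay`` s
    before the teaching spike (100 ms compensates the sensorimotor delay)."""
    if target_delay <= 0:
        raise ValueError("target_delay must be positive")
    return target_delay / ltd_kernel_argmax()


# --------------------------------------------------------------------------
# configs


@dataclass
class PFPCRuleConfig:
    """PF-PC rule constants.

    ``tau_ltd`` is chosen so the eligibility peak sits at the sensorimotor
    delay; ``ltd_scale`` converts kernel mass into nS of depression per
    (PF spike, CF spike) pairing; ``alpha_ltp`` is the fixed LTP increment
    per PF spike.
    """

    tau_ltd: float = field(default_factory=lambda: calibrate_tau_ltd(0.125))
    alpha_ltp: float = 0.004  # nS per PF spike
    ltd_scale: float = 1.0  # nS per unit kernel
    w_max: float = 10.0  # nS, saturation bound of the PF conductance
    truncation_window: float = 0.300  # s of eligibility history kept

    def __post_init__(self):
        if self.tau_ltd <= 0:
            raise ValueError("tau_ltd must be positive")
        if self.alpha_ltp < 0:
            raise ValueError("alpha_ltp must be non-negative")


@dataclass
class MFDCNRuleConfig:
    """MF-DCN rule constants; ``sigma`` is the window width of the cos^2
    kernel (s), ``beta`` the lobe-damping factor."""

    sigma: float = 0.010
    beta: float = 2.0
    alpha_ltp: float = 0.008  # nS per MF spike
    ltd_scale: float = 0.003  # nS per unit kernel per PC spike
    w_max: float = 110.0  # nS, saturation bound of the MF conductance
    truncation_window: float = 0.030

    def __post_init__(self):
        if self.sigma <= 0 or self.beta <= 0:
            raise ValueError("sigma and beta must be positive")


@dataclass
class PCDCNRuleConfig:
    """PC-DCN inhibitory STDP constants for both candidate kernels.

    ``kernel_choice`` selects 'hebbian' (exponential pair rule, time
    constants ``tau1``/``tau2``) or 'symmetric' (coincidence rule with
    window ``sigma``, per-event bounds ``ltp_max`` > ``ltd_max``).
    ``scale`` multiplies the Hebbian pair value into weight units.
    """

    kernel_choice: str = "hebbian"
    tau1: float = 0.020
    tau2: float = 0.020
    sigma: float = 0.020
    ltp_max: float = 0.025
    ltd_max: float = 0.005
    scale: float = 0.02
    truncation_window: float = 0.060

    def __post_init__(self):
        if self.kernel_choice not in ("hebbian", "symmetric"):
            raise ValueError(f"unknown kernel_choice {self.kernel_choice!r}")
        if min(self.tau1, self.tau2, self.sigma) <= 0:
            raise ValueError("time constants must be positive")
        if not (self.ltp_max > self.ltd_max > 0):
            raise ValueError("need ltp_max > ltd_max > 0")


# --------------------------------------------------------------------------
# eligibility trace


class EligibilityBuffer:
    """Time-logged record of recent presynaptic spikes for one synapse.

    Keeps spike times within ``window`` seconds of the most recent ``now``
    passed to :meth:`advance`; appending a future-dated spike relative to
    the buffer clock is allowed (the clock advances to it).
    """

    def __init__(self, window: float):
        if window <= 0:
            raise ValueError("window must be positive")
        self.window = window
        self._times: list[float] = []
        self._now = 0.0

    def append(self, t: float) -> None:
        self._now = max(self._now, t)
        self._times.append(t)
        self._prune()

    def advance(self, now: float) -> None:
        self._now = max(self._now, now)
        self._prune()

    def _prune(self) -> None:
        lo = self._now - self.window
        self._times = [t for t in self._times if t >= lo]

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self._times, dtype=float)

    def __len__(self) -> int:
        return len(self._times)


# --------------------------------------------------------------------------
# PF-PC events


def pfpc_on_cf_spike(buffers, t_cf: float, config: PFPCRuleConfig) -> np.ndarray:
    """LTD at every PF synapse of the PC targeted by a teaching spike.

    ``buffers`` maps PF index -> EligibilityBuffer (or bare array of spike
    times). Returns the (non-positive) weight increment per PF: minus the
    kernel-weighted sum over buffered PF spikes.
    """
    dw = np.zeros(len(buffers))
    for j, buf in enumerate(buffers):
        times = buf.times if isinstance(buf, EligibilityBuffer) else np.asarray(buf, float)
        if times.size == 0:
            continue
        if np.any(times > t_cf):
            raise ValueError("eligibility buffer contains future-dated spikes")
        lags = t_cf - times
        lags = lags[lags <= config.truncation_window]
        dw[j] = -config.ltd_scale * float(np.sum(pfpc_ltd_kernel(lags / config.tau_ltd)))
    return dw


def pfpc_on_pf_spike(config: PFPCRuleConfig) -> float:
    """Fixed LTP increment applied on each presynaptic PF spike."""
    return config.alpha_ltp


# --------------------------------------------------------------------------
# MF-DCN events


def mfdcn_on_pc_spike(mf_buffers, t_pc: float, config: MFDCNRuleConfig) -> np.ndarray:
    """LTD at every MF synapse of the DCN cell hit by a Purkinje spike.

    Sums the (past) MF spikes within the truncation window under the
    symmetric kernel. MF spikes *after* the PC spike contribute the same
    kernel value by symmetry; the event-driven caller realises them by
    invoking :func:`mfdcn_deferred_on_mf_spike` on each later MF spike.
    """
    dw = np.zeros(len(mf_buffers))
    for j, buf in enumerate(mf_buffers):
        times = buf.times if isinstance(buf, EligibilityBuffer) else np.asarray(buf, float)
        if times.size == 0:
            continue
        lags = t_pc - times
        lags = lags[np.abs(lags) <= config.truncation_window]
        dw[j] = -config.ltd_scale * float(
            np.sum(mfdcn_kernel(lags / config.sigma, config.beta))
        )
    return dw


def mfdcn_deferred_on_mf_spike(pc_spike_times, t_mf: float, config: MFDCNRuleConfig) -> float:
    """Deferred LTD contribution of one MF spike against earlier PC spikes
    (the post-``t_pc`` half of the two-sided window)."""
    times = np.asarray(pc_spike_times, float)
    lags = t_mf - times
    lags = lags[(lags > 0) & (lags <= config.truncation_window)]
    return -config.ltd_scale * float(np.sum(mfdcn_kernel(lags / config.sigma, config.beta)))


def mfdcn_on_mf_spike(config: MFDCNRuleConfig) -> float:
    """Fixed LTP increment per presynaptic MF spike (prevents saturation)."""
    return config.alpha_ltp


# --------------------------------------------------------------------------
# PC-DCN events


def pcdcn_hebbian(delta_t, config: PCDCNRuleConfig):
    """Classical inhibitory STDP pair value for ``delta_t = t_post - t_pre``.

    Post-after-pre (``delta_t >= 0``) potentiates the inhibitory weight by
    ``scale * exp(-delta_t/tau1)``; pre-after-post depresses by
    ``scale * exp(-|delta_t|/tau2)``. Coincidence is treated as
    potentiation, consistent with the symmetric kernel's philosophy.
    """
    dt = np.asarray(delta_t, dtype=float)
    out = np.where(
        dt >= 0.0,
        config.scale * np.exp(-dt / config.tau1),
        -config.scale * np.exp(dt / config.tau2),
    )
    return out if out.ndim else float(out)


def pcdcn_symmetric(delta_t, config: PCDCNRuleConfig):
    """Symmetric iSTDP pair value: ``ltp_max * exp(-|u|) cos(u)^2 - ltd_max``
    with ``u = delta_t / sigma``; an unpaired presynaptic spike contributes
    the bare ``-ltd_max`` depression term."""
    u = np.asarray(delta_t, dtype=float) / config.sigma
    out = config.ltp_max * np.exp(-np.abs(u)) * np.cos(u) ** 2 - config.ltd_max
    return out if out.ndim else float(out)


def pcdcn_symmetric_on_pc_spike(dcn_spike_times, t_pc: float, config: PCDCNRuleConfig) -> float:
    """Per-presynaptic-spike update of the symmetric rule: one fixed
    depression plus coincidence LTP over past DCN spikes in the window.
    (LTP against future DCN spikes is added by
    :func:`pcdcn_symmetric_on_dcn_spike`.)"""
    times = np.asarray(dcn_spike_times, float)
    lags = t_pc - times
    lags = lags[(lags >= 0) & (lags <= config.truncation_window)]
    u = lags / config.sigma
    return -config.ltd_max + config.ltp_max * float(
        np.sum(np.exp(-np.abs(u)) * np.cos(u) ** 2)
    )


def pcdcn_symmetric_on_dcn_spike(pc_spike_times, t_dcn: float, config: PCDCNRuleConfig) -> float:
    """Deferred coincidence LTP of the symmetric rule: on a postsynaptic DCN
    spike, potentiate for each strictly earlier PC spike in the window."""
    times = np.asarray(pc_spike_times, float)
    lags = t_dcn - times
    lags = lags[(lags > 0) & (lags <= config.truncation_window)]
    u = lags / config.sigma
    return config.ltp_max * float(np.sum(np.exp(-np.abs(u)) * np.cos(u) ** 2))


# --------------------------------------------------------------------------
# kernel-comparison normalisation


def normalize_istdp_rates(
    hebbian: PCDCNRuleConfig,
    symmetric: PCDCNRuleConfig,
    rng,
    rate_pre: float = 80.0,
    rate_post: float = 40.0,
    duration: float = 20.0,
):
    """Rescale the symmetric rule so both iSTDP kernels produce the same
    mean |dW| per event on a common calibration pair of Poisson trains.

    Returns ``(hebbian, scaled_symmetric, ratio)`` where ``ratio`` is the
    factor applied to the symmetric rule's ``ltp_max``/``ltd_max``. The
    comparison experiments then reflect kernel *shape*, not raw scale.
    """
    t_pre = np.cumsum(rng.exponential(1.0 / rate_pre, int(rate_pre * duration * 1.5)))
    t_pre = t_pre[t_pre < duration]
    t_post = np.cumsum(rng.exponential(1.0 / rate_post, int(rate_post * duration * 1.5)))
    t_post = t_post[t_post < duration]

    # Hebbian: nearest-neighbour pairing, one update per event against the
    # most recent opposite spike.
    total_hebb, n_events = 0.0, 0
    for t in t_post:
        earlier = t_pre[t_pre <= t]
        if earlier.size:
            total_hebb += abs(pcdcn_hebbian(t - earlier[-1], hebbian))
            n_events += 1
    for t in t_pre:
        earlier = t_post[t_post < t]
        if earlier.size:
            total_hebb += abs(pcdcn_hebbian(-(t - earlier[-1]), hebbian))
            n_events += 1
    mean_hebb = total_hebb / max(n_events, 1)

    total_sym = 0.0
    for t in t_pre:
        total_sym += abs(pcdcn_symmetric_on_pc_spike(t_post[t_post <= t], t, symmetric))
    for t in t_post:
        total_sym += abs(pcdcn_symmetric_on_dcn_spike(t_pre[t_pre < t], t, symmetric))
    mean_sym = total_sym / max(len(t_pre) + len(t_post), 1)

    ratio = mean_hebb / mean_sym if mean_sym > 0 else 1.0
    scaled = PCDCNRuleConfig(
        kernel_choice="symmetric",
        tau1=symmetric.tau1,
        tau2=symmetric.tau2,
        sigma=symmetric.sigma,
        ltp_max=symmetric.ltp_max * ratio,
        ltd_max=symmetric.ltd_max * ratio,
        scale=symmetric.scale,
        truncation_window=symmetric.truncation_window,
    )
    return hebbian, scaled, ratio
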