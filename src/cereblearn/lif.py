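"""Clock-driven leaky integrate-and-fire populations with conductance synapses.

The whole network advances in fixed steps (default 2 ms, the step the
coding scheme is defined on) with forward-Euler integration over internal
substeps. Synapses are conductance-based with single-exponential decay;
spikes produced at step *n* are delivered at step *n+1* (one-step uniform
synaptic delay).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._fast import lif_step

__all__ = [
    "DT",
    "N_SUBSTEPS",
    "LIFParameters",
    "PopulationState",
    "SpikeEvent",
    "step_population",
    "Network",
]

DT = 0.002  # s, clock step of the whole simulation
N_SUBSTEPS = 10  # Euler substeps inside one clock step


class SpikeEvent(NamedTuple):
    """A single spike: absolute time (s) and global neuron index."""

    time: float
    neuron_id: int


@dataclass(frozen=True)
class LIFParameters:
    """Membrane and synapse constants of one population.

    Values are config-first: the defaults describe a generic small neuron
    (tau_m = 10 ms); the network builder assigns population-specific
    parameter sets sized to each cell type's synaptic load.
    """

    membrane_capacitance: float = 2.0  # pF
    leak_conductance: float = 0.2  # nS
    resting_potential: float = -70.0  # mV
    threshold: float = -50.0  # mV
    reset_potential: float = -70.0  # mV
    refractory_period: float = 0.001  # s
    excitatory_reversal: float = 0.0  # mV
    inhibitory_reversal: float = -80.0  # mV
    tau_exc: float = 0.0005  # s
    tau_inh: float = 0.010  # s

    def __post_init__(self):
        if not self.threshold > self.reset_potential:
            raise ValueError("threshold must exceed reset_potential")
        if self.tau_exc <= 0 or self.tau_inh <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.refractory_period < 0:
            raise ValueError("refractory_period must be non-negative")
        if self.membrane_capacitance <= 0 or self.leak_conductance <= 0:
            raise ValueError("capacitance and leak conductance must be positive")


@dataclass
class PopulationState:
    """Per-neuron dynamic state of one population."""

    membrane_potential: np.ndarray  # mV
    g_exc: np.ndarray  # nS
    g_inh: np.ndarray  # nS
    refractory_until: np.ndarray  # s

    @classmethod
    def resting(cls, n: int, params: LIFParameters) -> "PopulationState":
        return cls(
            membrane_potential=np.full(n, params.resting_potential),
            g_exc=np.zeros(n),
            g_inh=np.zeros(n),
            refractory_until=np.full(n, -np.inf),
        )

    @property
    def n(self) -> int:
        return self.membrane_potential.shape[0]


def step_population(
    state: PopulationState,
    params: LIFParameters,
    dt: float = DT,
    exc_input: np.ndarray | None = None,
    inh_input: np.ndarray | None = None,
    t: float = 0.0,
    n_substeps: int = N_SUBSTEPS,
) -> tuple[PopulationState, list[SpikeEvent]]:
    """Advance one population by ``dt`` and return emitted spikes.

    ``exc_input`` / ``inh_input`` are per-neuron conductance increments (nS,
    the summed weights of spikes delivered this step; must be >= 0). The
    state is updated in place and also returned. Raises ``RuntimeError``
    with the offending neuron if the membrane goes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = state.n
    exc = np.zeros(n) if exc_input is None else np.asarray(exc_input, float)
    inh = np.zeros(n) if inh_input is None else np.asarray(inh_input, float)
    if np.any(exc < 0) or np.any(inh < 0):
        raise ValueError("synaptic weights are non-negative conductances")
    spikes = np.zeros(n, dtype=np.int64)
    bad = lif_step(
        state.membrane_potential, state.g_exc, state.g_inh, state.refractory_until,
        exc, inh, t, dt, n_substeps,
        params.membrane_capacitance, params.leak_conductance,
        params.resting_potential, params.threshold, params.reset_potential,
        params.refractory_period, params.excitatory_reversal,
        params.inhibitory_reversal, params.tau_exc, params.tau_inh,
        spikes,
    )
    if bad:
        culprit = int(np.flatnonzero(~np.isfinite(state.membrane_potential))[0])
        raise RuntimeError(
            f"non-finite membrane potential in neuron {culprit} at t={t:.6f} s"
        )
    events = [
        SpikeEvent(t, int(i)) for i in np.flatnonzero(spikes) for _ in range(spikes[i])
    ]
    return state, events


@dataclass
class Network:
    """Minimal synchronous multi-population stepper.

    ``populations`` maps name -> (state, params); ``projections`` is a list
    of dicts with keys pre, post, pre_ids, post_ids, weights, kind
    ('exc'|'inh'). Spikes emitted at one call are buffered and delivered as
    conductance increments at the next call (one-step delay). External
    drive is supplied per call as name -> excitatory increment array.
    """

    populations: dict
    projections: list
    t: float = 0.0
    dt: float = DT
    _pending: dict = field(default_factory=dict)
    _offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        off = 0
        for name, (state, _p) in self.populations.items():
            self._offsets[name] = off
            off += state.n
        for proj in self.projections:
            if proj["pre"] not in self.populations or proj["post"] not in self.populations:
                raise ValueError(f"projection references unknown population: {proj}")
            n_pre = self.populations[proj["pre"]][0].n
            n_post = self.populations[proj["post"]][0].n
            if np.any(proj["pre_ids"] >= n_pre) or np.any(proj["post_ids"] >= n_post):
                raise ValueError("dangling projection index")

    def step(self, external: dict | None = None) -> list[SpikeEvent]:
        external = external or {}
        exc = {n: np.zeros(s.n) for n, (s, _p) in self.populations.items()}
        inh = {n: np.zeros(s.n) for n, (s, _p) in self.populations.items()}
        for name, drive in external.items():
            exc[name] += drive
        # deliver last step's spikes through projections
        for proj in self.projections:
            fired = self._pending.get(proj["pre"])
            if fired is None or not fired.any():
                continue
            mask = fired[proj["pre_ids"]] > 0
            target = inh if proj["kind"] == "inh" else exc
            np.add.at(
                target[proj["post"]],
                proj["post_ids"][mask],
                proj["weights"][mask] * fired[proj["pre_ids"]][mask],
            )
        events: list[SpikeEvent] = []
        new_pending = {}
        for name, (state, params) in self.populations.items():
            spikes = np.zeros(state.n, dtype=np.int64)
            bad = lif_step(
                state.membrane_potential, state.g_exc, state.g_inh,
                state.refractory_until, exc[name], inh[name],
                self.t, self.dt, N_SUBSTEPS,
                params.membrane_capacitance, params.leak_conductance,
                params.resting_potential, params.threshold, params.reset_potential,
                params.refractory_period, params.excitatory_reversal,
                params.inhibitory_reversal, params.tau_exc, params.tau_inh,
                spikes,
            )
            if bad:
                raise RuntimeError(f"non-finite state in population {name} at t={self.t}")
            new_pending[name] = spikes
            base = self._offsets[name]
            events.extend(SpikeEvent(self.t, base + int(i)) for i in np.flatnonzero(spikes))
        self._pending = new_pending
        self.t += self.dt
        return events
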