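"""Spike coding at the model's borders.

* Mossy-fibre and granule-cell *state generators*: disjoint, equally-sized
  cell groups activated in a fixed order each trial, ticking off the
  passage of time (a deterministic stand-in for the recurrent granular
  network). 2000 GCs / 4 per state / 2 ms steps give the 500 states of a
  1 s trial; 100 MFs give 25 coarser states of 20 steps each.
* Climbing-fibre (inferior olive) encoder: given the normalised error
  ``eps`` in [0, 1], a CF fires in a step with probability
  ``eps * r_max * dt`` — the classic "fire if eps > eta" comparison with a
  rate cap keeping CF activity below ~10 spikes/s per fibre.
* Deep-nuclei decoder: a recursive exponential (one-pole) filter turning
  DCN spike counts into an analog corrective signal,
  ``y[n] = exp(-1/tau) * y[n-1] + gain * count[n]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif import DT

__all__ = [
    "StateSchedule",
    "DecoderConfig",
    "build_state_schedule",
    "emit_state_spikes",
    "encode_error",
    "decode_spikes",
    "ExpDecoder",
    "split_error",
    "combine_channels",
]


@dataclass(frozen=True)
class StateSchedule:
    """Partition of a cell population into sequentially active states."""

    n_cells: int
    cells_per_state: int
    n_states: int
    step_duration: float  # s each state stays active
    assignment: np.ndarray  # (n_states, cells_per_state) cell ids

    def state_at(self, trial_time: float) -> int:
        return min(int(trial_time / self.step_duration + 1e-9), self.n_states - 1)

    def cells_at(self, trial_time: float) -> np.ndarray:
        return self.assignment[self.state_at(trial_time)]


def build_state_schedule(
    n_cells: int,
    cells_per_state: int,
    trial_duration: float,
    dt: float = DT,
) -> StateSchedule:
    """Build the deterministic state partition for one population.

    The number of states is the smaller of (steps in a trial) and
    (n_cells / cells_per_state): 2000 GCs yield one state per 2 ms step
    (500 for a 1 s trial), while 100 MFs yield 25 states each spanning 20
    consecutive steps. States are visited in fixed order and restart at
    trial onset.
    """
    if n_cells % cells_per_state != 0:
        raise ValueError("n_cells must be divisible by cells_per_state")
    n_steps = int(round(trial_duration / dt))
    if n_steps <= 0:
        raise ValueError("trial must span at least one step")
    n_groups = n_cells // cells_per_state
    n_states = min(n_groups, n_steps)
    if n_steps % n_states != 0:
        raise ValueError(
            f"{n_steps} steps cannot be evenly divided into {n_states} states"
        )
    assignment = np.arange(n_cells).reshape(n_groups, cells_per_state)[:n_states]
    return StateSchedule(
        n_cells=n_cells,
        cells_per_state=cells_per_state,
        n_states=n_states,
        step_duration=trial_duration / n_states,
        assignment=assignment,
    )


def emit_state_spikes(
    schedule: StateSchedule,
    trial_time: float,
    mode: str = "gc",
    trial_duration: float | None = None,
    rate_hz: float = 100.0,
    dt: float = DT,
) -> np.ndarray:
    """Cell ids spiking at ``trial_time`` under the schedule.

    GC mode: each of the current state's cells emits exactly one spike per
    step. MF mode: the active group fires a deterministic comb at
    ``rate_hz`` inside its window (silent on off-steps and between trials).
    """
    if trial_duration is None:
        trial_duration = schedule.n_states * schedule.step_duration
    if trial_time < 0 or trial_time >= trial_duration + 1e-12:
        raise ValueError("trial_time outside the trial")
    cells = schedule.cells_at(trial_time)
    if mode == "gc":
        return cells.copy()
    if mode == "mf":
        step = int(round(trial_time / dt))
        period = max(1, int(round(1.0 / (rate_hz * dt))))
        return cells.copy() if step % period == 0 else np.empty(0, dtype=int)
    raise ValueError(f"unknown mode {mode!r}")


def encode_error(
    eps: float,
    dt: float = DT,
    r_max: float = 10.0,
    rng: np.random.Generator | None = None,
    u: float | None = None,
) -> bool:
    """One Bernoulli draw of the probabilistic climbing-fibre encoder.

    Fires iff a uniform draw eta falls below ``eps * r_max * dt``, i.e. the
    error-threshold comparison with per-step probability scaled so a fully
    saturated error channel sustains at most ``r_max`` spikes/s.
    """
    if not (0.0 <= eps <= 1.0):
        raise ValueError("eps must lie in [0, 1] after clipping")
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if u is None:
        if rng is None:
            raise ValueError("provide rng or a pre-drawn uniform u")
        u = rng.random()
    return u < eps * r_max * dt


@dataclass(frozen=True)
class DecoderConfig:
    """Recursive exponential decoder: decay constant in taps and gain in
    output units per spike."""

    tau_taps: float = 25.0
    gain: float = 1.0
    n_channels: int = 1

    def __post_init__(self):
        if self.tau_taps <= 0:
            raise ValueError("tau_taps must be positive")

    @property
    def decay(self) -> float:
        return float(np.exp(-1.0 / self.tau_taps))


def decode_spikes(counts, config: DecoderConfig) -> np.ndarray:
    """Filter per-step spike counts into an analog signal.

    ``y[n] = decay * y[n-1] + gain * counts[n]`` — linear in its input; a
    single spike at step 0 leaves ``gain * decay**k`` at lag k.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    from scipy.signal import lfilter

    return config.gain * lfilter([1.0], [1.0, -config.decay], counts, axis=0)


class ExpDecoder:
    """Stateful one-step version of :func:`decode_spikes` for closed loops."""

    def __init__(self, config: DecoderConfig):
        self.config = config
        self.y = np.zeros(config.n_channels)

    def step(self, counts) -> np.ndarray:
        self.y = self.config.decay * self.y + self.config.gain * np.asarray(counts, float)
        return self.y

    def reset(self) -> None:
        self.y = np.zeros(self.config.n_channels)


def split_error(raw_error: float, normalization: float) -> tuple[float, float]:
    """Route a signed raw error into the agonist/antagonist CF channels.

    Returns ``(eps_pos, eps_neg)``, each the clipped normalised magnitude of
    the corresponding sign; at most one is nonzero.
    """
    if normalization <= 0:
        raise ValueError("normalization must be positive")
    x = raw_error / normalization
    return float(np.clip(x, 0.0, 1.0)), float(np.clip(-x, 0.0, 1.0))


def combine_channels(y_pos, y_neg):
    """Adder/subtractor of the nuclear output: agonist minus antagonist."""
    y_pos = np.asarray(y_pos, dtype=float)
    y_neg = np.asarray(y_neg, dtype=float)
    if y_pos.shape != y_neg.shape:
        raise ValueError("channel length mismatch")
    out = y_pos - y_neg
    return out if out.ndim else float(out)
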