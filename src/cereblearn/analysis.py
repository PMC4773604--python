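"""Metrics over learned weights and spike trains.

These implement the model's headline analyses: per-state weight
profiles and their counter-phase transfer score (learning consolidation),
averaged gains (gain control), PC/DCN reverse cross-correlation, settling
("convergence") trials of metric series, and error-reduction percentages.

"Reverse cross-correlation" here is defined operationally as the maximum
over lags of *minus* the binned Pearson correlation between the PC and DCN
spike trains (PC inhibits DCN, so strong coupling shows up as
anti-correlation): 10 ms bins, lags up to +-100 ms by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import StateSchedule

__all__ = [
    "WeightProfile",
    "CorrelogramResult",
    "weight_profile",
    "counter_phase_score",
    "reverse_cross_correlation",
    "averaged_gain",
    "convergence_trial",
    "error_reduction_pct",
    "two_timescale_check",
]


@dataclass
class WeightProfile:
    projection: str
    index: np.ndarray  # state index
    mean_weight: np.ndarray  # nS per state
    trial: int | None = None


def weight_profile(
    weights: np.ndarray,
    schedule: StateSchedule,
    columns=None,
    projection: str = "",
    trial: int | None = None,
) -> WeightProfile:
    """Mean weight per state of a state-coded projection.

    ``weights`` is the dense (n_pre, n_post) matrix; ``columns`` restricts
    the postsynaptic cells (e.g. one microcomplex's PC group). Each state's
    value is the mean over its presynaptic cell group x selected columns.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim == 1:
        weights = weights[:, None]
    if weights.shape[0] != schedule.n_cells:
        raise ValueError(
            f"weight rows ({weights.shape[0]}) != scheduled cells ({schedule.n_cells})"
        )
    cols = np.arange(weights.shape[1]) if columns is None else np.asarray(columns)
    prof = np.array(
        [weights[np.ix_(group, cols)].mean() for group in schedule.assignment]
    )
    return WeightProfile(
        projection=projection, index=np.arange(schedule.n_states),
        mean_weight=prof, trial=trial,
    )


def _profile_values(p) -> np.ndarray:
    return p.mean_weight if isinstance(p, WeightProfile) else np.asarray(p, float)


def counter_phase_score(pfpc_profile, mfdcn_profile) -> float:
    """Pearson correlation of the PF profile (block-binned down to the MF
    profile's resolution) with the MF profile.

    Consolidation transfers the PF-PC pattern to MF-DCN *in counter phase*,
    so success shows as a strongly negative score. Zero-variance profiles
    have no defined correlation and return NaN.
    """
    a = _profile_values(pfpc_profile)
    b = _profile_values(mfdcn_profile)
    if len(a) % len(b) != 0:
        raise ValueError("PF profile length must be a multiple of the MF profile's")
    a = a.reshape(len(b), -1).mean(axis=1)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CorrelogramResult:
    lags: np.ndarray  # s
    correlation: np.ndarray  # Pearson r per lag, in [-1, 1]
    summary: float  # max over lags of -correlation


def reverse_cross_correlation(
    pc_train,
    dcn_train,
    bin_width: float = 0.010,
    max_lag: float = 0.100,
    window: tuple | None = None,
) -> CorrelogramResult:
    """Lagged binned Pearson correlation between PC and DCN spike trains.

    ``pc_train``/``dcn_train`` are spike time arrays; both are binned on a
    common grid (``window`` defaults to their joint span). The summary is
    the anti-correlation magnitude ``max_lag(-r)``. Empty trains are
    undefined and raise ``ValueError``.
    """
    pc = np.sort(np.asarray(pc_train, float))
    dcn = np.sort(np.asarray(dcn_train, float))
    if pc.size == 0 or dcn.size == 0:
        raise ValueError("empty spike train: correlation undefined")
    if window is None:
        window = (min(pc[0], dcn[0]), max(pc[-1], dcn[-1]) + bin_width)
    edges = np.arange(window[0], window[1] + bin_width, bin_width)
    a, _ = np.histogram(pc, edges)
    b, _ = np.histogram(dcn, edges)
    k = int(round(max_lag / bin_width))
    lags = np.arange(-k, k + 1)
    corr = np.full(lags.shape, np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: len(a) - lag or None], b[lag:]
        else:
            x, y = a[-lag:], b[: len(b) + lag or None]
        if len(x) > 1 and np.std(x) > 0 and np.std(y) > 0:
            corr[i] = np.corrcoef(x, y)[0, 1]
    valid = corr[~np.isnan(corr)]
    if valid.size == 0:
        raise ValueError("no lag with defined correlation")
    return CorrelogramResult(
        lags=lags * bin_width, correlation=corr, summary=float(np.max(-valid))
    )


def averaged_gain(weights: np.ndarray, indices=None) -> float:
    """Arithmetic mean weight of one microcomplex's synapses."""
    w = np.asarray(weights, dtype=float)
    if indices is not None:
        w = w[np.asarray(indices)]
    return float(w.mean())


def convergence_trial(
    series,
    fraction: float = 0.05,
    window: int = 50,
) -> int | None:
    """First trial after which the smoothed series stays within
    ``(1 +- fraction)`` of its final plateau value.

    The series is smoothed with a centred moving mean of ``window`` trials;
    the plateau is the smoothed final value. Returns ``None`` when the
    criterion is never met (reported as not-converged). For a plateau at
    exactly zero the band falls back to ``fraction`` times the smoothed
    series' peak magnitude.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    w = max(1, min(window, x.size))
    kernel = np.ones(w) / w
    sm = np.convolve(x, kernel, mode="valid")
    plateau = sm[-1]
    tol = fraction * abs(plateau)
    if tol == 0.0:
        tol = fraction * np.max(np.abs(sm)) if np.any(sm) else 0.0
    inside = np.abs(sm - plateau) <= tol
    # last index where the series is outside the band
    bad = np.flatnonzero(~inside)
    if bad.size == 0:
        return 0
    first = int(bad[-1]) + 1
    if first >= sm.size:
        return None
    return first


def error_reduction_pct(mae_series, baseline_window, final_window) -> float:
    """Percentage drop of the mean MAE between two trial windows.

    ``100 * (mean(baseline) - mean(final)) / mean(baseline)``; always
    <= 100. A zero baseline is undefined and raises ``ValueError``.
    """
    x = np.asarray(mae_series, dtype=float)
    base = x[slice(*baseline_window)].mean()
    final = x[slice(*final_window)].mean()
    if base == 0:
        raise ValueError("zero baseline: reduction undefined")
    return float(100.0 * (base - final) / base)


def two_timescale_check(
    pfpc_series,
    mfdcn_series,
    pcdcn_series,
    fraction: float = 0.05,
    window: int = 50,
) -> dict:
    """Settling order of the three learning sites.

    Returns the convergence trial of each series and whether the
    fast-cortex / slow-nuclei ordering holds strictly
    (PF-PC before MF-DCN, MF-DCN no later than PC-DCN). Ties or
    non-convergence do not pass.
    """
    t_pf = convergence_trial(pfpc_series, fraction, window)
    t_mf = convergence_trial(mfdcn_series, fraction, window)
    t_pc = convergence_trial(pcdcn_series, fraction, window)
    ok = (
        t_pf is not None and t_mf is not None and t_pc is not None
        and t_pf < t_mf <= t_pc
    )
    return {"pfpc": t_pf, "mfdcn": t_mf, "pcdcn": t_pc, "ordered": bool(ok)}
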