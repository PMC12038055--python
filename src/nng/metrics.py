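"""Coordination and learning metrics for spike matrices and trajectories.

All statistics operate on plain arrays: an N x 2 cursor/target trajectory and
an N x k binary spike matrix per group. Undefined values (0/0 rates,
zero-variance correlations) propagate as ``nan``, never as 0. The Heaviside
convention is strict: H(0) = 0, so "no change" never counts as improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import TWO_PI, angle_to_unit


def _distances(cursor, target):
    cursor = np.asarray(cursor, dtype=float)
    target = np.asarray(target, dtype=float)
    if target.ndim == 1:
        target = np.broadcast_to(target, cursor.shape)
    diff = target - cursor
    return np.hypot(diff[:, 0], diff[:, 1])


def improvement_rate(cursor, target) -> float:
    """Fraction of steps at which distance-to-target strictly decreased.

    ``target`` may be a single fixed point or an N x 2 trajectory (the actor
    target moves).
    """
    d = _distances(cursor, target)
    if d.shape[0] < 2:
        raise ValueError("need at least two time points")
    return float(np.mean(d[:-1] - d[1:] > 0.0))


def correct_response_rate(spikes, cursor, target, assigned_direction: float) -> float:
    """Among a player's presses, the fraction at which a unit step along the
    assigned direction would have strictly reduced distance-to-target.

    Returns ``nan`` when the player never pressed.
    """
    spikes = np.asarray(spikes)
    cursor = np.asarray(cursor, dtype=float)[: spikes.shape[0]]
    target = np.asarray(target, dtype=float)
    if target.ndim == 1:
        target = np.broadcast_to(target, cursor.shape)
    target = target[: spikes.shape[0]]
    pressed = spikes == 1
    if not pressed.any():
        return float("nan")
    stepv = angle_to_unit(assigned_direction)
    d0 = _distances(cursor[pressed], target[pressed])
    d1 = _distances(cursor[pressed] + stepv, target[pressed])
    return float(np.mean(d0 - d1 > 0.0))


def spike_triggered_circular_variance(
    spikes, stimulus_angles, spike_triggered: bool = True
) -> float:
    """Circular variance 1 - ||mean unit stimulus vector||.

    With ``spike_triggered=True`` (default, matching the figure captions) the
    mean runs over the stimuli at press times only; with ``False`` it runs
    over all defined stimuli (the literal printed sum). ``nan`` stimulus
    entries (degenerate / hidden target) are excluded; returns ``nan`` when
    no stimulus qualifies.
    """
    spikes = np.asarray(spikes)
    angles = np.asarray(stimulus_angles, dtype=float)
    mask = ~np.isnan(angles)
    if spike_triggered:
        mask &= spikes[: angles.shape[0]] == 1
    if not mask.any():
        return float("nan")
    sel = angles[mask]
    return float(1.0 - math.hypot(np.cos(sel).mean(), np.sin(sel).mean()))


def action_time_correlation(spikes_i, spikes_j) -> float:
    """Product-moment correlation of two binary spike trains.

    ``nan`` when either train has zero sample variance.
    """
    x = np.asarray(spikes_i, dtype=float)
    y = np.asarray(spikes_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spike trains must be 1-D and equally long")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two time points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt((xc @ xc) / (n - 1))
    sy = math.sqrt((yc @ yc) / (n - 1))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc @ yc) / ((n - 1) * sx * sy))


def _entropy_bits(symbols) -> float:
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def encode_action_vectors(actions) -> np.ndarray:
    """Encode an N x k binary action matrix as one symbol per step
    (k-bit integer, so a 4-unit group has 16 possible joint actions)."""
    actions = np.asarray(actions)
    weights = 1 << np.arange(actions.shape[1])
    return actions @ weights


def discretize_angles(angles, bins: int = 8) -> np.ndarray:
    """Equal-width circular bins with bin 0 centred at angle 0; ``nan``
    angles map to the sentinel -1 (goal reached / hidden)."""
    angles = np.asarray(angles, dtype=float)
    width = TWO_PI / bins
    idx = np.floor(angles / width + 0.5).astype(np.int64) % bins
    return np.where(np.isnan(angles), -1, idx)


def mutual_information(stimulus_symbols, action_symbols) -> float:
    """Plug-in mutual information in bits between two symbol streams."""
    x = np.asarray(stimulus_symbols)
    y = np.asarray(action_symbols)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("symbol streams must be non-empty and equally long")
    # joint symbols via pairing
    xu, xi = np.unique(x, return_inverse=True)
    yu, yi = np.unique(y, return_inverse=True)
    joint = xi * len(yu) + yi
    return _entropy_bits(xi) + _entropy_bits(yi) - _entropy_bits(joint)


def windowed_mutual_information(
    stimulus_symbols, action_symbols, window: int = 150, stride: int = 10
):
    """Sliding-window MI time course; returns (window centres, MI values)."""
    x = np.asarray(stimulus_symbols)
    y = np.asarray(action_symbols)
    n = x.shape[0]
    centres, values = [], []
    for start in range(0, max(n - window + 1, 1), stride):
        stop = min(start + window, n)
        if stop - start < 2:
            break
        centres.append(start + (stop - start) // 2)
        values.append(mutual_information(x[start:stop], y[start:stop]))
    return np.asarray(centres), np.asarray(values)


def cross_correlation(spikes_i, spikes_j, max_window: int) -> tuple:
    """Lagged product cross-correlation R(tau) = sum_t x[t + tau] * y[t].

    Positive tau means the first train's spikes occur tau steps *after* the
    second train's. Returns (lags, values) for tau in [-max_window,
    max_window].
    """
    x = np.asarray(spikes_i, dtype=float)
    y = np.asarray(spikes_j, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("spike trains must be nonempty")
    lags = np.arange(-max_window, max_window + 1)
    vals = np.empty(lags.shape[0])
    n = min(x.shape[0], y.shape[0])
    for k, tau in enumerate(lags):
        if tau >= 0:
            vals[k] = float(x[tau:n] @ y[: n - tau])
        else:
            vals[k] = float(x[: n + tau] @ y[-tau:n])
    return lags, vals


def cross_correlation_max_lag(spikes_i, spikes_j, max_window: int) -> float:
    """Lag maximising the product cross-correlation.

    Ties broken toward the smallest |tau|, then the positive sign. ``nan``
    when the product is zero for every lag (no coincident activity).
    """
    lags, vals = cross_correlation(spikes_i, spikes_j, max_window)
    if vals.max() <= 0.0:
        return float("nan")
    best = vals.max()
    cand = lags[vals == best]
    order = np.lexsort((-np.sign(cand), np.abs(cand)))
    return float(cand[order[0]])


@dataclass
class MannKendallResult:
    z: float
    tau: float
    p: float
    s: int


def mann_kendall_trend(series) -> MannKendallResult:
    """Mann-Kendall trend test with tie-corrected variance and continuity
    correction, plus Kendall's tau (tie-corrected denominator)."""
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least three observations")
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, k=1).sum())
    # tie correction
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - (ties * (ties - 1) * (2 * ties + 5)).sum()) / 18.0
    n_pairs = n * (n - 1) / 2.0
    tie_term = (ties * (ties - 1) / 2.0).sum()
    denom = math.sqrt((n_pairs - tie_term) * n_pairs)
    tau = s / denom if denom > 0 else 0.0
    if var_s <= 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var_s)
    else:
        z = (s + 1) / math.sqrt(var_s)
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    return MannKendallResult(z=float(z), tau=float(tau), p=float(p), s=s)


def activity_count_fit(spikes) -> tuple:
    """Binomial MLE of the per-step per-unit activation probability.

    The per-step number of active players is modelled Binomial(k, p); returns
    (p_hat, chi2, p_value) where the chi-square statistic compares observed
    per-step activity counts with the fitted binomial (k - 1 dof, one
    estimated parameter).
    """
    a = np.asarray(spikes)
    if a.ndim != 2 or a.shape[0] < 100:
        raise ValueError("need an N x k spike matrix with N >= 100")
    n, k = a.shape
    counts = a.sum(axis=1)
    p_hat = float(counts.mean() / k)
    from scipy.stats import binom, chi2 as chi2_dist

    observed = np.bincount(counts, minlength=k + 1).astype(float)
    expected = n * binom.pmf(np.arange(k + 1), k, p_hat)
    if p_hat in (0.0, 1.0):
        return p_hat, 0.0, 1.0
    # pool cells with tiny expectation to keep the statistic stable
    keep = expected > 1e-9
    chi2 = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    dof = max(int(keep.sum()) - 2, 1)
    p_value = float(chi2_dist.sf(chi2, dof))
    return p_hat, chi2, p_value
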