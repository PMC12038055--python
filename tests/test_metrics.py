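"""Metric suite: worked examples plus brute-force oracle twins."""

import math

import numpy as np
import pytest
from scipy.stats import kendalltau

from nng import metrics as M

RNG = np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# improvement rate


def test_improvement_rate_examples():
    # straight approach to a fixed target: every step improves
    cursor = np.stack([np.arange(10.0), np.zeros(10)], axis=1)
    target = np.array([100.0, 0.0])
    assert M.improvement_rate(cursor, target) == 1.0
    # static cursor: H(0) = 0, nothing improves
    static = np.zeros((5, 2))
    assert M.improvement_rate(static, target) == 0.0
    # distances (10, 8, 8, 9, 7): strict decreases at 2 of 4 transitions
    d = [10.0, 8.0, 8.0, 9.0, 7.0]
    cursor = np.stack([np.asarray(d), np.zeros(5)], axis=1)
    assert M.improvement_rate(cursor, np.array([0.0, 0.0])) == pytest.approx(0.5)


def test_improvement_rate_needs_two_points():
    with pytest.raises(ValueError):
        M.improvement_rate(np.zeros((1, 2)), np.array([1.0, 0.0]))


def _improvement_oracle(cursor, target):
    total = 0
    n = len(cursor)
    for t in range(n - 1):
        d0 = math.dist(cursor[t], target[t])
        d1 = math.dist(cursor[t + 1], target[t + 1])
        total += 1 if (d0 - d1) > 0 else 0
    return total / (n - 1)


# ---------------------------------------------------------------------------
# correct response rate


def test_correct_response_rate_examples():
    # press only when the target lies exactly along mu
    cursor = np.zeros((4, 2))
    target = np.tile([5.0, 0.0], (4, 1))
    spikes = np.array([1, 1, 0, 1])
    assert M.correct_response_rate(spikes, cursor, target, 0.0) == 1.0
    # press only when target along mu + pi (distance > 1): always wrong
    assert M.correct_response_rate(spikes, cursor, target, math.pi) == 0.0
    # no presses -> undefined sentinel, not zero
    assert math.isnan(M.correct_response_rate(np.zeros(4), cursor, target, 0.0))


def test_correct_response_rate_three_of_four():
    # 4 presses; target along mu for 3 of them, opposite for 1
    cursor = np.zeros((4, 2))
    target = np.array([[5.0, 0.0], [4.0, 1.0], [5.0, -1.0], [-5.0, 0.0]])
    spikes = np.ones(4, dtype=int)
    assert M.correct_response_rate(spikes, cursor, target, 0.0) == pytest.approx(0.75)


def _crr_oracle(spikes, cursor, target, mu):
    stepv = (math.cos(mu), math.sin(mu))
    hits, presses = 0, 0
    for t in range(len(spikes)):
        if spikes[t] != 1:
            continue
        presses += 1
        d0 = math.dist(cursor[t], target[t])
        moved = (cursor[t][0] + stepv[0], cursor[t][1] + stepv[1])
        if d0 - math.dist(moved, target[t]) > 0:
            hits += 1
    return float("nan") if presses == 0 else hits / presses


# ---------------------------------------------------------------------------
# circular variance


def test_circular_variance_examples():
    spikes = np.ones(4, dtype=int)
    assert M.spike_triggered_circular_variance(spikes, np.zeros(4)) == pytest.approx(0.0)
    four_winds = np.array([0.0, math.pi / 2, math.pi, 3 * math.pi / 2])
    assert M.spike_triggered_circular_variance(spikes, four_winds) == pytest.approx(1.0)
    two = np.array([0.0, math.pi / 2])
    expected = 1.0 - math.sqrt(2) / 2
    assert M.spike_triggered_circular_variance(np.ones(2, int), two) == pytest.approx(expected)


def test_circular_variance_spike_selection_and_sentinel():
    angles = np.array([0.0, math.pi, 0.0, np.nan])
    spikes = np.array([1, 0, 1, 1])
    # only the two pressed-and-defined zeros enter
    assert M.spike_triggered_circular_variance(spikes, angles) == pytest.approx(0.0)
    assert math.isnan(M.spike_triggered_circular_variance(np.zeros(4, int), angles))
    # all-t variant includes the un-pressed pi
    allt = M.spike_triggered_circular_variance(spikes, angles, spike_triggered=False)
    assert allt == pytest.approx(1.0 - 1.0 / 3.0)


# ---------------------------------------------------------------------------
# action time correlation


def test_action_time_correlation_examples():
    a = np.array([1, 0, 1, 0])
    assert M.action_time_correlation(a, a) == pytest.approx(1.0)
    assert M.action_time_correlation(a, 1 - a) == pytest.approx(-1.0)
    b = np.array([1, 0, 0, 0])
    assert M.action_time_correlation(a, b) == pytest.approx(0.57735, abs=1e-5)
    assert math.isnan(M.action_time_correlation(a, np.zeros(4, int)))


# ---------------------------------------------------------------------------
# mutual information


def test_mutual_information_examples():
    # bijection between two binary streams: exactly 1 bit
    x = np.array([0, 1] * 50)
    assert M.mutual_information(x, 1 - x) == pytest.approx(1.0)
    # independent product table: exactly zero for a balanced sample
    x = np.repeat([0, 0, 1, 1], 25)
    y = np.tile([0, 1], 50)
    assert M.mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)
    # joint table ((0.4, 0.1), (0.1, 0.4)) via exact counts out of 10
    x = np.array([0] * 5 + [1] * 5)
    y = np.array([0] * 4 + [1] + [0] + [1] * 4)
    assert M.mutual_information(x, y) == pytest.approx(0.27807, abs=1e-5)


def _mi_oracle(x, y):
    n = len(x)
    total = 0.0
    for xv in set(x.tolist()):
        for yv in set(y.tolist()):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy == 0:
                continue
            px = np.mean(x == xv)
            py = np.mean(y == yv)
            total += pxy * math.log2(pxy / (px * py))
    return total


def test_mutual_information_properties():
    for _ in range(20):
        x = RNG.integers(0, 5, size=60)
        y = RNG.integers(0, 3, size=60)
        mi = M.mutual_information(x, y)
        assert mi >= -1e-12
        hx = M.mutual_information(x, x)
        hy = M.mutual_information(y, y)
        assert mi <= min(hx, hy) + 1e-9
        # invariance under relabeling
        relabel = RNG.permutation(5)
        assert M.mutual_information(relabel[x], y) == pytest.approx(mi, abs=1e-12)


# ---------------------------------------------------------------------------
# cross correlation


def test_cross_correlation_lag_examples():
    rng = np.random.default_rng(3)
    a = (rng.random(200) < 0.3).astype(int)
    b = np.roll(a, 3)  # b's spikes happen 3 steps after a's
    assert M.cross_correlation_max_lag(b, a, 8) == 3.0
    assert M.cross_correlation_max_lag(a, a, 8) == 0.0
    sensor = np.zeros(20, int)
    sensor[[3, 10]] = 1
    actor = np.zeros(20, int)
    actor[[6, 13]] = 1
    assert M.cross_correlation_max_lag(actor, sensor, 8) == 3.0
    # no coincident activity at any lag -> sentinel
    lone_a = np.zeros(30, int)
    lone_a[0] = 1
    lone_b = np.zeros(30, int)
    lone_b[29] = 1
    assert math.isnan(M.cross_correlation_max_lag(lone_a, lone_b, 5))


def _xcorr_oracle(x, y, w):
    n = len(x)
    best_val, best_lag = -1.0, None
    for tau in range(-w, w + 1):
        total = 0
        for t in range(n):
            if 0 <= t + tau < n:
                total += x[t + tau] * y[t]
        better = total > best_val
        tie = total == best_val and (
            abs(tau) < abs(best_lag) or (abs(tau) == abs(best_lag) and tau > best_lag)
        )
        if better or tie:
            best_val, best_lag = total, tau
    return float("nan") if best_val <= 0 else float(best_lag)


# ---------------------------------------------------------------------------
# Mann-Kendall


def test_mann_kendall_examples():
    up = M.mann_kendall_trend(np.arange(10.0))
    assert up.tau == pytest.approx(1.0)
    assert up.z > 0 and up.p < 0.01
    down = M.mann_kendall_trend(np.arange(10.0)[::-1])
    assert down.tau == pytest.approx(-1.0)
    small = M.mann_kendall_trend([1.0, 3.0, 2.0])
    assert small.s == 1
    assert small.tau == pytest.approx(1.0 / 3.0)
    flat = M.mann_kendall_trend(np.ones(6))
    assert flat.z == 0.0 and flat.tau == 0.0


def test_mann_kendall_matches_scipy_tau():
    for _ in range(10):
        x = RNG.normal(size=30)
        x[RNG.integers(30)] = x[0]  # introduce a tie sometimes
        res = M.mann_kendall_trend(x)
        ref, _ = kendalltau(np.arange(30), x)
        assert res.tau == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# activity count fit


def test_activity_count_fit_recovery():
    rng = np.random.default_rng(5)
    spikes = (rng.random((10000, 4)) < 0.4).astype(int)
    p_hat, chi2, p_val = M.activity_count_fit(spikes)
    assert p_hat == pytest.approx(0.4, abs=0.02)
    assert p_val > 0.01
    zeros = np.zeros((200, 4), int)
    assert M.activity_count_fit(zeros)[0] == 0.0
    ones = np.ones((200, 4), int)
    assert M.activity_count_fit(ones)[0] == 1.0


# ---------------------------------------------------------------------------
# every metric equals its brute-force oracle on random instances


@pytest.mark.parametrize("seed", range(8))
def test_metrics_match_oracles_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = 50
    cursor = rng.normal(size=(n, 2)) * 10
    target = rng.normal(size=(n, 2)) * 10
    spikes = (rng.random((n, 2)) < 0.4).astype(int)
    mu = rng.uniform(0, 2 * math.pi)
    assert M.improvement_rate(cursor, target) == pytest.approx(
        _improvement_oracle(cursor, target), abs=1e-10
    )
    got = M.correct_response_rate(spikes[:, 0], cursor, target, mu)
    want = _crr_oracle(spikes[:, 0], cursor, target, mu)
    if math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(want, abs=1e-10)
    # circular variance oracle: direct resultant
    angles = rng.uniform(0, 2 * math.pi, size=n)
    sel = angles[spikes[:, 0] == 1]
    if sel.size:
        want_var = 1 - abs(np.exp(1j * sel).mean())
        assert M.spike_triggered_circular_variance(spikes[:, 0], angles) == pytest.approx(
            want_var, abs=1e-10
        )
    # correlation oracle: definition with explicit loops
    x, y = spikes[:, 0].astype(float), spikes[:, 1].astype(float)
    if x.std() > 0 and y.std() > 0:
        num = float(((x - x.mean()) * (y - y.mean())).sum())
        den = (n - 1) * x.std(ddof=1) * y.std(ddof=1)
        assert M.action_time_correlation(x, y) == pytest.approx(num / den, abs=1e-10)
    # MI oracle
    xs = rng.integers(0, 4, size=n)
    ys = rng.integers(0, 4, size=n)
    assert M.mutual_information(xs, ys) == pytest.approx(_mi_oracle(xs, ys), abs=1e-10)
    # cross-correlation lag oracle (exhaustive tau sweep)
    got_lag = M.cross_correlation_max_lag(spikes[:, 0], spikes[:, 1], 7)
    want_lag = _xcorr_oracle(spikes[:, 0], spikes[:, 1], 7)
    if math.isnan(want_lag):
        assert math.isnan(got_lag)
    else:
        assert got_lag == want_lag
    # Mann-Kendall S oracle (brute force over pairs)
    series = rng.normal(size=20)
    s = sum(
        np.sign(series[j] - series[i]) for i in range(20) for j in range(i + 1, 20)
    )
    assert M.mann_kendall_trend(series).s == int(s)
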