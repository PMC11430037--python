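"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by enumeration or dense numerics, without
touching the implementation path it checks.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def riemann_twag(times, values, step: float = 0.001) -> float:
    """Dense midpoint Riemann-sum time-weighted average over the
    piecewise-linear glucose curve (integration cells of at most ``step``
    hours, aligned to the measurement segments)."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    area = 0.0
    for t0, t1, v0, v1 in zip(times[:-1], times[1:], values[:-1], values[1:]):
        n_cells = max(1, math.ceil((t1 - t0) / step))
        h = (t1 - t0) / n_cells
        mids = t0 + (np.arange(n_cells) + 0.5) * h
        interp = v0 + (mids - t0) / (t1 - t0) * (v1 - v0)
        area += float(np.sum(interp) * h)
    return area / (times[-1] - times[0])


def mannwhitney_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n, m = len(a), len(b)
    # enumerate index assignments (not values) so duplicates are handled
    idx = range(n + m)
    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    us = []
    for combo in itertools.combinations(idx, n):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in idx if i not in combo]
        us.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs + 1e-12)
    p_high = np.mean(us >= u_obs - 1e-12)
    return float(min(1.0, 2 * min(p_low, p_high)))


def signed_rank_p(pre, post) -> float:
    """Exact two-sided Wilcoxon signed-rank p by sign-flip enumeration
    (assumes no zero differences and no tied absolute differences)."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(np.sum(ranks * np.asarray(signs))))
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2 * min(p_low, p_high)))


def fisher_p(table) -> float:
    """Two-sided Fisher exact p by summing hypergeometric probabilities of all
    tables with the same margins that are no more probable than the observed."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    total = row1 + row2

    def prob(x):
        return (
            math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(total, col1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)))


def grid_logit(x, y, *, rounds: int = 8, width: float = 10.0, grid: int = 81):
    """Brute-force maximum-likelihood logistic fit (intercept + slope) by
    iteratively refined grid search over the hand-written log-likelihood."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def nll(b0, b1):
        eta = b0 + b1 * x
        # log(1 + e^eta) - y*eta, stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    c0, c1, w = 0.0, 0.0, width
    for _ in range(rounds):
        b0s = np.linspace(c0 - w, c0 + w, grid)
        b1s = np.linspace(c1 - w, c1 + w, grid)
        vals = np.array([[nll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        c0, c1 = float(b0s[i]), float(b1s[j])
        w /= grid / 4  # shrink around the current optimum
    return c0, c1
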