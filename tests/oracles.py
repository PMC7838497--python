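"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's own code paths: permutation
enumeration is done positionally, ECDFs by direct counting, and the
Friedman statistic by the textbook rank formula.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ecdf_at(sample: np.ndarray, x: float) -> float:
    return float(np.sum(np.asarray(sample) <= x) / len(sample))


def ks_d_brute(x, y) -> float:
    pts = list(x) + list(y)
    return max(abs(ecdf_at(x, p) - ecdf_at(y, p)) for p in pts)


def mwu_u_brute(x, y) -> float:
    """U for x by direct pairwise counting (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mwu_exact_p_brute(x, y) -> float:
    """Two-sided exact p: doubled smaller tail over all C(n+m, n) labelings."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = mwu_u_brute(x, y)
    us = []
    idx = set(range(len(pooled)))
    for c in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in c]
        ys = [pooled[i] for i in idx - set(c)]
        us.append(mwu_u_brute(xs, ys))
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def ks_exact_p_brute(x, y) -> float:
    pooled = list(x) + list(y)
    n = len(x)
    d_obs = ks_d_brute(x, y)
    idx = set(range(len(pooled)))
    ds = []
    for c in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in c]
        ys = [pooled[i] for i in idx - set(c)]
        ds.append(ks_d_brute(xs, ys))
    return float(np.mean(np.asarray(ds) >= d_obs - 1e-9))


def friedman_stat_brute(blocks: np.ndarray) -> float:
    """12/(nk(k+1)) * sum_j (R_j - n(k+1)/2)^2 — no tie correction."""
    from scipy.stats import rankdata

    blocks = np.asarray(blocks, float)
    n, k = blocks.shape
    ranks = np.vstack([rankdata(row) for row in blocks])
    rj = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum((rj - n * (k + 1) / 2.0) ** 2))


def best_window_brute(edges: np.ndarray, values: np.ndarray, onset: float, width: float):
    """Exhaustive scan over all bin-aligned windows starting at/after onset."""
    bw = edges[1] - edges[0]
    n_win = int(round(width / bw))
    best = None
    for i in range(len(values) - n_win + 1):
        if edges[i] < onset - 1e-9:
            continue
        m = np.nanmean(values[i : i + n_win])
        if best is None or m > best[1] + 1e-12:
            best = (float(edges[i]), m)
    if best is None:
        raise ValueError("no window fits")
    return best[0], best[0] + n_win * bw


def match_events(true_times, det_times, tol):
    """Greedy one-to-one matching; returns (tp, fn, fp)."""
    det = np.asarray(det_times, float)
    used = np.zeros(det.size, bool)
    tp = fn = 0
    for t in np.asarray(true_times, float):
        cand = np.flatnonzero((np.abs(det - t) <= tol) & ~used)
        if cand.size:
            used[cand[np.argmin(np.abs(det[cand] - t))]] = True
            tp += 1
        else:
            fn += 1
    return tp, fn, int(np.sum(~used))
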