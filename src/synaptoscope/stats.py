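"""Nonparametric tests with exact small-sample behaviour.

The comparisons used throughout the pipeline are the two-sample
Mann–Whitney U (epoch-wise frequency/amplitude bins), the two-sample
Kolmogorov–Smirnov test (inter-event-interval, amplitude and cell-activity
distributions), and the Friedman test (paired per-cell activity across
control / drug / wash).

For small samples the U and KS null distributions are computed by full
enumeration of the C(n+m, n) relabelings of the pooled sample, which is
exact under exchangeability even with ties; larger samples fall back on the
standard tie-corrected normal (U) and Kolmogorov asymptotic (KS)
approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import kolmogorov, ndtr
from scipy.stats import chi2, rankdata

__all__ = ["TestResult", "mann_whitney_u", "ks_two_sample", "friedman"]

_EXACT_MWU_MAX_N = 12  # n + m at or below which U p-values are enumerated
_EXACT_KS_MAX_N = 10


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    exact: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n": list(self.n),
            "exact": self.exact,
        }


def _check_samples(x: np.ndarray, y: np.ndarray) -> None:
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")


# ---------------------------------------------------------------------------
# Mann–Whitney U


def _u_statistic(ranks: np.ndarray, idx: np.ndarray, n: int) -> float:
    return float(np.sum(ranks[idx]) - n * (n + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], two_sided: bool = True
) -> TestResult:
    """Mann–Whitney U test with midrank ties.

    The reported statistic is U for the first sample. For ``n + m <= 12``
    the p-value is exact (enumeration of all pooled relabelings); otherwise
    the tie-corrected normal approximation with continuity correction is
    used. Two-sided p is the doubled smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_samples(x, y)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks, np.arange(n), n)

    if n + m <= _EXACT_MWU_MAX_N:
        us = np.array(
            [_u_statistic(ranks, np.array(c), n) for c in combinations(range(n + m), n)]
        )
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        if two_sided:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        else:
            p = p_le
        return TestResult(u_obs, float(p), "mann_whitney_u_exact", (n, m), True)

    mean_u = n * m / 2.0
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
    var_u = n * m / 12.0 * ((N + 1) - tie_term)
    if var_u <= 0:  # all values tied
        return TestResult(u_obs, 1.0, "mann_whitney_u_normal", (n, m), False)
    # continuity-corrected z toward the mean
    diff = u_obs - mean_u
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_u) if diff != 0 else 0.0
    p_one = float(1.0 - ndtr(abs(z)))
    p = min(1.0, 2.0 * p_one) if two_sided else (float(ndtr(z)) if diff < 0 else p_one)
    return TestResult(u_obs, p, "mann_whitney_u_normal", (n, m), False)


# ---------------------------------------------------------------------------
# two-sample Kolmogorov–Smirnov


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| by a sweep over the pooled support."""
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), grid, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample KS test: D = sup |ECDF_x − ECDF_y|.

    Exact p by enumeration for ``n + m <= 10``; otherwise the Kolmogorov
    asymptotic distribution with the Stephens small-sample correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_samples(x, y)
    n, m = x.size, y.size
    d_obs = _ks_d(x, y)

    if n + m <= _EXACT_KS_MAX_N:
        pooled = np.concatenate([x, y])
        ds = []
        idx_all = frozenset(range(n + m))
        for c in combinations(range(n + m), n):
            xi = pooled[list(c)]
            yi = pooled[list(idx_all - frozenset(c))]
            ds.append(_ks_d(xi, yi))
        ds = np.array(ds)
        p = float(np.mean(ds >= d_obs - 1e-9))
        return TestResult(d_obs, p, "ks_two_sample_exact", (n, m), True)

    en = np.sqrt(n * m / (n + m))
    p = float(kolmogorov((en + 0.12 + 0.11 / en) * d_obs))
    return TestResult(d_obs, min(1.0, max(0.0, p)), "ks_two_sample_asymptotic", (n, m), False)


# ---------------------------------------------------------------------------
# Friedman


def friedman(blocks: np.ndarray) -> TestResult:
    """Friedman test on a subjects × conditions matrix of paired measures.

    Within-subject midranks give the tie-corrected chi-square statistic

        chi2 = [12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / (1 - C)

    with C = sum_i sum(t^3 - t) / (n k (k^2 - 1)) over tie groups t in each
    subject's row; p from the chi-square distribution with k − 1 df. A
    matrix whose rows are all completely tied yields statistic 0, p = 1.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be a 2-D subjects × conditions matrix")
    n, k = blocks.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(blocks)):
        raise ValueError("missing cells are not supported")

    ranks = np.apply_along_axis(rankdata, 1, blocks)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    tie_sum = 0.0
    for row in blocks:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:  # every row fully tied: no evidence at all
        return TestResult(0.0, 1.0, "friedman", (n, k), False)
    stat = float(stat / correction)
    p = float(chi2.sf(stat, k - 1))
    return TestResult(stat, p, "friedman", (n, k), False)
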