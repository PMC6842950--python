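"""Local similarity analysis (LSA) for OTU time series.

LSA scores the strongest locally aligned co-varying segment between two
time series: after a rank-based normal-score transform, a dynamic
program finds the contiguous run (allowing a bounded time delay between
the two series) whose summed product of z-scores is largest, separately
for positive and for negative association.  Division by the series
length keeps the score comparable to a correlation coefficient.
Significance is assessed by permuting one series, which preserves its
marginal distribution while destroying temporal alignment.

The all-pairs driver evaluates every pair of core OTUs and keeps the
pairs significant at a chosen level; these are the edges of the
co-variance network.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "LsaPair",
    "LocalSimilarity",
    "normal_score_transform",
    "local_similarity",
    "lsa_pvalue",
    "lsa_all_pairs",
]


@dataclass(frozen=True)
class LsaPair:
    """A significant signed local-similarity association between two OTUs."""

    otu_i: str
    otu_j: str
    score: float
    sign: int
    p_value: float
    n_timepoints: int
    max_delay: int

    def __post_init__(self) -> None:
        if self.otu_i == self.otu_j:
            raise ValueError("self-pairs are not allowed")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class LocalSimilarity:
    """Full output of one pairwise local-similarity computation.

    ``score`` is signed: ``s_pos`` when positive association dominates,
    ``-s_neg`` otherwise.  Spans are 0-based inclusive index ranges of
    the best aligned run in each series.
    """

    score: float
    sign: int
    s_pos: float
    s_neg: float
    x_span: tuple[int, int]
    y_span: tuple[int, int]


def normal_score_transform(series) -> np.ndarray:
    """Map a series to normal scores via average ranks.

    Values are ranked (ties get average ranks) and mapped through the
    standard normal quantile function at rank/(n+1).  Any monotone
    transform of the input yields the same output, so the downstream
    similarity is insensitive to the scale of normalized counts.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("normal score transform needs at least 3 observations")
    if np.isnan(x).any():
        raise ValueError("series contains NaN")
    if np.all(x == x[0]):
        raise ValueError("constant series has no defined ranks for similarity")
    ranks = rankdata(x, method="average")
    return norm.ppf(ranks / (n + 1))


def _dp_scores(w: np.ndarray, max_delay: int) -> tuple[float, float]:
    """Best nonnegative-reset aligned-run sums of +w and -w products.

    ``w[i, j] = x_i * y_j`` restricted to ``|i - j| <= max_delay``;
    returns un-normalized (S+, S-) sums.
    """
    n = w.shape[0]
    pos = np.zeros((n + 1, n + 1))
    neg = np.zeros((n + 1, n + 1))
    best_pos = 0.0
    best_neg = 0.0
    for i in range(1, n + 1):
        jlo = max(1, i - max_delay)
        jhi = min(n, i + max_delay)
        for j in range(jlo, jhi + 1):
            inc = w[i - 1, j - 1]
            pos[i, j] = max(0.0, pos[i - 1, j - 1] + inc)
            neg[i, j] = max(0.0, neg[i - 1, j - 1] - inc)
            best_pos = max(best_pos, pos[i, j])
            best_neg = max(best_neg, neg[i, j])
    return best_pos, best_neg


def local_similarity(x, y, max_delay: int = 0) -> LocalSimilarity:
    """Signed local-similarity score between two equal-length z-vectors.

    The positive score is the maximum, over alignments offset by at
    most ``max_delay`` steps, of the best nonnegative-reset running sum
    of elementwise products, divided by the series length; the negative
    score uses the negated products.  The larger of the two wins and
    sets the sign (ties go to the positive reading).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = xv.size
    if not 0 <= max_delay < n:
        raise ValueError("max_delay must satisfy 0 <= D < n")

    w = np.outer(xv, yv)
    # full DP with run-length tracking for the alignment span
    pos = np.zeros((n + 1, n + 1))
    neg = np.zeros((n + 1, n + 1))
    lpos = np.zeros((n + 1, n + 1), dtype=int)
    lneg = np.zeros((n + 1, n + 1), dtype=int)
    best = {1: (0.0, 0, 0, 0), -1: (0.0, 0, 0, 0)}  # sign -> (sum, i, j, length)
    for i in range(1, n + 1):
        for j in range(max(1, i - max_delay), min(n, i + max_delay) + 1):
            inc = w[i - 1, j - 1]
            cand = pos[i - 1, j - 1] + inc
            if cand > 0:
                pos[i, j] = cand
                lpos[i, j] = lpos[i - 1, j - 1] + 1
                if cand > best[1][0]:
                    best[1] = (cand, i, j, lpos[i, j])
            cand = neg[i - 1, j - 1] - inc
            if cand > 0:
                neg[i, j] = cand
                lneg[i, j] = lneg[i - 1, j - 1] + 1
                if cand > best[-1][0]:
                    best[-1] = (cand, i, j, lneg[i, j])

    s_pos = best[1][0] / n
    s_neg = best[-1][0] / n
    sign = 1 if s_pos >= s_neg else -1
    _, bi, bj, length = best[sign]
    if length == 0:
        x_span = y_span = (0, -1)  # empty alignment (all-zero input)
    else:
        x_span = (bi - length, bi - 1)
        y_span = (bj - length, bj - 1)
    score = s_pos if sign == 1 else -s_neg
    return LocalSimilarity(
        score=score, sign=sign, s_pos=s_pos, s_neg=s_neg, x_span=x_span, y_span=y_span
    )


def _abs_scores_lag0(w: np.ndarray) -> np.ndarray:
    """Vectorized lag-0 DP over rows of a product matrix ``w``.

    Each row is one permutation replicate's elementwise-product series;
    returns the un-normalized max(S+, S-) per row.
    """
    m, n = w.shape
    p = np.zeros(m)
    q = np.zeros(m)
    best = np.zeros(m)
    for i in range(n):
        col = w[:, i]
        p = np.maximum(0.0, p + col)
        q = np.maximum(0.0, q - col)
        np.maximum(best, p, out=best)
        np.maximum(best, q, out=best)
    return best


def lsa_pvalue(
    x,
    y,
    max_delay: int = 0,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the local-similarity score.

    The second argument is permuted (documented convention; the
    all-pairs driver passes arguments in a canonical order so results
    do not depend on column order).  Two-sided on the unsigned score:
    ``p = (1 + #{|score_perm| >= |score_obs|}) / (1 + n_perm)``.
    """
    if n_perm < 19:
        raise ValueError("n_perm < 19 cannot resolve significance at 0.05")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have equal length")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = xv.size
    obs = abs(local_similarity(xv, yv, max_delay).score)
    tol = 1e-12
    if max_delay == 0:
        perms = rng.permuted(np.tile(yv, (n_perm, 1)), axis=1)
        null = _abs_scores_lag0(perms * xv) / n
        hits = int(np.count_nonzero(null >= obs - tol))
    else:
        hits = 0
        for _ in range(n_perm):
            yp = rng.permutation(yv)
            sp, sn = _dp_scores(np.outer(xv, yp), max_delay)
            if max(sp, sn) / n >= obs - tol:
                hits += 1
    return (1 + hits) / (1 + n_perm)


def _pair_rng(master_seed: int, name_i: str, name_j: str) -> np.random.Generator:
    """Deterministic per-pair stream keyed by the unordered OTU names.

    Keying on names (not column positions) makes the all-pairs result
    invariant to column order in the input table.
    """
    a, b = sorted((name_i, name_j))
    key = zlib.crc32(f"{a}\t{b}".encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


def lsa_all_pairs(
    core_table: pd.DataFrame,
    max_delay: int = 0,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    time_index=None,
) -> list[LsaPair]:
    """Evaluate every OTU pair and keep those significant at ``alpha``.

    Parameters
    ----------
    core_table
        Normalized counts, samples (time-ordered) x core OTUs.
    time_index
        Optional explicit collection order; must be strictly
        increasing, otherwise the rows are not a valid time series.
    alpha
        Raw permutation-p threshold (no multiple-testing correction by
        default, matching a p < 0.05 edge filter).

    Returns
    -------
    list of :class:`LsaPair`, sorted by (otu_i, otu_j).
    """
    if len(core_table) < 4:
        raise ValueError("need at least 4 time-ordered samples for LSA")
    if time_index is not None:
        t = np.asarray(time_index)
        if len(t) != len(core_table):
            raise ValueError("time_index length mismatch")
        if not np.all(np.diff(t) > 0):
            raise ValueError("samples are not strictly time-ordered")
    zscores: dict[str, np.ndarray] = {}
    for otu in core_table.columns:
        col = core_table[otu].to_numpy(dtype=float)
        if np.all(col == col[0]):
            logger.warning("dropping constant OTU column %s from LSA", otu)
            continue
        zscores[otu] = normal_score_transform(col)

    pairs: list[LsaPair] = []
    n = len(core_table)
    for otu_a, otu_b in combinations(sorted(zscores), 2):
        za, zb = zscores[otu_a], zscores[otu_b]
        res = local_similarity(za, zb, max_delay)
        rng = _pair_rng(seed, otu_a, otu_b)
        p = lsa_pvalue(za, zb, max_delay=max_delay, n_perm=n_perm, rng=rng)
        if p < alpha:
            pairs.append(
                LsaPair(
                    otu_i=otu_a,
                    otu_j=otu_b,
                    score=res.score,
                    sign=res.sign,
                    p_value=p,
                    n_timepoints=n,
                    max_delay=max_delay,
                )
            )
    return pairs
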