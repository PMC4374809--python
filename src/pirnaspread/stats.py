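"""Exact small-sample statistics: Fisher's exact test and the Wilcoxon
signed-rank test, implemented by direct enumeration of the null.

Both are written from first principles (log-space hypergeometric mass,
explicit sign-flip null) so their behavior is fully specified here; library
implementations are used only as independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TWO_SIDED = "two_sided"
GREATER = "greater"
LESS = "less"
_ALTERNATIVES = {TWO_SIDED, GREATER, LESS}

# Relative slack when comparing table probabilities to the observed one in
# the two-sided rule; conventions differ only in this tie handling.
_TWO_SIDED_RELTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("table entries must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_hypergeom(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(X = a) for the hypergeometric with fixed margins.

    ``row1 = a+b``, ``row2 = c+d``, ``col1 = a+c``.  Log-gamma keeps this
    stable for margins up to ~1e6.
    """
    n = row1 + row2
    lg = math.lgamma
    return (
        lg(row1 + 1) - lg(a + 1) - lg(row1 - a + 1)
        + lg(row2 + 1) - lg(col1 - a + 1) - lg(row2 - (col1 - a) + 1)
        - (lg(n + 1) - lg(col1 + 1) - lg(n - col1 + 1))
    )


def fisher_exact(table, alternative: str = TWO_SIDED) -> float:
    """Fisher's exact test p-value for a 2x2 table.

    ``greater`` tests whether cell ``a`` is larger than expected under the
    hypergeometric null (odds ratio > 1); ``two_sided`` sums the probability
    of every table (with the observed margins) whose probability does not
    exceed the observed table's, the probability-mass convention.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
        ContingencyTable2x2(a, b, c, d)  # validation
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    if lo == hi:  # degenerate margin: a single admissible table
        return 1.0
    logp = {x: _log_hypergeom(x, row1, row2, col1) for x in range(lo, hi + 1)}
    if alternative == GREATER:
        p = sum(math.exp(lp) for x, lp in logp.items() if x >= a)
    elif alternative == LESS:
        p = sum(math.exp(lp) for x, lp in logp.items() if x <= a)
    else:
        cutoff = logp[a] + math.log1p(_TWO_SIDED_RELTOL)
        p = sum(math.exp(lp) for lp in logp.values() if lp <= cutoff)
    return min(1.0, p)


DROP = "drop"
PRATT = "pratt"


@dataclass(frozen=True)
class SignedRankResult:
    n_nonzero: int
    W: float
    p: float
    method: str
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, W: float, alternative: str) -> float:
    """Enumerate all sign assignments of the ranks (tie-free case)."""
    n = len(ranks)
    # distribution of W over the 2^n equiprobable sign patterns, built by
    # dynamic programming over integer ranks
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        counts[r:] = counts[r:] + counts[:total + 1 - r]
    counts /= counts.sum()
    w = int(round(W))
    if alternative == GREATER:
        return float(counts[w:].sum())
    if alternative == LESS:
        return float(counts[:w + 1].sum())
    return float(min(1.0, 2.0 * min(counts[w:].sum(), counts[:w + 1].sum())))


def wilcoxon_signed_rank(diffs, alternative: str = TWO_SIDED,
                         zero_policy: str = DROP,
                         exact_threshold: int = 12) -> SignedRankResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped by default (Wilcoxon's original treatment); ``pratt``
    keeps them for ranking and then discards their ranks.  W is the sum of
    positive ranks (midranks under ties).  The exact sign-flip null is
    enumerated when the sample is small and tie-free; otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    if zero_policy not in (DROP, PRATT):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    d = np.asarray(diffs, dtype=np.float64)
    if d.size == 0:
        raise ValueError("need at least one difference")

    nonzero = d != 0
    n_nonzero = int(nonzero.sum())
    if n_nonzero == 0:
        return SignedRankResult(0, 0.0, 1.0, "degenerate", degenerate=True)

    if zero_policy == DROP:
        dd = d[nonzero]
        absd = np.abs(dd)
        order = np.argsort(absd, kind="stable")
        ranks = np.empty_like(absd)
        ranks[order] = _midranks(absd[order])
        W = float(ranks[dd > 0].sum())
        rank_set = ranks
    else:  # pratt: rank including zeros, then drop zero ranks
        absd = np.abs(d)
        order = np.argsort(absd, kind="stable")
        allranks = np.empty_like(absd)
        allranks[order] = _midranks(absd[order])
        W = float(allranks[d > 0].sum())
        rank_set = allranks[nonzero]

    has_ties = len(np.unique(np.abs(d[nonzero]))) != n_nonzero or zero_policy == PRATT
    if n_nonzero <= exact_threshold and not has_ties:
        p = _exact_signed_rank_p(rank_set, W, alternative)
        return SignedRankResult(n_nonzero, W, max(p, 0.0), "exact")

    # normal approximation; mean/variance under the sign-flip null
    mu = float(rank_set.sum()) / 2.0
    var = float((rank_set ** 2).sum()) / 4.0
    if var == 0:
        return SignedRankResult(n_nonzero, W, 1.0, "degenerate", degenerate=True)
    sd = math.sqrt(var)
    from scipy.stats import norm
    if alternative == GREATER:
        z = (W - mu - 0.5) / sd
        p = float(norm.sf(z))
    elif alternative == LESS:
        z = (W - mu + 0.5) / sd
        p = float(norm.cdf(z))
    else:
        z = (abs(W - mu) - 0.5) / sd
        p = float(2.0 * norm.sf(z))
    return SignedRankResult(n_nonzero, W, min(1.0, max(p, 0.0)), "normal_approx")


def _midranks(sorted_vals: np.ndarray) -> np.ndarray:
    """Midranks (1-based) of an ascending-sorted array."""
    n = len(sorted_vals)
    ranks = np.empty(n, dtype=np.float64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[i:j + 1] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted q-values (utility; pipeline reports raw p by default)."""
    p = np.asarray(pvals, dtype=np.float64)
    n = p.size
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * n / (rank_idx + 1))
        q[i] = val
        prev = val
    return q
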