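"""Shared enrichment statistics.

Pure functions used by every downstream stage: the hypergeometric
over-representation tail, Fisher's exact 2x2 test, Benjamini-Hochberg
step-up adjustment, the minimum-hypergeometric (mHG) statistic with its
exact path-counting p-value, and Fisher's product method for combining
two p-values.

All tail probabilities are evaluated through log-gamma-based routines
(scipy), so gene-universe sizes in the tens of thousands do not overflow.
Over-representation tests are one-sided: "enrichment" means more overlap
than expected under random draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "MHGResult",
    "hypergeom_tail",
    "fisher_exact_2x2",
    "bh_adjust",
    "mhg_statistic",
    "mhg_pvalue",
    "fishers_product",
    "hypergeom_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation result.

    ``k`` genes of the query of size ``n`` fall in a term of size ``K``
    within a universe of ``N`` genes.
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    padj: float = float("nan")


@dataclass(frozen=True)
class MHGResult:
    """Minimum-hypergeometric statistic for a ranked binary list.

    ``statistic`` is the minimum hypergeometric tail over list prefixes,
    ``threshold`` the prefix length attaining it (smallest on ties), and
    ``b_at_threshold`` the number of hits inside that prefix. ``pvalue``
    is filled in by :func:`mhg_pvalue`.
    """

    statistic: float
    threshold: int
    b_at_threshold: int
    pvalue: float | None = None


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Drawing ``n`` genes without replacement from a universe of ``N``
    containing ``K`` marked genes, the probability of seeing ``k`` or
    more marked genes. Returns exactly 0.0 when ``k`` exceeds the
    largest possible overlap and 1.0 when ``k <= max(0, n+K-N)``.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        return 0.0
    if k <= max(0, n + K - N):
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], alternative: str = "two-sided"
) -> float:
    """Fisher's exact test p-value for a 2x2 contingency table.

    Two-sided by the point-probability method; one-sided ``greater`` is
    identical to the hypergeometric over-representation tail.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError(f"expected 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    return float(sps.fisher_exact(arr, alternative=alternative)[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j>=i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mhg_statistic(ranked_labels: Sequence[int]) -> MHGResult:
    """Minimum hypergeometric statistic of a ranked 0/1 membership vector.

    For every prefix length n' in [1, N-1] compute the hypergeometric
    tail of b(n') hits among the top n' of a list of N items containing
    B hits in total; the mHG statistic is the minimum tail, attained at
    the smallest such prefix on ties.
    """
    labels = np.asarray(ranked_labels, dtype=int)
    if labels.ndim != 1 or labels.size < 2:
        raise ValueError("ranked_labels must be a 1-d vector of length >= 2")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("ranked_labels must contain only 0 and 1")
    N = labels.size
    B = int(labels.sum())
    if B == 0 or B == N:
        raise ValueError("mHG undefined for all-zero or all-one label vectors")
    cum_b = np.cumsum(labels)
    n_primes = np.arange(1, N)
    tails = sps.hypergeom.sf(cum_b[: N - 1] - 1, N, B, n_primes)
    # smallest prefix on ties, tolerant to last-ulp rounding of equal tails
    best = int(np.flatnonzero(tails <= tails.min() * (1 + 1e-12))[0])
    return MHGResult(
        statistic=float(tails[best]),
        threshold=int(n_primes[best]),
        b_at_threshold=int(cum_b[best]),
    )


def mhg_pvalue(mhg: float, N: int, B: int) -> float:
    """Exact P(min-hypergeometric <= mhg) over random orderings.

    Counts lattice paths from (0, 0) to (N, B) — one step per list
    position, moving diagonally on a hit — that never enter a cell
    (n', b) with hypergeometric tail <= mhg for n' in [1, N-1]. Path
    counting uses exact integer arithmetic; the p-value is one minus
    the surviving fraction of the C(N, B) equally likely orderings.
    """
    if not (0 < B < N):
        raise ValueError(f"need 0 < B < N, got B={B}, N={N}")
    if N > 10_000:
        raise ValueError("exact mHG p-value limited to N <= 10,000")
    if mhg >= 1.0:
        return 1.0
    # tolerant comparison: the minimum itself must fall in the rejection
    # region despite float rounding of equal tails
    thresh = mhg * (1 + 1e-9) + 1e-300
    paths = [[0] * (B + 1) for _ in range(N + 1)]
    paths[0][0] = 1
    for n_prime in range(1, N + 1):
        lo = max(0, B - (N - n_prime))
        hi = min(B, n_prime)
        bs = np.arange(lo, hi + 1)
        if 1 <= n_prime <= N - 1:
            blocked = sps.hypergeom.sf(bs - 1, N, B, n_prime) <= thresh
        else:
            blocked = np.zeros(bs.size, dtype=bool)
        for b, is_blocked in zip(bs.tolist(), blocked.tolist()):
            if is_blocked:
                paths[n_prime][b] = 0
                continue
            total = paths[n_prime - 1][b]
            if b > 0:
                total += paths[n_prime - 1][b - 1]
            paths[n_prime][b] = total
    surviving = paths[N][B]
    return float(1 - surviving / comb(N, B))


def fishers_product(p1: float, p2: float) -> float:
    """Combine two p-values by Fisher's product method.

    p = P(chi2_4 >= -2 (ln p1 + ln p2)). Zero inputs are clamped to the
    smallest positive float with a warning.
    """
    ps = []
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-values must lie in [0, 1], got {p}")
        if p == 0.0:
            warnings.warn(
                "zero p-value clamped to smallest positive float in "
                "Fisher's product",
                RuntimeWarning,
                stacklevel=2,
            )
            p = np.nextafter(0.0, 1.0)
        ps.append(p)
    chi2 = -2.0 * (math.log(ps[0]) + math.log(ps[1]))
    return float(sps.chi2.sf(chi2, df=4))


def hypergeom_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    skip_disjoint: bool = True,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with ``universe`` first; sets with no member in
    the universe are skipped with a warning (or raise when
    ``skip_disjoint`` is False). BH adjustment runs across all tested
    sets. Returns a DataFrame sorted by term id with columns
    term/k/K/n/N/p/padj.
    """
    query = set(query) & set(universe)
    N = len(universe)
    n = len(query)
    rows = []
    for term in sorted(gene_sets):
        members = set(gene_sets[term]) & set(universe)
        if not members:
            if not skip_disjoint:
                raise ValueError(f"gene set {term!r} disjoint from universe")
            warnings.warn(
                f"gene set {term!r} has no member in the universe; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        k = len(query & members)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": len(members),
                "n": n,
                "N": N,
                "p": hypergeom_tail(k, len(members), n, N),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
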