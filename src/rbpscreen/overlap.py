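"""Gene-set overlap statistics: hypergeometric enrichment, Venn counts, BH adjustment.

Every overlap claim in the screen — shared ncRNA targets between strains,
stability changes versus expression changes, bound versus regulated RNAs —
reduces to the same question: is the intersection of two gene sets drawn from
a common universe larger than chance?  The observed overlap k of sets of
sizes n1 and n2 in a universe of size N is compared with the hypergeometric
null; the expected overlap is n1*n2/N (the number printed in brackets in
Venn diagrams).

The universe must be explicit for every comparison and identical between the
two sets: the screen switches between coding genes, ncRNAs and introns, and
silently intersecting mismatched universes would change N and hence every
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GeneSet", "OverlapResult", "overlap_test", "venn_report", "bh_adjust"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.members <= self.universe:
            extra = sorted(self.members - self.universe)[:3]
            raise ValueError(f"set {self.name!r} has members outside its universe, e.g. {extra}")


@dataclass(frozen=True)
class OverlapResult:
    k: int
    expected: float
    p_value: float
    n1: int
    n2: int
    N: int


def overlap_test(a: GeneSet, b: GeneSet, alternative: str = "greater") -> OverlapResult:
    """Hypergeometric test of the overlap between two gene sets.

    ``alternative="greater"`` (the default) gives the upper-tail enrichment
    p-value P(X >= k); ``"two-sided"`` uses Fisher's exact test on the
    corresponding 2x2 table.  Mismatched universes raise rather than being
    silently intersected.
    """
    if a.universe != b.universe:
        raise ValueError(
            f"universes differ (|a|={len(a.universe)}, |b|={len(b.universe)}); "
            "overlap p-values are only meaningful on a shared universe"
        )
    N = len(a.universe)
    n1, n2 = len(a.members), len(b.members)
    k = len(a.members & b.members)
    expected = n1 * n2 / N if N else 0.0
    if alternative == "greater":
        # P(X >= k) for X ~ Hypergeom(N, n1, n2)
        p = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    elif alternative == "two-sided":
        table = [[k, n1 - k], [n2 - k, N - n1 - n2 + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return OverlapResult(k=k, expected=round(expected, 2), p_value=p, n1=n1, n2=n2, N=N)


def venn_report(a: GeneSet, b: GeneSet) -> dict:
    """Pairwise Venn partition plus the overlap test.

    Returns ``{"a_only", "b_only", "both", "test": OverlapResult}``; the three
    counts partition the union of the two sets.
    """
    res = overlap_test(a, b)
    both = len(a.members & b.members)
    return {
        "a_only": len(a.members) - both,
        "b_only": len(b.members) - both,
        "both": both,
        "test": res,
    }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
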