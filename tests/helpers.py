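"""Independent oracles and small builders shared across tests.

The oracles here deliberately re-derive quantities by direct
enumeration (running-sum walk, exact hypergeometric tail with integer
arithmetic) so they stay independent of the implementation paths they
check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Sequence

from pylogs.ranking import RankedGene, RankedGeneList


def brute_force_v(is_member: Sequence[bool], statistic: str = "ks") -> float:
    """Walk the ranked list and track the maximum positive running sum."""
    n = len(is_member)
    m = sum(is_member)
    assert 0 < m < n
    total = 0.0 if statistic == "ks" else 0
    best = 0.0 if statistic == "ks" else 0
    for hit in is_member:
        if statistic == "ks":
            total += 1.0 / m if hit else -1.0 / (n - m)
        else:
            total += (n - m) if hit else -m
        if total > best:
            best = total
    return float(best)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n), via integer arithmetic."""
    lo = max(0, n + K - N)
    hi = min(n, K)
    total = comb(N, n)
    tail = sum(comb(K, x) * comb(N - K, n - x) for x in range(max(k, lo), hi + 1))
    return float(Fraction(tail, total))


def ranked_from_ids(ids: Sequence[str]) -> RankedGeneList:
    """A ranked list with the given gene order and placeholder scores."""
    return RankedGeneList(
        [RankedGene(g, raw_cm=float(i), score=float(i), rank=i + 1) for i, g in enumerate(ids)]
    )
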