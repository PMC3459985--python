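"""Hypergeometric gene-list overlap statistics.

Given two gene lists of sizes m and n drawn from a universe of N genes
with k genes in common, the upper-tail probability
``P(X >= k) = sum_{i>=k} C(m,i) C(N-m,n-i) / C(N,n)`` measures how
surprising the observed co-occurrence is under independent draws.
"""

from __future__ import annotations

from scipy import stats

from .model import OverlapResult


def hypergeom_overlap(
    universe_size: int,
    list_a_size: int,
    list_b_size: int,
    overlap: int,
    tail: str = "upper",
) -> OverlapResult:
    """Hypergeometric overlap probability of two gene lists.

    ``tail='upper'`` (default) gives P(X >= k); ``tail='point'`` gives the
    point probability P(X = k).  Symmetric in the two list sizes.
    """
    N, m, n, k = universe_size, list_a_size, list_b_size, overlap
    if N <= 0:
        raise ValueError(f"universe_size must be positive, got {N}")
    if not (0 <= m <= N):
        raise ValueError(f"list_a_size must lie in [0, universe_size], got {m}")
    if not (0 <= n <= N):
        raise ValueError(f"list_b_size must lie in [0, universe_size], got {n}")
    if not (0 <= k <= min(m, n)):
        raise ValueError(
            f"overlap must lie in [0, min(list sizes)] = [0, {min(m, n)}], got {k}"
        )
    dist = stats.hypergeom(M=N, n=m, N=n)
    if tail == "upper":
        p = float(dist.sf(k - 1))
    elif tail == "point":
        p = float(dist.pmf(k))
    else:
        raise ValueError(f"tail must be 'upper' or 'point', got {tail!r}")
    p = min(max(p, 0.0), 1.0)
    return OverlapResult(
        universe_size=N, list_a_size=m, list_b_size=n, overlap=k,
        p_value=p, direction="over",
    )


def overlap_from_lists(
    universe: set[str] | list[str], list_a, list_b, tail: str = "upper"
) -> OverlapResult:
    """Convenience wrapper taking gene id collections instead of sizes."""
    uni = set(universe)
    a = set(list_a) & uni
    b = set(list_b) & uni
    return hypergeom_overlap(len(uni), len(a), len(b), len(a & b), tail=tail)
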