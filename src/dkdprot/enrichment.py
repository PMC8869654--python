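"""Hypergeometric over-representation analysis with BH correction.

For a query list of proteins drawn from a quantified background of size N, a
gene set with K background members and k query members is scored with the
two-sided hypergeometric p-value (doubled smaller tail, capped at 1) and the
set of p-values is adjusted by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["EnrichmentRecord", "hypergeom_pvalue", "bh_adjust", "enrich"]


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    k: int  # query members in the set
    K: int  # background members in the set
    n: int  # query size
    N: int  # background size
    p_value: float
    p_adjusted: float
    members_hit: tuple[str, ...]
    significant: bool


def hypergeom_pvalue(k: int, K: int, n: int, N: int, two_sided: bool = True) -> float:
    """Hypergeometric p-value for k of n drawn query members falling in a set
    of K among N background identifiers.

    Two-sided (default): min(1, 2 * min(P(X >= k), P(X <= k))).  One-sided:
    the enrichment (upper) tail P(X >= k).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    upper = float(hypergeom.sf(k - 1, N, K, n))
    if not two_sided:
        return min(upper, 1.0)
    lower = float(hypergeom.cdf(k, N, K, n))
    return float(min(1.0, 2.0 * min(upper, lower)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def enrich(
    query,
    background,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> list[EnrichmentRecord]:
    """Score every gene set against a query drawn from a background universe.

    Set members are intersected with the background before testing; sets
    with no background member are skipped.  Records are sorted by adjusted
    then raw p-value.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(f"query identifiers outside background: {sorted(stray)[:5]}")
    N = len(background)
    n = len(query)
    tested: list[tuple[str, int, int, tuple[str, ...]]] = []
    for name in sets.names():
        members = sets.members(name) & background
        if not members:
            continue
        hit = members & query
        tested.append((name, len(hit), len(members), tuple(sorted(hit))))
    pvals = [hypergeom_pvalue(k, K, n, N, two_sided=two_sided) for _, k, K, _ in tested]
    adj = bh_adjust(pvals)
    records = [
        EnrichmentRecord(
            set_name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            p_adjusted=float(a),
            members_hit=hit,
            significant=bool(a <= alpha),
        )
        for (name, k, K, hit), p, a in zip(tested, pvals, adj)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.p_value, r.set_name))
    return records
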