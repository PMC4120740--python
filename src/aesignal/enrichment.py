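"""Hypergeometric group enrichment over the inferred AE hierarchy.

After detection, each flagged AE term is propagated to every asserted-or-
inferred ancestor (the classifier must have been run so that anatomy groups
receive their reasoned children).  For a group with K universe terms at or
under it, of which k are flagged out of n flagged terms in a universe of N,
the upper-tail hypergeometric probability P(X >= k) measures whether hits
concentrate under the group more than chance would allow; Benjamini-
Hochberg adjustment controls the false discovery rate across groups.  The
universe is the set of AE terms actually observed in the dataset, and groups
covering fewer than two universe terms are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Dict, Iterable, List, Sequence, Set

from statsmodels.stats.multitest import multipletests

from .errors import OntologyError
from .ontology import Ontology, TermId


@dataclass
class EnrichmentRow:
    group: TermId
    label: str
    k: int  # flagged terms at or under the group
    K: int  # universe terms at or under the group
    n: int  # flagged terms overall
    N: int  # universe size
    p: float
    q: float


def propagate_to_ancestors(
    ontology: Ontology, terms: Iterable[TermId]
) -> Dict[TermId, Set[TermId]]:
    """Map each group to the input terms at or under it.

    Every input term contributes once to itself and to each of its asserted-
    or-inferred ancestors, regardless of how many paths lead there.
    """
    out: Dict[TermId, Set[TermId]] = {}
    for term in terms:
        if term not in ontology:
            raise OntologyError(f"unknown term id: {term!r}")
        for group in ontology.ancestors(term, include_inferred=True) | {term}:
            out.setdefault(group, set()).add(term)
    return out


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated in integer arithmetic (sum of C(K,i)*C(N-K,n-i) over C(N,n)),
    so the result is correctly rounded.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return float(Fraction(numerator, comb(N, n)))


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    pvals = list(pvalues)
    if not pvals:
        return []
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def enrich_groups(
    ontology: Ontology,
    significant: Set[TermId],
    universe: Set[TermId],
    min_group_size: int = 2,
) -> List[EnrichmentRow]:
    """One row per ontology group covering >= ``min_group_size`` universe
    terms, sorted by ascending p (ties by group id)."""
    significant = set(significant)
    universe = set(universe)
    if not significant <= universe:
        extra = sorted(significant - universe)
        raise ValueError(f"significant terms outside the universe: {extra}")
    if not significant:
        return []
    membership = propagate_to_ancestors(ontology, universe)
    flagged = propagate_to_ancestors(ontology, significant)
    N, n = len(universe), len(significant)
    rows: List[EnrichmentRow] = []
    for group, members in membership.items():
        K = len(members)
        if K < min_group_size:
            continue
        k = len(flagged.get(group, ()))
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append(
            EnrichmentRow(
                group=group,
                label=ontology.label(group),
                k=k,
                K=K,
                n=n,
                N=N,
                p=p,
                q=1.0,
            )
        )
    rows.sort(key=lambda r: (r.p, r.group))
    qvalues = bh_adjust([r.p for r in rows])
    for row, q in zip(rows, qvalues):
        row.q = q
    return rows
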