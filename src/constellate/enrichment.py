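"""Hub-protein enrichment with the hybrid score and per-level ranking.

Enrichment of a query protein set against a named hub interactome is judged
with the one-sided hypergeometric upper tail (the Fisher's-exact convention of
web enrichment tools): with a universe of N proteins of which K belong to the
hub and a query of n, the probability of observing an overlap of at least k by
chance.  The hybrid score combines effect size and surprise:

    H = k * (-log10 p),    H = 0 when k = 0.

Summing hybrid scores over a panel of target hubs (e.g. the DNA-damage-
response hubs PRKDC, TP53, PARP1, TOP1) and counting hubs enriched at a given
alpha ranks perturbation levels by how strongly they engage that panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .io_formats import ConstellateError, GeneID, GeneSetCollection, SpecError, normalize_gene_ids

__all__ = [
    "DEFAULT_DDR_TARGETS",
    "P_FLOOR",
    "EnrichmentResult",
    "EnrichmentSummary",
    "hypergeom_upper_tail",
    "hybrid_score",
    "enrich_set",
    "summarize_hubs",
    "rank_levels",
]

logger = logging.getLogger(__name__)

#: DNA-damage-response hubs used by default when ranking perturbation levels.
DEFAULT_DDR_TARGETS: tuple[str, ...] = ("PRKDC", "TP53", "PARP1", "TOP1")

#: Probabilities are clamped to this floor before taking -log10, so scores stay finite.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class EnrichmentResult:
    hub: str
    k: int  # overlap count
    n: int  # query size (within universe)
    K: int  # hub size
    N: int  # universe size
    p: float  # one-sided hypergeometric upper-tail probability
    hybrid: float  # k * (-log10 p); 0 when k == 0


@dataclass(frozen=True)
class EnrichmentSummary:
    query: str
    occurrence_count: int  # number of target hubs with p <= alpha
    hybrid_total: float  # sum of hybrid scores over target hubs
    alpha: float


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n).

    N: universe size, K: hub size, n: query size, k: observed overlap.
    Tails too small for double precision are floored at ``P_FLOOR`` so the
    returned probability is always positive.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise SpecError(f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P[X >= k]; scipy's parametrization is (M=N, n=K, N=n)
    return max(float(hypergeom.sf(k - 1, N, K, n)), P_FLOOR)


def hybrid_score(k: int, p: float, p_floor: float = P_FLOOR) -> float:
    """k * (-log10 p); defined as 0 when k == 0 regardless of p."""
    if k < 0:
        raise SpecError(f"negative overlap count {k}")
    if k == 0:
        return 0.0
    if p <= 0.0 or p > 1.0:
        raise SpecError(f"probability {p} outside (0,1]")
    return k * (-math.log10(max(p, p_floor)))


def enrich_set(
    query: Iterable[str],
    hubs: GeneSetCollection,
    query_name: str = "query",
) -> list[EnrichmentResult]:
    """Enrichment of a query set against every hub in the collection.

    Query members outside the collection's universe are dropped (with a
    logged warning count).  Results are sorted by ascending p, then
    descending hybrid, then hub name, so ordering is deterministic.
    """
    q = normalize_gene_ids(query)
    dropped = len(q - hubs.universe)
    if dropped:
        logger.warning("%s: %d query members outside the universe were dropped", query_name, dropped)
    q &= hubs.universe
    if not q:
        raise ConstellateError(f"{query_name}: query empty after universe intersection")
    N = len(hubs.universe)
    n = len(q)
    results = []
    for hub_name, members in hubs.sets.items():
        k = len(q & members)
        p = hypergeom_upper_tail(k, n, len(members), N)
        results.append(
            EnrichmentResult(hub=hub_name, k=k, n=n, K=len(members), N=N, p=p, hybrid=hybrid_score(k, p))
        )
    results.sort(key=lambda r: (r.p, -r.hybrid, r.hub))
    return results


def summarize_hubs(
    results: Sequence[EnrichmentResult],
    target_hubs: Sequence[str],
    alpha: float = 0.05,
    query_name: str = "query",
) -> EnrichmentSummary:
    """Occurrence count (hubs with p <= alpha) and total hybrid score over target hubs."""
    by_hub = {r.hub: r for r in results}
    missing = [h for h in target_hubs if h not in by_hub]
    if missing:
        raise KeyError(f"unknown hub name(s) {missing}")
    chosen = [by_hub[h] for h in target_hubs]
    return EnrichmentSummary(
        query=query_name,
        occurrence_count=sum(1 for r in chosen if r.p <= alpha),
        hybrid_total=sum(r.hybrid for r in chosen),
        alpha=alpha,
    )


def rank_levels(
    level_sets: Mapping[str, Iterable[str]],
    hubs: GeneSetCollection,
    target_hubs: Sequence[str] = DEFAULT_DDR_TARGETS,
    alpha: float = 0.05,
) -> list[tuple[str, EnrichmentSummary]]:
    """Rank perturbation levels by total hybrid score over the target hubs.

    Descending hybrid_total; ties broken by descending occurrence_count, then
    level label.
    """
    if not level_sets:
        raise SpecError("rank_levels needs at least one level")
    ranked = []
    for level, members in level_sets.items():
        summary = summarize_hubs(enrich_set(members, hubs, query_name=level), target_hubs, alpha, query_name=level)
        ranked.append((level, summary))
    ranked.sort(key=lambda item: (-item[1].hybrid_total, -item[1].occurrence_count, item[0]))
    return ranked
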