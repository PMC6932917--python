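"""Multi-interrogator cosine profiling, group contrasts and percentile ranking.

A panel of interrogation phrases (e.g. age-related versus non-age-related
disease concepts) is scored against a gene set, giving a gene x interrogator
cosine matrix.  Group contrasts (aging vs non-aging) use a two-sample
Student's t-test on per-gene summed group scores.  The "disease continuum"
is the union of genes associated (explicitly or implicitly) with a battery of
disease interrogators; within it, each gene's correlation count — the number
of therapeutic interrogators it scores above a counting cutoff — is ranked,
and genes strictly above the chosen percentile of counts are the candidate
therapeutic targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ConstellateError, GeneID, SpecError
from .lsi import AssociationThresholds, DEFAULT_THRESHOLDS, SemanticModel, interrogate, query_cosine

__all__ = [
    "AGING_TERMS",
    "NON_AGING_TERMS",
    "CosineProfile",
    "ContinuumResult",
    "cosine_profile",
    "group_mean_scores",
    "group_difference_test",
    "build_disease_continuum",
    "therapeutic_correlation_counts",
    "percentile_hits",
    "run_continuum",
]

logger = logging.getLogger(__name__)

#: Age-related interrogation concepts used in the study's semantic profiling.
AGING_TERMS: tuple[str, ...] = (
    "Neurodegeneration",
    "Cognitive impairment",
    "Senescence",
    "Parkinson's Disease",
    "Amyotrophic lateral sclerosis",
    "Alzheimer's Disease",
)

#: Matched non-age-related control concepts.
NON_AGING_TERMS: tuple[str, ...] = (
    "Tuberculosis",
    "Spina Bifida",
    "Asthma",
    "Tourette syndrome",
    "ADHD",
    "Achondroplasia",
)


@dataclass(frozen=True)
class CosineProfile:
    """Gene x interrogator cosine score matrix with optional term grouping."""

    scores: pd.DataFrame  # index: genes, columns: interrogator phrases
    groups: Mapping[str, tuple[str, ...]]
    thresholds: AssociationThresholds

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", {g: tuple(ts) for g, ts in self.groups.items()})
        seen: dict[str, str] = {}
        for group, terms in self.groups.items():
            for term in terms:
                if term in seen:
                    raise SpecError(f"interrogator {term!r} assigned to both {seen[term]!r} and {group!r}")
                if term not in self.scores.columns:
                    raise SpecError(f"group {group!r} references unknown interrogator {term!r}")
                seen[term] = group


@dataclass(frozen=True)
class ContinuumResult:
    """Disease-continuum membership with therapeutic correlation ranking."""

    continuum: frozenset[GeneID]
    correlation_counts: Mapping[GeneID, int]
    quantile_q: float
    quantile_value: int
    hits: tuple[GeneID, ...]  # genes with count strictly above the quantile


def cosine_profile(
    model: SemanticModel,
    genes: Iterable[GeneID],
    interrogators: Mapping[str, Sequence[str]] | Sequence[str],
    th: AssociationThresholds = DEFAULT_THRESHOLDS,
) -> CosineProfile:
    """Score every gene against every interrogator phrase.

    ``interrogators`` is either a flat phrase list (no grouping) or a mapping
    from group name to phrase list.  Genes are ordered sorted, interrogators
    in their given order.  Genes absent from the model are dropped with a
    warning; an empty gene list is an error.
    """
    if isinstance(interrogators, Mapping):
        groups = {g: tuple(ts) for g, ts in interrogators.items()}
        phrases: list[str] = [t for ts in groups.values() for t in ts]
    else:
        groups = {}
        phrases = list(interrogators)
    if len(set(phrases)) != len(phrases):
        raise SpecError("duplicate interrogator phrases")
    gene_list = sorted(set(genes))
    if not gene_list:
        raise SpecError("empty gene list")
    known = [g for g in gene_list if g in set(model.genes)]
    if len(known) < len(gene_list):
        logger.warning("%d gene(s) absent from the model were dropped", len(gene_list) - len(known))
    if not known:
        raise ConstellateError("no requested gene is present in the model")
    columns = {}
    for phrase in phrases:
        scores = query_cosine(model, phrase)
        columns[phrase] = [scores[g] for g in known]
    frame = pd.DataFrame(columns, index=known)
    return CosineProfile(scores=frame, groups=groups, thresholds=th)


def group_mean_scores(profile: CosineProfile) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene mean cosine per group, plus group grand means over genes."""
    if not profile.groups:
        raise SpecError("profile has no interrogator groups")
    per_gene = pd.DataFrame(
        {group: profile.scores[list(terms)].mean(axis=1) for group, terms in profile.groups.items()}
    )
    grand = {group: float(per_gene[group].mean()) for group in per_gene.columns}
    return per_gene, grand


def group_difference_test(
    profile: CosineProfile,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test on per-gene summed group scores (two-sided).

    Observations are, for each gene, the sum of its cosines over the group's
    interrogators.  Student's equal-variance t by default; Welch optional.
    Identical degenerate samples give (0.0, 1.0).
    """
    for g in (group_a, group_b):
        if g not in profile.groups or not profile.groups[g]:
            raise SpecError(f"unknown or empty group {g!r}")
    a = profile.scores[list(profile.groups[group_a])].sum(axis=1).to_numpy()
    b = profile.scores[list(profile.groups[group_b])].sum(axis=1).to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise SpecError("need >=2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ConstellateError("zero variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def build_disease_continuum(
    model: SemanticModel,
    disease_terms: Sequence[str],
    th: AssociationThresholds = DEFAULT_THRESHOLDS,
) -> frozenset[GeneID]:
    """Union over disease terms of genes associated at >= the implicit cutoff."""
    if not disease_terms:
        raise SpecError("need at least one disease term")
    out: frozenset[GeneID] = frozenset()
    for term in disease_terms:
        out |= interrogate(model, term, th)
    return out


def therapeutic_correlation_counts(
    model: SemanticModel,
    continuum: Iterable[GeneID],
    therapeutic_terms: Sequence[str],
    counting_cutoff: float = DEFAULT_THRESHOLDS.explicit_cutoff,
) -> dict[GeneID, int]:
    """Per continuum gene: number of therapeutic terms scoring >= the cutoff."""
    members = sorted(set(continuum))
    if not members:
        raise SpecError("empty continuum")
    if not therapeutic_terms:
        raise SpecError("need at least one therapeutic term")
    counts = {g: 0 for g in members}
    for term in therapeutic_terms:
        scores = query_cosine(model, term)
        for g in members:
            if scores.get(g, 0.0) >= counting_cutoff:
                counts[g] += 1
    return counts


def percentile_hits(counts: Mapping[GeneID, int], q: float = 0.99) -> ContinuumResult:
    """Genes whose correlation count strictly exceeds the q-quantile of counts.

    The quantile uses the nearest-rank definition (value at rank ceil(q * n)
    of the ascending counts); hits are ordered by descending count, then
    gene label.  With all counts equal the hit list is empty.
    """
    if not counts:
        raise SpecError("empty count map")
    if not (0.0 < q < 1.0):
        raise SpecError(f"quantile q={q} outside (0,1)")
    values = sorted(counts.values())
    rank = max(1, math.ceil(q * len(values)))
    qvalue = values[rank - 1]
    hits = sorted(
        (g for g, c in counts.items() if c > qvalue),
        key=lambda g: (-counts[g], g),
    )
    return ContinuumResult(
        continuum=frozenset(counts),
        correlation_counts=dict(counts),
        quantile_q=q,
        quantile_value=qvalue,
        hits=tuple(hits),
    )


def run_continuum(
    model: SemanticModel,
    disease_terms: Sequence[str],
    therapeutic_terms: Sequence[str],
    th: AssociationThresholds = DEFAULT_THRESHOLDS,
    counting_cutoff: float | None = None,
    q: float = 0.99,
) -> ContinuumResult:
    """The full continuum pipeline: membership, correlation counts, percentile hits."""
    cutoff = th.explicit_cutoff if counting_cutoff is None else counting_cutoff
    continuum = build_disease_continuum(model, disease_terms, th)
    if not continuum:
        raise ConstellateError("disease continuum is empty at the given thresholds")
    counts = therapeutic_correlation_counts(model, continuum, therapeutic_terms, cutoff)
    return percentile_hits(counts, q=q)
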