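"""Seeded generators emulating the statistical structure of the study's inputs.

Every generator is a pure function of its spec (seed included): the pseudo-
random bit stream is numpy's PCG64 (``numpy.random.default_rng``), so a seed
reproduces the same output byte-for-byte across runs and platforms.  Synthetic
universe members are labelled ``G000001`` style, deliberately distinct from
real gene symbols.

Each generator returns its planted ground truth alongside the data, so every
downstream stage can be tested for exact parameter recovery at the generator's
own thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    Corpus,
    Document,
    GeneID,
    GeneSetCollection,
    QuantRecord,
    QuantTable,
    SpecError,
    normalize_gene_id,
)
from .partition import DEFAULT_CRITERIA, SignificanceCriteria

__all__ = [
    "REFERENCE_HUB_SIZES",
    "DEFAULT_LEVELS",
    "REFERENCE_LEVEL_TOTALS",
    "PlantedQuantSpec",
    "PlantedCorpusSpec",
    "RandomSetSpec",
    "synthetic_universe",
    "generate_quant_table",
    "generate_hub_collection",
    "generate_interactome_pair",
    "generate_corpus",
    "generate_random_gene_sets",
]

#: Curated-interactome hub cardinalities used throughout the study: three
#: oxidative-stress hubs (G3BP1, SIRT1, SOD1) and six DNA-damage-response hubs.
REFERENCE_HUB_SIZES: dict[str, int] = {
    "G3BP1": 299,
    "SIRT1": 251,
    "SOD1": 294,
    "PRKDC": 283,
    "H2AFX": 300,
    "MDM2": 299,
    "MDC1": 198,
    "TP53": 300,
    "BRCA1": 301,
}

#: The five ectopic-expression levels of the constellation design.
DEFAULT_LEVELS: tuple[str, ...] = ("0.5ug", "1ug", "2ug", "5ug", "10ug")

#: Per-level counts of significantly altered proteins reported by the study.
REFERENCE_LEVEL_TOTALS: dict[str, int] = {
    "0.5ug": 183,
    "1ug": 293,
    "2ug": 297,
    "5ug": 278,
    "10ug": 269,
}


def synthetic_universe(size: int, prefix: str = "G") -> list[GeneID]:
    """Synthetic gene labels G000001..G{size}, distinct from real symbols."""
    return [f"{prefix}{i:06d}" for i in range(1, size + 1)]


# ---------------------------------------------------------------------------
# Quantification tables with planted significant proteins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedQuantSpec:
    """Spec for an iTRAQ-style per-level ratio table with planted effects.

    ``frac_significant_per_level`` may be one probability (same at every
    level) or one per level — the latter reproduces unequal per-level totals
    such as the study's 183/293/297/278/269.  ``frac_shared_all_levels`` of
    the proteins are planted as significant at every level (the common core).
    """

    n_proteins: int = 1000
    levels: tuple[str, ...] = DEFAULT_LEVELS
    frac_significant_per_level: float | tuple[float, ...] = 0.25
    frac_shared_all_levels: float = 0.05
    effect_log2: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0

    def fractions(self) -> tuple[float, ...]:
        f = self.frac_significant_per_level
        if isinstance(f, (int, float)):
            return tuple(float(f) for _ in self.levels)
        f = tuple(float(x) for x in f)
        if len(f) != len(self.levels):
            raise SpecError("one significance fraction per level required")
        return f

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise SpecError("n_proteins must be >= 1")
        fracs = self.fractions()
        for fr in fracs:
            if not (0.0 <= fr <= 1.0):
                raise SpecError(f"significance fraction {fr} outside [0,1]")
        if not (0.0 <= self.frac_shared_all_levels <= 1.0):
            raise SpecError("frac_shared_all_levels outside [0,1]")
        if self.frac_shared_all_levels > min(fracs, default=0.0):
            raise SpecError("frac_shared_all_levels exceeds a per-level fraction")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


def generate_quant_table(
    spec: PlantedQuantSpec,
    criteria: SignificanceCriteria = DEFAULT_CRITERIA,
) -> tuple[QuantTable, dict[str, frozenset[GeneID]]]:
    """Generate a quant table plus the planted per-level significant sets.

    Planted-significant records get p-values below ``criteria.max_p`` and
    |log2 ratio| at least ``criteria.min_abs_log2_ratio`` (centred on
    ``effect_log2`` with Gaussian noise, random sign); all other records get
    p-values strictly above ``criteria.max_p`` and near-zero ratios, so
    filtering at the same criteria recovers the planted truth exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    proteins = np.array(synthetic_universe(spec.n_proteins))
    fracs = spec.fractions()
    n_sig = [round(fr * spec.n_proteins) for fr in fracs]
    n_shared = round(spec.frac_shared_all_levels * spec.n_proteins)
    if any(n_shared > k for k in n_sig):
        raise SpecError("shared core larger than a per-level significant count")

    shared_idx = rng.choice(spec.n_proteins, size=n_shared, replace=False)
    shared = set(shared_idx.tolist())
    rest = np.array(sorted(set(range(spec.n_proteins)) - shared))

    truth: dict[str, frozenset[GeneID]] = {}
    records: list[QuantRecord] = []
    lo_null = np.nextafter(criteria.max_p, 1.0)  # keep nulls strictly above max_p
    extras_so_far: set[int] | None = None
    for idx_level, (level, k) in enumerate(zip(spec.levels, n_sig)):
        pool = rest
        if idx_level == len(spec.levels) - 1 and extras_so_far:
            # keep the planted core unambiguous: no non-planted protein may be
            # significant at every level by chance
            pool = np.array(sorted(set(rest.tolist()) - extras_so_far))
        n_extra = k - n_shared
        if n_extra > len(pool):
            raise SpecError("per-level significant count infeasible for n_proteins")
        extra = rng.choice(pool, size=n_extra, replace=False) if n_extra > 0 else np.array([], dtype=int)
        extra_set = set(extra.tolist())
        extras_so_far = extra_set if extras_so_far is None else (extras_so_far & extra_set)
        sig_idx = shared | extra_set
        truth[level] = frozenset(proteins[i] for i in sig_idx)
        for i in range(spec.n_proteins):
            if i in sig_idx:
                mag = max(criteria.min_abs_log2_ratio, spec.effect_log2 + rng.normal(0.0, spec.noise_sd))
                lr = float(rng.choice([-1.0, 1.0]) * mag)
                p = float(rng.uniform(0.0, criteria.max_p))
            else:
                lr = float(rng.normal(0.0, spec.noise_sd))
                p = float(rng.uniform(lo_null, 1.0))
            records.append(QuantRecord(protein=proteins[i], level=level, log2_ratio=lr, p_value=p))
    return QuantTable(records=tuple(records)), truth


# ---------------------------------------------------------------------------
# Hub interactome collections and query interactome pairs
# ---------------------------------------------------------------------------


def generate_hub_collection(
    hub_sizes: Mapping[str, int] | None = None,
    universe_size: int = 20000,
    seed: int = 0,
    disjoint: bool = False,
) -> GeneSetCollection:
    """Sample named hub interactomes of exact cardinalities from a synthetic universe.

    Defaults to the study's nine curated-hub cardinalities over a genome-scale
    (20,000 member) universe.  With ``disjoint=True`` the hubs are sampled
    without replacement globally, so they are mutually disjoint — the layout
    overlap planting requires.
    """
    hub_sizes = dict(REFERENCE_HUB_SIZES if hub_sizes is None else hub_sizes)
    for name, size in hub_sizes.items():
        if size > universe_size:
            raise SpecError(f"hub {name!r} size {size} exceeds universe {universe_size}")
    rng = np.random.default_rng(seed)
    universe = np.array(synthetic_universe(universe_size))
    if disjoint:
        total = sum(hub_sizes.values())
        if total > universe_size:
            raise SpecError("disjoint hubs need a universe at least as large as their total size")
        draw = rng.choice(universe, size=total, replace=False)
        sets = {}
        offset = 0
        for name, size in hub_sizes.items():
            sets[name] = frozenset(draw[offset : offset + size].tolist())
            offset += size
    else:
        sets = {
            name: frozenset(rng.choice(universe, size=size, replace=False).tolist())
            for name, size in hub_sizes.items()
        }
    return GeneSetCollection(sets=sets, universe=frozenset(universe.tolist()))


def generate_interactome_pair(
    collection: GeneSetCollection,
    control_size: int = 47,
    stress_size: int = 268,
    control_overlaps: Mapping[str, int] | None = None,
    stress_overlaps: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[frozenset[GeneID], frozenset[GeneID]]:
    """Generate a (control, stress) query-interactome pair with planted overlaps.

    ``*_overlaps`` map target-set names in ``collection`` to the exact number
    of that target's members to plant in the query.  The default sizes (47
    control, 268 stress) mirror the study's AP-MS interactomes.  Referenced
    targets must be mutually disjoint so the planted counts are unambiguous;
    non-planted members are drawn from outside every referenced target.
    """
    control_overlaps = dict(control_overlaps or {})
    stress_overlaps = dict(stress_overlaps or {})
    names = sorted(set(control_overlaps) | set(stress_overlaps))
    for name in names:
        if name not in collection:
            raise SpecError(f"unknown target set {name!r}")
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if collection[a] & collection[b]:
                raise SpecError(f"planting targets {a!r} and {b!r} overlap; must be disjoint")
    blocked = frozenset().union(*(collection[n] for n in names)) if names else frozenset()
    pool = np.array(sorted(collection.universe - blocked))
    rng = np.random.default_rng(seed)

    def build(size: int, overlaps: Mapping[str, int]) -> frozenset[GeneID]:
        planted: set[GeneID] = set()
        for name in sorted(overlaps):
            count = overlaps[name]
            target = sorted(collection[name])
            if count > min(len(target), size):
                raise SpecError(f"cannot plant {count} members of {name!r}")
            planted |= set(rng.choice(target, size=count, replace=False).tolist())
        n_fill = size - len(planted)
        if n_fill < 0:
            raise SpecError("planted overlaps exceed query size")
        if n_fill > len(pool):
            raise SpecError("universe too small to fill query outside planted targets")
        fill = rng.choice(pool, size=n_fill, replace=False).tolist()
        return frozenset(planted) | frozenset(fill)

    return build(control_size, control_overlaps), build(stress_size, stress_overlaps)


# ---------------------------------------------------------------------------
# Gene-tagged corpora with planted gene-term co-occurrence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCorpusSpec:
    """Spec for a toy gene-tagged literature corpus with planted associations.

    Each gene tags ``n_docs_per_gene`` documents.  A planted (gene, term)
    pair makes the term appear in each of the gene's documents with
    probability ``co_occurrence_prob``.  Every document additionally carries
    background noise: each of ``doc_length`` slots is, with probability
    ``background_term_prob``, filled with a token drawn uniformly from the
    filler (non-planted) vocabulary.  Restricting background to filler terms
    keeps planted terms concentrated in their gene's documents, the way a
    gene's marker vocabulary concentrates in its own abstracts; the sparse
    high-dimensional filler background emulates the lexical heterogeneity of
    real abstracts.  Defaults give planted pairs an explicit association
    (cosine >= 0.2) and leave non-planted pairs below the 0.1 implicit
    cutoff under the semantic engine's default configuration.
    """

    n_genes: int = 20
    n_docs_per_gene: int = 20
    vocab_size: int = 200
    planted: tuple[tuple[GeneID, str, float], ...] = ()
    background_term_prob: float = 0.05
    doc_length: int = 20
    seed: int = 0

    def genes(self) -> list[GeneID]:
        return synthetic_universe(self.n_genes)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_docs_per_gene < 1:
            raise SpecError("need at least one gene and one doc per gene")
        if not (0.0 <= self.background_term_prob <= 1.0):
            raise SpecError("background_term_prob outside [0,1]")
        genes = set(self.genes())
        planted_terms = {t for _, t, _ in self.planted}
        if len(planted_terms) > self.vocab_size:
            raise SpecError("vocabulary too small for the planted terms")
        for gene, term, prob in self.planted:
            if normalize_gene_id(gene) not in genes:
                raise SpecError(f"planted gene {gene!r} not in the synthetic gene list")
            if not (0.0 <= prob <= 1.0):
                raise SpecError("co-occurrence probability outside [0,1]")
            if prob <= self.background_term_prob:
                raise SpecError(
                    f"planted ({gene},{term}): co-occurrence {prob} must exceed "
                    f"background {self.background_term_prob}"
                )

    def planted_terms(self) -> list[str]:
        return sorted({t.lower() for _, t, _ in self.planted})

    def fillers(self) -> list[str]:
        n = self.vocab_size - len(self.planted_terms())
        return [f"w{i:04d}" for i in range(1, n + 1)]

    def vocabulary(self) -> list[str]:
        return self.planted_terms() + self.fillers()


def generate_corpus(
    spec: PlantedCorpusSpec,
) -> tuple[Corpus, dict[tuple[GeneID, str], float]]:
    """Generate a corpus plus the planted (gene, term) -> probability truth table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fillers = np.array(spec.fillers())
    if spec.background_term_prob > 0 and len(fillers) == 0:
        raise SpecError("no filler vocabulary available for background tokens")
    by_gene: dict[GeneID, list[tuple[str, float]]] = {}
    truth: dict[tuple[GeneID, str], float] = {}
    for gene, term, prob in spec.planted:
        g = normalize_gene_id(gene)
        by_gene.setdefault(g, []).append((term.lower(), prob))
        truth[(g, term.lower())] = prob

    docs: list[Document] = []
    for gene in spec.genes():
        pairs = by_gene.get(gene, [])
        for j in range(spec.n_docs_per_gene):
            tokens: list[str] = []
            for term, prob in pairs:
                if rng.random() < prob:
                    tokens.append(term)
            n_bg = int((rng.random(spec.doc_length) < spec.background_term_prob).sum())
            if n_bg:
                tokens.extend(rng.choice(fillers, size=n_bg, replace=True).tolist())
            docs.append(
                Document(doc_id=f"{gene}-d{j:04d}", genes=frozenset([gene]), tokens=tuple(tokens))
            )
    return Corpus(docs=tuple(docs)), truth


# ---------------------------------------------------------------------------
# Size-matched random null sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomSetSpec:
    """Spec for size-matched random protein sets drawn from a universe."""

    size: int
    n_sets: int
    seed: int
    universe: frozenset[GeneID]

    def validate(self) -> None:
        if self.n_sets < 1:
            raise SpecError("n_sets must be >= 1")
        if self.size > len(self.universe):
            raise SpecError(f"set size {self.size} exceeds universe {len(self.universe)}")


def generate_random_gene_sets(spec: RandomSetSpec) -> list[frozenset[GeneID]]:
    """``n_sets`` sets of exactly ``size`` members, sampled without replacement."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    universe = np.array(sorted(spec.universe))
    return [
        frozenset(rng.choice(universe, size=spec.size, replace=False).tolist())
        for _ in range(spec.n_sets)
    ]
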