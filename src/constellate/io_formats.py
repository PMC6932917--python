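"""Readers/writers for the formats the pipeline touches, plus shared domain types.

Gene/protein identifiers are plain uppercase tokens (``GeneID``); gene-set
collections travel as GMT (one named set per tab-separated line); per-level
protein quantification travels as TSV/CSV with a header; gene-tagged document
corpora travel as JSONL.  Every reader normalizes identifiers on the way in so
downstream set algebra never has to worry about case or whitespace.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ConstellateError",
    "InvalidIdentifierError",
    "ParseError",
    "SpecError",
    "GeneID",
    "normalize_gene_id",
    "normalize_gene_ids",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "QuantRecord",
    "QuantTable",
    "read_quant_table",
    "write_quant_table",
    "Document",
    "Corpus",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]


class ConstellateError(Exception):
    """Base class for all errors raised by this package."""


class InvalidIdentifierError(ConstellateError, ValueError):
    """An empty or whitespace-only gene/protein identifier."""


class ParseError(ConstellateError, ValueError):
    """A malformed input file; carries the offending line number when known."""


class SpecError(ConstellateError, ValueError):
    """An infeasible or inconsistent generator / analysis specification."""


#: Gene/protein identifiers are plain strings after normalization.
GeneID = str


def normalize_gene_id(raw: str) -> GeneID:
    """Normalize a raw gene/protein identifier to its canonical token.

    The token is stripped of surrounding whitespace and uppercased with
    standard Unicode uppercasing (ASCII is preserved; e.g. ``"γ-H2AX"`` maps
    to ``"Γ-H2AX"``).  Normalization is idempotent.

    Raises
    ------
    InvalidIdentifierError
        If the identifier is empty after trimming.
    """
    token = raw.strip().upper()
    if not token:
        raise InvalidIdentifierError(f"empty gene identifier: {raw!r}")
    return token


def normalize_gene_ids(raw: Iterable[str]) -> frozenset[GeneID]:
    """Normalize and de-duplicate a collection of identifiers."""
    return frozenset(normalize_gene_id(r) for r in raw)


# ---------------------------------------------------------------------------
# Gene-set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a shared background universe.

    Used for BioGRID-style hub interactomes, disease signatures and
    significance lists alike.  Every member of every set must belong to the
    universe; by default the universe is the union of all sets (callers may
    supply a wider explicit universe, e.g. a whole-genome background).
    """

    sets: Mapping[str, frozenset[GeneID]]
    universe: frozenset[GeneID]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", dict(self.sets))
        object.__setattr__(self, "universe", frozenset(self.universe))
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise SpecError(
                    f"set {name!r} has {len(extra)} members outside the universe"
                )

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        """Build a collection, normalizing members; universe defaults to the union."""
        norm = {name: normalize_gene_ids(members) for name, members in sets.items()}
        if universe is None:
            uni: frozenset[GeneID] = frozenset().union(*norm.values()) if norm else frozenset()
        else:
            uni = normalize_gene_ids(universe)
        return cls(sets=norm, universe=uni)

    def __getitem__(self, name: str) -> frozenset[GeneID]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def with_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(sets=self.sets, universe=normalize_gene_ids(universe))


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (``name<TAB>description<TAB>member...`` per line).

    Members are normalized and de-duplicated.  The universe defaults to the
    union of all members unless an explicit one is given.

    Raises
    ------
    ParseError
        On a line with fewer than three fields or a duplicate set name.
    """
    sets: dict[str, frozenset[GeneID]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0].strip()
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = normalize_gene_ids(m for m in fields[2:] if m.strip())
    return GeneSetCollection.from_sets(sets, universe=universe)


def write_gmt(
    collection: GeneSetCollection,
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write a collection as GMT; members are emitted in sorted order."""
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Quantification tables (TSV/CSV)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantRecord:
    protein: GeneID
    level: str
    log2_ratio: float
    p_value: float


@dataclass(frozen=True)
class QuantTable:
    """Per-protein, per-expression-level quantification records.

    Each record carries the log2 ratio of the protein's abundance at a given
    perturbation level versus control, with an associated p-value.
    ``(protein, level)`` pairs are unique; p-values lie in [0, 1]; ratios are
    finite.
    """

    records: tuple[QuantRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[GeneID, str]] = set()
        for rec in self.records:
            if not (0.0 <= rec.p_value <= 1.0):
                raise SpecError(
                    f"p-value {rec.p_value} outside [0,1] for {rec.protein}/{rec.level}"
                )
            if not math.isfinite(rec.log2_ratio):
                raise SpecError(f"non-finite log2 ratio for {rec.protein}/{rec.level}")
            key = (rec.protein, rec.level)
            if key in seen:
                raise SpecError(f"duplicate (protein, level) pair {key}")
            seen.add(key)

    @property
    def levels(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.level not in out:
                out.append(rec.level)
        return out

    def proteins(self) -> frozenset[GeneID]:
        return frozenset(rec.protein for rec in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


_QUANT_COLUMNS = ("protein", "level", "log2_ratio", "p_value")


def read_quant_table(
    path: str | Path,
    dialect: str = "tsv",
    columns: Mapping[str, str] | None = None,
) -> QuantTable:
    """Read a quantification table from TSV (default) or CSV.

    The header must contain protein, level, log2_ratio and p_value columns;
    alternative header names may be mapped via ``columns`` (canonical -> file).
    """
    if dialect not in ("tsv", "csv"):
        raise SpecError(f"unknown dialect {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    colmap = {c: c for c in _QUANT_COLUMNS}
    if columns:
        colmap.update(columns)
    records: list[QuantRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, no header")
        missing = [colmap[c] for c in _QUANT_COLUMNS if colmap[c] not in reader.fieldnames]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    QuantRecord(
                        protein=normalize_gene_id(row[colmap["protein"]]),
                        level=row[colmap["level"]].strip(),
                        log2_ratio=float(row[colmap["log2_ratio"]]),
                        p_value=float(row[colmap["p_value"]]),
                    )
                )
            except (ValueError, KeyError) as exc:
                if isinstance(exc, SpecError):
                    raise
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return QuantTable(records=tuple(records))


def write_quant_table(table: QuantTable, path: str | Path, dialect: str = "tsv") -> None:
    if dialect not in ("tsv", "csv"):
        raise SpecError(f"unknown dialect {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(_QUANT_COLUMNS)
        for rec in table.records:
            writer.writerow([rec.protein, rec.level, repr(rec.log2_ratio), repr(rec.p_value)])


# ---------------------------------------------------------------------------
# Gene-tagged document corpora (JSONL)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Document:
    doc_id: str
    genes: frozenset[GeneID]
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class Corpus:
    """A collection of gene-tagged documents for semantic indexing.

    Each document carries the set of genes it is tagged with and its token
    sequence (already lowercased/tokenized).  Document ids are unique.
    """

    docs: tuple[Document, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "docs", tuple(self.docs))
        ids = [d.doc_id for d in self.docs]
        if len(ids) != len(set(ids)):
            raise SpecError("duplicate document ids in corpus")

    def genes(self) -> frozenset[GeneID]:
        out: set[GeneID] = set()
        for d in self.docs:
            out |= d.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.docs)

    def __iter__(self):
        return iter(self.docs)


def read_corpus_jsonl(path: str | Path) -> Corpus:
    """Read a corpus from JSONL: one object per line with doc_id, genes, tokens."""
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            for key in ("doc_id", "genes", "tokens"):
                if key not in obj:
                    raise ParseError(f"{path}:{lineno}: missing field {key!r}")
            docs.append(
                Document(
                    doc_id=str(obj["doc_id"]),
                    genes=normalize_gene_ids(obj["genes"]) if obj["genes"] else frozenset(),
                    tokens=tuple(str(t).lower() for t in obj["tokens"]),
                )
            )
    return Corpus(docs=tuple(docs))


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "genes": sorted(doc.genes),
                        "tokens": list(doc.tokens),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
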