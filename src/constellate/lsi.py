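"""Latent-semantic-indexing engine for gene-concept cosine interrogation.

Gene-tagged documents are concatenated into per-gene pseudo-documents, giving
a term x gene count matrix.  The matrix is weighted (log-entropy by default,
the classical LSI choice; smoothed tf-idf as an alternative), factorized with
a truncated SVD, and genes/terms are embedded as singular-value-scaled factor
rows (symmetric scaling: term vectors are U_k S_k, gene vectors are V_k S_k).
An interrogation phrase maps to the sum of its tokens' term vectors; its
cosine against each gene vector is the association score.  In the convention
of literature-indexing tools, a cosine above 0.2 marks an explicit
(literature-stated) association and scores from 0.1 to 0.2 an implicit one;
below 0.1 the association is discarded.

With symmetric scaling, concept-space term-term cosines reproduce the cosines
of the raw weighted matrix's rows at full rank, and gene-gene cosines those of
its columns (W^T W = (VS)(VS)^T and W W^T = (US)(US)^T).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import svd as dense_svd

from .io_formats import ConstellateError, Corpus, GeneID, SpecError

__all__ = [
    "DEFAULT_STOPWORDS",
    "AssociationThresholds",
    "DEFAULT_THRESHOLDS",
    "SemanticModel",
    "tokenize",
    "build_gene_documents",
    "weight_matrix",
    "fit_lsi",
    "fit_corpus",
    "query_cosine",
    "classify_association",
    "interrogate",
    "theoretical_dataset",
    "count_frequencies",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Minimal English stop-word list for frequency counting; user-overridable.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a an and are as at be been but by can did do for from had has have in into
    is it its more not of on or our than that the their then there these this
    to was we were which will with""".split()
)

_TOKEN_SPLIT = re.compile(r"[^0-9a-zA-Z]+")


def tokenize(text: str, min_len: int = 2) -> list[str]:
    """Split on non-alphanumerics, lowercase, drop tokens shorter than min_len."""
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if len(t) >= min_len]


@dataclass(frozen=True)
class AssociationThresholds:
    """Cosine cutoffs separating explicit, implicit and discarded associations.

    Scores strictly above ``explicit_cutoff`` (default 0.2) are explicit;
    scores in [implicit_cutoff, explicit_cutoff] (default lower bound 0.1)
    are implicit; anything below is discarded.  Both boundary scores class as
    implicit.
    """

    implicit_cutoff: float = 0.1
    explicit_cutoff: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.implicit_cutoff <= self.explicit_cutoff <= 1.0):
            raise SpecError(
                f"need 0 <= implicit ({self.implicit_cutoff}) <= explicit "
                f"({self.explicit_cutoff}) <= 1"
            )


DEFAULT_THRESHOLDS = AssociationThresholds()


@dataclass(frozen=True)
class SemanticModel:
    """Rank-k concept space holding singular-value-scaled gene and term vectors."""

    vocabulary: tuple[str, ...]
    genes: tuple[GeneID, ...]
    rank_k: int
    term_vectors: np.ndarray  # (|vocabulary|, k), rows are U_k S_k
    gene_vectors: np.ndarray  # (|genes|, k), rows are V_k S_k
    singular_values: np.ndarray  # (k,), non-increasing
    weighting: str

    def term_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.vocabulary)}


# ---------------------------------------------------------------------------
# Term-gene matrix construction and weighting
# ---------------------------------------------------------------------------


def build_gene_documents(corpus: Corpus) -> pd.DataFrame:
    """Term x gene count matrix from gene-tagged documents.

    Column g sums the token counts of every document tagged with gene g; a
    document tagged with several genes contributes fully to each.  Genes
    appear only if they tag at least one document.
    """
    counts: dict[GeneID, dict[str, int]] = {}
    for doc in corpus:
        for gene in doc.genes:
            col = counts.setdefault(gene, {})
            for tok in doc.tokens:
                col[tok] = col.get(tok, 0) + 1
    if not counts:
        raise ConstellateError("corpus has no gene-tagged documents")
    frame = pd.DataFrame(counts).fillna(0.0)
    frame = frame.sort_index(axis=0).sort_index(axis=1)
    return frame


def weight_matrix(counts: pd.DataFrame, scheme: str = "log_entropy") -> pd.DataFrame:
    """Weight a term x gene count matrix; all-zero term rows are removed.

    log_entropy: local log(1 + c_tg) times global 1 + sum_g p_tg log p_tg / log G,
    with p_tg = c_tg / sum_g c_tg.  A term spread uniformly over all G genes
    gets global weight 0; a term confined to one gene gets 1.

    tfidf: sublinear tf log(1 + c_tg) times the smoothed inverse document
    frequency log((1 + G) / (1 + df_t)) + 1, df_t the number of gene columns
    containing the term.
    """
    if counts.empty:
        raise SpecError("empty count matrix")
    counts = counts.loc[counts.sum(axis=1) > 0]
    C = counts.to_numpy(dtype=float)
    G = C.shape[1]
    local = np.log1p(C)
    if scheme == "log_entropy":
        if G == 1:
            global_w = np.ones(C.shape[0])
        else:
            row_sums = C.sum(axis=1, keepdims=True)
            p = C / row_sums
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(p > 0, p * np.log(p), 0.0)
            global_w = 1.0 + plogp.sum(axis=1) / np.log(G)
    elif scheme == "tfidf":
        df = (C > 0).sum(axis=1)
        global_w = np.log((1.0 + G) / (1.0 + df)) + 1.0
    else:
        raise SpecError(f"unknown weighting scheme {scheme!r}")
    W = local * global_w[:, None]
    return pd.DataFrame(W, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Factorization and interrogation
# ---------------------------------------------------------------------------


def fit_lsi(weighted: pd.DataFrame, k: int | None = None, weighting: str = "log_entropy") -> SemanticModel:
    """Truncated SVD of the weighted term x gene matrix.

    ``k`` defaults to min(300, min(dims) - 1), floored at 1.  The dense
    LAPACK SVD is used, so the factorization is deterministic.
    """
    T, G = weighted.shape
    max_k = min(T, G)
    if k is None:
        k = max(1, min(300, max_k - 1))
    if not (1 <= k <= max_k):
        raise SpecError(f"rank k={k} outside [1, {max_k}]")
    U, s, Vt = dense_svd(weighted.to_numpy(dtype=float), full_matrices=False)
    return SemanticModel(
        vocabulary=tuple(weighted.index),
        genes=tuple(weighted.columns),
        rank_k=k,
        term_vectors=U[:, :k] * s[:k],
        gene_vectors=Vt[:k].T * s[:k],
        singular_values=s[:k].copy(),
        weighting=weighting,
    )


def fit_corpus(corpus: Corpus, k: int | None = None, weighting: str = "log_entropy") -> SemanticModel:
    """Convenience: counts -> weighting -> truncated SVD in one call."""
    return fit_lsi(weight_matrix(build_gene_documents(corpus), scheme=weighting), k=k, weighting=weighting)


def query_cosine(model: SemanticModel, interrogator: str) -> dict[GeneID, float]:
    """Cosine of an interrogation phrase against every gene vector.

    The query vector is the sum of the term vectors of the phrase's in-
    vocabulary tokens; out-of-vocabulary tokens are dropped with a warning,
    and a fully out-of-vocabulary query is an error.  Zero-norm vectors
    yield a cosine of 0.
    """
    tokens = tokenize(interrogator, min_len=1)
    index = model.term_index()
    known = [t for t in tokens if t in index]
    if not known:
        raise ConstellateError(f"no token of {interrogator!r} is in the model vocabulary")
    if len(known) < len(tokens):
        logger.warning(
            "query %r: %d token(s) out of vocabulary dropped", interrogator, len(tokens) - len(known)
        )
    q = model.term_vectors[[index[t] for t in known]].sum(axis=0)
    qn = float(np.linalg.norm(q))
    gn = np.linalg.norm(model.gene_vectors, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = model.gene_vectors @ q / (gn * qn)
    cos = np.where((qn > 0) & (gn > 0), cos, 0.0)
    return {g: float(c) for g, c in zip(model.genes, cos)}


def classify_association(score: float, th: AssociationThresholds = DEFAULT_THRESHOLDS) -> str:
    """Class a cosine score as 'explicit', 'implicit' or 'none'."""
    if not (-1.0 - 1e-9 <= score <= 1.0 + 1e-9):
        raise SpecError(f"cosine {score} outside [-1, 1]")
    if score > th.explicit_cutoff:
        return "explicit"
    if score >= th.implicit_cutoff:
        return "implicit"
    return "none"


def interrogate(
    model: SemanticModel, term: str, th: AssociationThresholds = DEFAULT_THRESHOLDS
) -> frozenset[GeneID]:
    """Genes associated with a term at or above the implicit cutoff."""
    scores = query_cosine(model, term)
    return frozenset(g for g, s in scores.items() if s >= th.implicit_cutoff)


def theoretical_dataset(
    model: SemanticModel,
    term_a: str,
    term_b: str,
    th: AssociationThresholds = DEFAULT_THRESHOLDS,
) -> frozenset[GeneID]:
    """Intersection of two single-term interrogations (a concept-pair gene set)."""
    return interrogate(model, term_a, th) & interrogate(model, term_b, th)


def count_frequencies(
    tokens: Sequence[str],
    top_n: int = 10,
    mode: str = "word",
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> list[tuple[str, int]]:
    """Top-n word or adjacent-bigram frequencies after stop-word removal.

    In bigram mode, stop-words are removed first and the remaining adjacent
    token pairs are counted (a cheap stand-in for noun-phrase chunking).
    Ties are broken lexicographically; empty input yields an empty list.
    """
    if top_n < 1:
        raise SpecError("top_n must be >= 1")
    kept = [t for t in tokens if t not in stopwords]
    if mode == "word":
        items: list[str] = kept
    elif mode == "bigram_phrase":
        items = [f"{a} {b}" for a, b in zip(kept, kept[1:])]
    else:
        raise SpecError(f"unknown frequency mode {mode!r}")
    counts: dict[str, int] = {}
    for item in items:
        counts[item] = counts.get(item, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


# ---------------------------------------------------------------------------
# Model persistence (JSON container with a format version stamp)
# ---------------------------------------------------------------------------


def save_model(model: SemanticModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "vocabulary": list(model.vocabulary),
        "genes": list(model.genes),
        "rank_k": model.rank_k,
        "weighting": model.weighting,
        "term_vectors": model.term_vectors.tolist(),
        "gene_vectors": model.gene_vectors.tolist(),
        "singular_values": model.singular_values.tolist(),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> SemanticModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ConstellateError(f"unsupported model format version {version!r}")
    return SemanticModel(
        vocabulary=tuple(payload["vocabulary"]),
        genes=tuple(payload["genes"]),
        rank_k=int(payload["rank_k"]),
        term_vectors=np.asarray(payload["term_vectors"], dtype=float),
        gene_vectors=np.asarray(payload["gene_vectors"], dtype=float),
        singular_values=np.asarray(payload["singular_values"], dtype=float),
        weighting=payload["weighting"],
    )
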