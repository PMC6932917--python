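# Methods

This note records the statistical models, conventions and design choices
behind each stage of the pipeline, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Identifiers, formats and the background universe

Gene/protein identifiers are trimmed and uppercased with standard Unicode
uppercasing (ASCII preserved; `γ-H2AX` → `Γ-H2AX`); normalization is
idempotent, so symbols of mixed provenance (`brca1`, `BRCA1 `) collapse to
one token.  Gene sets travel as GMT (one named set per tab-separated line,
second field free-text), quantification tables as TSV/CSV with a
`protein/level/log2_ratio/p_value` header, corpora as JSONL
(`doc_id/genes/tokens`).  All readers/writers round-trip losslessly
(property-tested).

The background universe of an enrichment or overlap analysis defaults to the
union of the loaded sets (plus the query); every entry point accepts an
explicit universe because the choice materially changes hypergeometric
p-values and is rarely stated in published analyses.  Whole-genome-scale
backgrounds (~20,000 members) are used throughout the synthetic studies.

## Constellation partitioning

A protein is "significantly altered" at a level iff `p ≤ max_p` and
`|log2 ratio| ≥ min_abs_log2_ratio`.  Defaults: `max_p = 0.05`,
`min_abs_log2_ratio = log2(1.2) ≈ 0.263` — the conventional proteomics
cutoffs; both are explicit configuration because published totals can rarely
be regenerated without knowing them.  The multi-set Venn partition assigns
each protein to the cell keyed by the exact subset of levels containing it;
cells are disjoint, cover the union, and reconstruct every level set —
properties verified against a per-gene membership-bitmask oracle up to 5
sets × 10,000 genes.  Percentages (e.g. per-level unique fractions) are
rounded half-even at a configurable precision (default 2 decimals).

## PPI-hub enrichment and the hybrid score

The enrichment probability of an overlap `k` between a query of size `n`
and a hub of size `K` in a universe of `N` is the one-sided hypergeometric
upper tail `P[X ≥ k]` (the Fisher's-exact convention of web enrichment
tools), computed exactly via `scipy.stats.hypergeom` and verified against
exhaustive enumeration for all parameterizations with `N ≤ 12`.  Tails
below double precision are floored at `1e-300` so scores stay finite.

The hybrid score `H = k · (−log10 p)` couples effect size and surprise; it
is defined as 0 when `k = 0` (avoiding the `0 × −log10(1)` ambiguity).  `H`
is non-decreasing and `p` non-increasing in `k` at fixed margins.  Two
aggregations over a target-hub panel are reported side by side, because
"sum of enrichments" is ambiguous on discrete data: `occurrence_count`
(hubs with `p ≤ α`, default `α = 0.05`) and `hybrid_total` (summed hybrid
scores).  Levels are ranked by descending `hybrid_total`, ties by
`occurrence_count`, then label.  The default target panel is the
DNA-damage-response hubs PRKDC, TP53, PARP1, TOP1 (configurable).

## Interactome overlap with size-matched nulls

Observed overlaps are judged against random gene sets of exactly the
query's cardinality sampled without replacement from the universe.  The
empirical p-value uses the add-one estimator
`(1 + #{null ≥ observed}) / (1 + n_sets)`, which is never zero and is
super-uniform under the null.  The default is `n_sets = 1000`; the original
three-set design is supported for fidelity runs but its smallest attainable
p is 1/4, which the package surfaces rather than hides.  Empirical null
moments converge to the closed-form hypergeometric mean `nK/N` and variance
`nK/N·(N−K)/N·(N−n)/(N−1)` (checked within three standard errors at
10,000 resamples).

## Latent semantic indexing

Documents tagged with a gene are concatenated into that gene's
pseudo-document, giving a term × gene count matrix; a document tagged with
several genes contributes fully to each.  Weighting is classical
log-entropy by default — local `log(1 + c)`, global
`1 + Σ_g p_tg log p_tg / log G` — which sends terms spread uniformly over
genes to weight 0 and gene-specific terms to 1; smoothed tf-idf
(`log(1+c) · [log((1+G)/(1+df)) + 1]`) is available.  All-zero term rows
are removed.

The weighted matrix is factorized with the deterministic dense LAPACK SVD;
rank defaults to `min(300, min(dims) − 1)`.  Both term and gene vectors are
scaled by the singular values (symmetric scaling, stated explicitly because
the convention changes cosines): term vectors are rows of `U_k S_k`, gene
vectors rows of `V_k S_k`.  With this convention, at full rank the
concept-space term–term cosines equal the raw weighted matrix's row cosines
and gene–gene cosines its column cosines (`W Wᵀ = (US)(US)ᵀ`,
`Wᵀ W = (VS)(VS)ᵀ`), and `U S Vᵀ` reconstructs `W` exactly — the
identities the test suite asserts to 1e-8.

A query phrase is tokenized (split on non-alphanumerics, lowercased, short
tokens dropped), mapped to the sum of its in-vocabulary term vectors, and
scored by cosine against every gene vector (zero-norm vectors score 0).
Association classes follow the literature-indexing convention: cosine
> 0.2 explicit, 0.1–0.2 implicit (both boundaries class as implicit,
matching "larger than 0.2" for explicit), below 0.1 discarded.
Interrogation returns the genes at or above the implicit cutoff; a
"theoretical" concept-pair dataset is the intersection of two single-term
interrogations.  Word/bigram frequency counting ships a small in-code
stop-word list (overridable); bigrams are adjacent pairs after stop-word
removal — a deliberate cheap stand-in for noun-phrase chunking.

## Semantic ranking and the disease continuum

Cosine profiles score a gene list against grouped interrogator panels.  The
group contrast (e.g. aging vs non-aging concepts) is a two-sided two-sample
Student's t-test (equal-variance by default, Welch optional) on per-gene
*summed* group scores — the summing convention is fixed here because it
changes the test's observations.  Degenerate identical samples return
`(t, p) = (0, 1)`.

The disease continuum is the union over disease interrogators of genes
associated at ≥ the implicit cutoff (0.1), reading "explicitly and
implicitly associated" as inclusive.  Within the continuum, each gene's
correlation count is the number of therapeutic interrogators it scores at
≥ the counting cutoff (default: the explicit threshold 0.2, since "a
correlation" is otherwise undefined; configurable).  The hit list contains
genes whose count *strictly* exceeds the nearest-rank `q`-quantile of
counts (default `q = 0.99`), ordered by descending count then label.
Strictness and the nearest-rank definition are stated because tie handling
changes hit counts on discrete data: with all counts equal the hit list is
empty, and the rule can only select hits when the ranked population exceeds
`1/(1−q)` members (~100 at the default).

## Synthetic data: what is emulated, and what is not

All generators are pure functions of their spec, seed included; the bit
stream is numpy's PCG64 (`default_rng`), so outputs are identical across
platforms.  Synthetic members are labelled `G000001…`, deliberately unlike
real gene symbols.

- **Quant tables**: planted-significant records receive p-values below the
  criteria's `max_p` and |log2 ratios| at least the fold-change cutoff
  (magnitude centred on `effect_log2 = 1.0` with Gaussian noise
  `sd = 0.2`, random sign); null records receive p-values strictly above
  `max_p` and near-zero ratios.  Filtering at the same criteria therefore
  recovers the planted truth exactly — the suite's central
  parameter-recovery property.  Per-level significant fractions may differ
  per level (e.g. the study totals 183/293/297/278/269 per 1,000 proteins
  with a 12-protein all-level core); the generator additionally prevents
  any non-planted protein from being significant at every level, keeping
  the planted core unambiguous.
- **Hub collections**: named sets of exact cardinalities (defaults: the
  nine curated hub sizes, G3BP1 299 … BRCA1 301, MDC1 198) sampled from a
  20,000-member universe, optionally mutually disjoint (required when
  planting overlaps against several hubs at once).
- **Interactome pairs**: control/stress query sets (defaults 47 and 268
  members) containing exactly the requested number of members of each named
  target set; non-planted members are drawn from outside every referenced
  target, and overlapping targets are rejected rather than resolved
  silently.
- **Corpora**: each gene tags 20 documents; a planted (gene, term) pair
  puts the term in each of the gene's documents with probability 0.8; each
  of 20 background slots per document carries, with probability 0.05, a
  token drawn uniformly from the 200-term vocabulary's filler (non-planted)
  portion.  Restricting background to filler terms mirrors how a gene's
  marker vocabulary concentrates in its own abstracts; vocabulary size and
  document length were chosen so that, under the default engine, planted
  pairs reach the explicit 0.2 cosine and non-planted pairs stay below the
  0.1 implicit cutoff with sensitivity and specificity ≥ 0.95 over 100
  seeds.

Not emulated: mass-spectrometry noise structure (isotope impurity, ratio
compression), real English text, citation structure, and the heavy-tailed
document counts of real literature.  Passing the recovery properties shows
the pipeline is correct and well-calibrated on data matching its
assumptions; it does not certify performance on real corpora, whose
weighting, rank and query construction sensitivities are larger.

## Numerical choices and degenerate inputs

- Probabilities are clamped to `1e-300` before `−log10`.
- Banker's (half-even) rounding for reported percentages.
- Empty queries after universe intersection, empty continua, all-out-of-
  vocabulary queries, undefined percentages on empty levels, and
  zero-variance-unequal-mean t-tests all raise typed errors rather than
  returning sentinel values; the single-null-set standard deviation is
  `None`, and z-scores are `None` when the null is degenerate.
- The problem sizes used by the test suite and the acceptance script
  (1,000-protein constellations, 20,000-member universes, 1,000–10,000
  null resamples, 100-seed corpus sweeps, a 400-gene continuum corpus) were
  chosen as the smallest scales at which the closed-form checks have
  adequate statistical resolution.

## Known limitations

- The hybrid score inherits the universe-choice sensitivity of every
  hypergeometric enrichment; results should always be read alongside the
  universe used.
- With very small null counts (the original three-set design) the empirical
  p is bounded below at 1/4 and carries almost no inferential weight.
- LSI association is transitive by construction: a gene strongly tied to a
  concept's other genes can score above the implicit cutoff without ever
  co-occurring with the concept.  This is the method's point — it surfaces
  implied relationships — but it means "exact recovery" of planted truth
  only holds when planted structures are sufficiently decorrelated.
- The continuum percentile rule is only informative when the continuum is
  substantially larger than `1/(1−q)`.
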