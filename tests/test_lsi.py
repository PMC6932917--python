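"""Term-gene matrix construction, weighting, SVD embedding and interrogation."""

import math

import numpy as np
import pandas as pd
import pytest

from constellate import (
    AssociationThresholds,
    ConstellateError,
    Corpus,
    Document,
    PlantedCorpusSpec,
    SpecError,
    build_gene_documents,
    classify_association,
    count_frequencies,
    fit_corpus,
    fit_lsi,
    generate_corpus,
    interrogate,
    load_model,
    query_cosine,
    save_model,
    synthetic_universe,
    theoretical_dataset,
    weight_matrix,
)


def _cos(a, b):
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestBuildGeneDocuments:
    def test_single_doc_counts(self):
        corpus = Corpus(docs=(Document("d1", frozenset({"G1"}), ("aa", "aa", "bb")),))
        counts = build_gene_documents(corpus)
        assert counts.loc["aa", "G1"] == 2 and counts.loc["bb", "G1"] == 1

    def test_multi_tagged_doc_contributes_to_both(self):
        corpus = Corpus(docs=(Document("d1", frozenset({"G1", "G2"}), ("aa",)),))
        counts = build_gene_documents(corpus)
        assert counts.loc["aa", "G1"] == 1 and counts.loc["aa", "G2"] == 1

    def test_column_sums_conserve_token_counts(self):
        genes = synthetic_universe(6)
        planted = ((genes[0], "aging", 0.8),)
        corpus, _ = generate_corpus(PlantedCorpusSpec(n_genes=6, planted=planted, seed=2))
        counts = build_gene_documents(corpus)
        for gene in genes:
            expected = sum(len(d.tokens) for d in corpus if gene in d.genes)
            assert counts[gene].sum() == expected

    def test_untagged_corpus_rejected(self):
        corpus = Corpus(docs=(Document("d1", frozenset(), ("aa",)),))
        with pytest.raises(ConstellateError):
            build_gene_documents(corpus)


class TestWeightMatrix:
    def test_uniform_term_carries_no_information(self):
        counts = pd.DataFrame({"G1": [3.0], "G2": [3.0], "G3": [3.0]}, index=["t"])
        assert weight_matrix(counts).loc["t"].abs().max() == pytest.approx(0.0)

    def test_concentrated_term_gets_unit_global_weight(self):
        counts = pd.DataFrame({"G1": [4.0], "G2": [0.0]}, index=["t"])
        weighted = weight_matrix(counts)
        assert weighted.loc["t", "G1"] == pytest.approx(math.log(5.0))

    def test_three_by_three_hand_computed(self):
        counts = pd.DataFrame(
            [[2.0, 0.0, 0.0], [1.0, 1.0, 1.0], [0.0, 2.0, 1.0]],
            index=["t1", "t2", "t3"],
            columns=["G1", "G2", "G3"],
        )
        weighted = weight_matrix(counts)
        ln2, ln3 = math.log(2), math.log(3)
        gw3 = 2 * ln2 / (3 * ln3)
        assert weighted.loc["t1", "G1"] == pytest.approx(ln3 * 1.0)
        assert weighted.loc["t2"].abs().max() == pytest.approx(0.0)
        assert weighted.loc["t3", "G2"] == pytest.approx(ln3 * gw3)
        assert weighted.loc["t3", "G3"] == pytest.approx(ln2 * gw3)

    def test_tfidf_smoothed_formulation(self):
        counts = pd.DataFrame(
            [[3.0, 0.0], [1.0, 1.0]], index=["t1", "t2"], columns=["G1", "G2"]
        )
        weighted = weight_matrix(counts, scheme="tfidf")
        idf_rare = math.log(3 / 2) + 1
        idf_common = math.log(3 / 3) + 1
        assert weighted.loc["t1", "G1"] == pytest.approx(math.log(4) * idf_rare)
        assert weighted.loc["t2", "G1"] == pytest.approx(math.log(2) * idf_common)

    def test_zero_rows_removed_and_unknown_scheme_rejected(self):
        counts = pd.DataFrame({"G1": [1.0, 0.0]}, index=["t1", "t2"])
        assert list(weight_matrix(counts).index) == ["t1"]
        with pytest.raises(SpecError):
            weight_matrix(counts, scheme="nope")


class TestFitLsi:
    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(0)
        W = pd.DataFrame(rng.random((4, 3)), index=list("abcd"), columns=["G1", "G2", "G3"])
        model = fit_lsi(W, k=2)
        U, s, Vt = np.linalg.svd(W.to_numpy(), full_matrices=False)
        # compare up to per-component sign
        for j in range(2):
            sign = np.sign(np.dot(model.term_vectors[:, j], U[:, j] * s[j]))
            assert np.allclose(model.term_vectors[:, j], sign * U[:, j] * s[j], atol=1e-8)
            assert np.allclose(model.gene_vectors[:, j], sign * Vt[j] * s[j], atol=1e-8)

    def test_singular_values_nonincreasing(self, planted_corpus_model):
        _, _, model, _ = planted_corpus_model
        s = model.singular_values
        assert np.all(s[:-1] >= s[1:] - 1e-12)

    def test_k_out_of_range_rejected(self):
        W = pd.DataFrame(np.eye(3), index=list("abc"), columns=["G1", "G2", "G3"])
        with pytest.raises(SpecError):
            fit_lsi(W, k=4)

    def test_full_rank_cosine_identity(self):
        rng = np.random.default_rng(1)
        raw = rng.random((30, 20))
        W = pd.DataFrame(raw, index=[f"t{i}" for i in range(30)], columns=[f"G{i}" for i in range(20)])
        model = fit_lsi(W, k=20)
        # term-term concept cosines equal raw row cosines; gene-gene equal column cosines
        for i, j in [(0, 1), (5, 17), (2, 29)]:
            assert _cos(model.term_vectors[i], model.term_vectors[j]) == pytest.approx(
                _cos(raw[i], raw[j]), abs=1e-8
            )
        for i, j in [(0, 1), (3, 19), (7, 11)]:
            assert _cos(model.gene_vectors[i], model.gene_vectors[j]) == pytest.approx(
                _cos(raw[:, i], raw[:, j]), abs=1e-8
            )
        # and the factorization reconstructs the weighted matrix exactly
        recon = (model.term_vectors / model.singular_values) @ model.gene_vectors.T
        assert np.allclose(recon, raw, atol=1e-8)

    def test_frobenius_error_nonincreasing_in_k(self):
        rng = np.random.default_rng(2)
        raw = rng.random((15, 10))
        W = pd.DataFrame(raw, index=[f"t{i}" for i in range(15)], columns=[f"G{i}" for i in range(10)])
        errors = []
        for k in (1, 3, 5, 10):
            model = fit_lsi(W, k=k)
            recon = (model.term_vectors / model.singular_values) @ model.gene_vectors.T
            errors.append(np.linalg.norm(recon - raw))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))


class TestQueryAndClassification:
    def test_exclusive_planted_term_is_collinear(self):
        genes = synthetic_universe(3)
        spec = PlantedCorpusSpec(
            n_genes=3, planted=((genes[0], "aging", 1.0),), background_term_prob=0.0, seed=0
        )
        corpus, _ = generate_corpus(spec)
        # only the planted gene has any token at all; the other columns are empty
        model = fit_corpus(corpus, k=1)
        scores = query_cosine(model, "aging")
        assert scores[genes[0]] == pytest.approx(1.0, abs=1e-9)

    def test_unknown_term_rejected(self, planted_corpus_model):
        _, _, model, _ = planted_corpus_model
        with pytest.raises(ConstellateError):
            query_cosine(model, "zzznotaword")

    @pytest.mark.parametrize(
        "score,expected",
        [(0.25, "explicit"), (0.15, "implicit"), (0.05, "none"), (0.2, "implicit"), (0.1, "implicit")],
    )
    def test_classification_boundaries(self, score, expected):
        assert classify_association(score) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(SpecError):
            AssociationThresholds(implicit_cutoff=0.3, explicit_cutoff=0.2)

    def test_interrogate_recovers_planted_gene(self, planted_corpus_model):
        _, truth, model, genes = planted_corpus_model
        for (gene, term), _prob in truth.items():
            assert interrogate(model, term) == {gene}

    def test_interrogate_zero_thresholds_returns_all_nonnegative(self, planted_corpus_model):
        _, _, model, genes = planted_corpus_model
        th = AssociationThresholds(implicit_cutoff=0.0, explicit_cutoff=0.0)
        scores = query_cosine(model, "term00")
        expected = {g for g, s in scores.items() if s >= 0.0}
        assert interrogate(model, "term00", th) == expected

    def test_theoretical_dataset_is_intersection(self):
        # noiseless corpus with per-gene anchor terms, so the planted structure
        # (and not background or transitive similarity) determines membership
        genes = synthetic_universe(10)
        anchors = tuple(
            (g, f"anchor{i:02d}x{j}", 0.9) for i, g in enumerate(genes) for j in range(3)
        )
        planted = (
            (genes[0], "signaling", 0.9),
            (genes[1], "signaling", 0.9),
            (genes[1], "aging", 0.9),
            (genes[2], "aging", 0.9),
        ) + anchors
        corpus, _ = generate_corpus(
            PlantedCorpusSpec(n_genes=10, planted=planted, background_term_prob=0.0, seed=0)
        )
        model = fit_corpus(corpus)
        joint = theoretical_dataset(model, "signaling", "aging")
        assert joint == {genes[1]}
        assert joint <= interrogate(model, "signaling")
        assert joint <= interrogate(model, "aging")


class TestCountFrequencies:
    def test_word_mode(self):
        assert count_frequencies(["dna", "repair", "dna"], top_n=5) == [("dna", 2), ("repair", 1)]

    def test_bigram_mode(self):
        assert count_frequencies(["dna", "repair", "dna"], top_n=5, mode="bigram_phrase") == [
            ("dna repair", 1),
            ("repair dna", 1),
        ]

    def test_stopwords_removed(self):
        assert count_frequencies(["the", "dna", "of", "dna"], top_n=3) == [("dna", 2)]

    def test_counts_conserve_totals(self):
        rng = np.random.default_rng(4)
        tokens = [f"w{i}" for i in rng.integers(0, 30, size=500)]
        out = count_frequencies(tokens, top_n=1000)
        assert sum(c for _, c in out) <= len(tokens)

    def test_empty_input(self):
        assert count_frequencies([], top_n=3) == []


class TestPersistence:
    def test_round_trip(self, planted_corpus_model, tmp_path):
        _, _, model, _ = planted_corpus_model
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.vocabulary == model.vocabulary
        assert back.genes == model.genes
        assert np.allclose(back.term_vectors, model.term_vectors)
        assert np.allclose(back.gene_vectors, model.gene_vectors)
        assert query_cosine(back, "term00") == query_cosine(model, "term00")
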