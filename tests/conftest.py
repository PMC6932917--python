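import pytest

from constellate import (
    PlantedCorpusSpec,
    fit_corpus,
    generate_corpus,
    generate_hub_collection,
    synthetic_universe,
)


@pytest.fixture(scope="session")
def hub_collection():
    """The study's nine hub interactomes (mutually disjoint) over a 20,000-member universe."""
    return generate_hub_collection(seed=11, disjoint=True)


@pytest.fixture(scope="session")
def planted_corpus_model():
    """One planted corpus (5 gene-term pairs) and its fitted semantic model."""
    genes = synthetic_universe(20)
    planted = tuple((genes[i], f"term{i:02d}", 0.8) for i in range(5))
    corpus, truth = generate_corpus(PlantedCorpusSpec(planted=planted, seed=7))
    model = fit_corpus(corpus)
    return corpus, truth, model, genes
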