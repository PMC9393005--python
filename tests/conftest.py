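import pytest

from bryolat import geo, nn, relations, synth


@pytest.fixture(scope="session")
def worked_doc():
    return synth.worked_example_document()


@pytest.fixture(scope="session")
def gazetteer():
    return synth.make_gazetteer(20, 0.1, seed=1)


@pytest.fixture(scope="session")
def corpus_bundle(gazetteer):
    return synth.generate_corpus(
        synth.species_pool(12, seed=3), gazetteer, n_docs=24, seed=2
    )


@pytest.fixture(scope="session")
def equal_angle_grid():
    return geo.make_band_grid("equal_angle")


@pytest.fixture(scope="session")
def trained_classifiers(corpus_bundle):
    """Both classifiers trained once on the shared synthetic corpus."""
    bundle = corpus_bundle
    split = relations.split_by_publication(bundle.gold, seed=4)
    docs = {d.doc_id: d for d in bundle.documents}
    rel_ex = nn.relation_examples(bundle.gold, docs)
    ver_ex = nn.verifier_examples(bundle.location_examples)
    vocab = sorted({t for e in rel_ex + ver_ex for t in e.tokens})
    emb = nn.synthetic_embeddings(vocab, dim=300, seed=0)
    cfg = nn.ModelConfig(embedding_dim=300, recurrent_hidden=32, epochs=50, seed=0)
    relation = nn.train_relation_classifier(*split.partition(rel_ex)[:2], cfg, emb)
    verifier = nn.train_verifier(*split.partition(ver_ex)[:2], cfg, emb)
    return {
        "split": split,
        "relation": relation,
        "verifier": verifier,
        "rel_examples": rel_ex,
        "ver_examples": ver_ex,
    }
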