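import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-doc synthetic corpus shared across tagger unit tests."""
    from mutmention import SynthConfig, generate_corpus

    return generate_corpus(SynthConfig(n_documents=30, seed=101))


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A CRF tagger trained (without embeddings) on the small corpus."""
    from mutmention import FeatureConfig, Hyperparams, train

    docs, gold = small_corpus
    return train(
        docs,
        gold,
        feature_config=FeatureConfig(use_embeddings=False),
        hyperparams=Hyperparams(max_iter=60),
    )
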