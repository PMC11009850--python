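import numpy as np
import pytest

from reviewfactors import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def planted_corpus():
    """Well-separated 5-topic corpus with ground truth, reused across tests."""
    cfg = GeneratorConfig(
        n_apps=10,
        reviews_per_app=50,
        n_topics_true=5,
        vocab_size=300,
        tokens_per_doc=60,
        seed=11,
    )
    table, truth = generate_corpus(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def planted_docs(planted_corpus):
    _, table, _ = planted_corpus
    return [t.split() for t in table["text"]]


def simulate_censored(rng, n, beta, sigma, lower=0.0, upper=4.0, k_topics=None):
    """Draw (X, y) from the exact censored-normal process with a
    Dirichlet-composition design (intercept + all but one topic column)."""
    k = len(beta) - 1 if k_topics is None else k_topics
    theta = rng.dirichlet(np.ones(k + 1), size=n)
    X = np.column_stack([np.ones(n), theta[:, :k]])
    ystar = X @ np.asarray(beta) + rng.normal(0.0, sigma, n)
    y = np.clip(ystar, lower, upper)
    return X, y
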