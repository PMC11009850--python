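"""Collapsed-Gibbs LDA: count consistency, simplex normalization,
degenerate limits, perplexity oracle, recovery and selection behaviour."""

import numpy as np
import pytest

from reviewfactors import (
    ConfigurationError,
    DataError,
    LatentDirichletAllocation,
    assign_topics,
    fit_lda,
    select_k,
    top_keywords,
)


def small_corpus():
    rng = np.random.default_rng(1)
    words = [f"w{i}" for i in range(12)]
    return [
        [words[rng.integers(0, 12)] for _ in range(rng.integers(5, 15))]
        for _ in range(20)
    ]


def greedy_matched_cosines(true_phi, est_phi):
    sim = (true_phi @ est_phi.T) / (
        np.linalg.norm(true_phi, axis=1)[:, None]
        * np.linalg.norm(est_phi, axis=1)[None, :]
    )
    k = sim.shape[0]
    used, out = set(), []
    for i in np.argsort(-sim.max(axis=1)):
        j = max((j for j in range(k) if j not in used), key=lambda j: sim[i, j])
        used.add(j)
        out.append(sim[i, j])
    return np.array(out)


def test_single_topic_phi_is_smoothed_word_frequency():
    docs = small_corpus()
    res = fit_lda(docs, 1, n_iter=5, seed=0)
    assert (res.z == 0).all()
    model = res.model
    counts = np.zeros(len(model.vocab))
    for doc in docs:
        for tok in doc:
            counts[model.word_index[tok]] += 1
    beta = model.beta
    expected = (counts + beta) / (counts.sum() + len(model.vocab) * beta)
    np.testing.assert_allclose(res.phi[0], expected, atol=1e-12)


def test_disjoint_vocabulary_documents_separate():
    """Two documents with disjoint vocabularies land on different dominant
    topics in a majority of seeds."""
    d1 = ["alpha", "bravo", "charlie"] * 10
    d2 = ["xray", "yankee", "zulu"] * 10
    wins = 0
    for seed in range(10):
        res = fit_lda([d1, d2], 2, alpha=0.1, n_iter=200, seed=seed)
        a, b = res.assign_topics()
        wins += int(a != b)
    assert wins >= 6


def test_counts_consistent_and_rows_normalized_after_fit():
    docs = small_corpus()
    res = fit_lda(docs, 3, n_iter=30, seed=2)
    res.check_counts()
    np.testing.assert_allclose(res.theta.sum(axis=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(res.phi.sum(axis=1), 1.0, atol=1e-10)
    assert (res.theta > 0).all() and (res.phi > 0).all()


def test_perplexity_of_uniform_single_topic_model_equals_vocab_size():
    docs = small_corpus()
    v = len({t for d in docs for t in d})
    res = fit_lda(docs, 1, beta=1e12, n_iter=2, seed=0)
    assert res.perplexity() == pytest.approx(v, rel=1e-6)


def test_perplexity_at_least_one_and_matches_brute_force():
    docs = small_corpus()
    res = fit_lda(docs, 3, n_iter=40, seed=3)
    theta, phi = res.theta, res.phi
    model = res.model
    # independent brute-force evaluation of the formula, pure python loops
    total, n_tokens = 0.0, 0
    for d, doc in enumerate(docs):
        for tok in doc:
            w = model.word_index[tok]
            mix = sum(theta[d, k] * phi[k, w] for k in range(3))
            total += np.log(mix)
            n_tokens += 1
    expected = np.exp(-total / n_tokens)
    assert res.perplexity() == pytest.approx(expected, abs=1e-8)
    assert res.perplexity() >= 1.0


def test_training_perplexity_improves_over_burn_in():
    """Final training perplexity <= after-one-sweep perplexity (median of
    5 seeds tolerates stochastic wobble)."""
    docs = [
        (["red", "blue", "green"] * 5 if i % 2 else ["cat", "dog", "fox"] * 5)
        for i in range(12)
    ]
    deltas = []
    for seed in range(5):
        res = fit_lda(docs, 2, alpha=0.5, n_iter=100, burn_in=50, seed=seed)
        deltas.append(res.perplexity_trace[100] - res.perplexity_trace[1])
    assert np.median(deltas) <= 0.0


def test_planted_topic_recovery(planted_corpus, planted_docs):
    cfg, _, truth = planted_corpus
    res = fit_lda(planted_docs, 5, alpha=0.1, n_iter=300, burn_in=150,
                  seed=4, vocab=cfg.vocabulary)
    cos = greedy_matched_cosines(truth.topic_word_dists, res.phi)
    assert (cos > 0.9).all()


def test_dominant_topic_assignment_recovers_truth(planted_corpus, planted_docs):
    cfg, _, truth = planted_corpus
    res = fit_lda(planted_docs, 5, alpha=0.1, n_iter=300, burn_in=150,
                  seed=4, vocab=cfg.vocabulary)
    sim = truth.topic_word_dists @ res.phi.T
    mapping = {}
    used = set()
    for i in np.argsort(-sim.max(axis=1)):
        j = max((j for j in range(5) if j not in used), key=lambda j: sim[i, j])
        mapping[j] = i
        used.add(j)
    est = np.array([mapping[k] for k in res.assign_topics()])
    true_dom = truth.theta.argmax(axis=1)
    assert (est == true_dom).mean() > 0.8


def test_select_k_single_candidate_is_forced():
    docs = small_corpus()
    curve = select_k(docs, [3], n_iter=20, seed=0)
    assert curve.chosen_k == 3
    assert len(curve.perplexities) == 1


def test_select_k_contract_and_override():
    docs = small_corpus()
    curve = select_k(docs, [2, 3, 4], n_iter=20, seed=0)
    assert curve.candidates == [2, 3, 4]
    assert all(np.isfinite(p) and p > 0 for p in curve.perplexities)
    assert curve.chosen_k in curve.candidates
    forced = select_k(docs, [2, 3, 4], n_iter=20, seed=0, override=4)
    assert forced.chosen_k == 4
    with pytest.raises(ConfigurationError):
        select_k(docs, [2, 3], n_iter=20, seed=0, override=7)


def test_assign_topics_argmax_and_tie_rule():
    theta = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0]])
    assert assign_topics(theta).tolist() == [1, 0]


def test_top_keywords_ordering_and_bounds():
    phi = np.array([[0.5, 0.2, 0.3], [0.2, 0.2, 0.6]])
    vocab = ["a", "b", "c"]
    assert top_keywords(phi, vocab, 1) == [["a"], ["c"]]
    assert top_keywords(phi, vocab, 3) == [["a", "c", "b"], ["c", "a", "b"]]
    # tie between a and b in topic 2 after c -> vocabulary order
    with pytest.raises(ConfigurationError):
        top_keywords(phi, vocab, 4)


def test_planted_top_word_ranks_first(planted_corpus, planted_docs):
    cfg, _, truth = planted_corpus
    res = fit_lda(planted_docs, 5, alpha=0.1, n_iter=300, burn_in=150,
                  seed=4, vocab=cfg.vocabulary)
    sim = truth.topic_word_dists @ res.phi.T
    kws = res.top_keywords(1)
    hits = 0
    for i in range(5):
        j = int(np.argmax(sim[i]))
        true_top = cfg.vocabulary[int(np.argmax(truth.topic_word_dists[i]))]
        hits += int(kws[j][0] == true_top)
    assert hits >= 4


def test_error_contracts():
    with pytest.raises(DataError):
        fit_lda([], 2)
    with pytest.raises(DataError):
        fit_lda([["a"], []], 2)
    with pytest.raises(ConfigurationError):
        fit_lda([["a", "b"]], 5)  # K exceeds token count
    res = fit_lda(small_corpus(), 2, n_iter=5, seed=0)
    with pytest.raises(DataError):
        res.perplexity([["unseen_token"]])
    with pytest.raises(ConfigurationError):
        select_k(small_corpus(), [0, 2], n_iter=5)
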