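"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The model/results split follows the usual fitted-model convention:
:class:`LatentDirichletAllocation` holds the corpus and priors, ``fit``
runs the sampler and returns a :class:`TopicModelResults` carrying the final
assignment state, the smoothed point estimates theta ((n_dk + alpha) /
(len_d + K*alpha)) and phi ((n_kw + beta) / (n_k + V*beta)), perplexity
evaluation (held-out documents are folded in with phi frozen), dominant-
topic assignment and top-keyword extraction.  Topic-number selection scans a
candidate list and picks the held-out-perplexity argmin, with a manual
override because practitioners also weigh interpretability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._gibbs import gibbs_foldin, gibbs_train
from .errors import ConfigurationError, DataError

__all__ = [
    "LatentDirichletAllocation",
    "TopicModelResults",
    "PerplexityCurve",
    "fit_lda",
    "select_k",
    "assign_topics",
    "top_keywords",
]

Docs = Sequence[Sequence[str]]


def _flatten(docs: Docs, word_index: dict[str, int]):
    doc_ids, word_ids = [], []
    for d, doc in enumerate(docs):
        for tok in doc:
            doc_ids.append(d)
            word_ids.append(word_index[tok])
    return (
        np.asarray(doc_ids, dtype=np.int64),
        np.asarray(word_ids, dtype=np.int64),
    )


class LatentDirichletAllocation:
    """LDA model over a tokenized corpus.

    Parameters
    ----------
    docs
        Sequence of token sequences; every document must be non-empty.
    n_topics
        Number of latent topics K (>= 1).
    alpha, beta
        Symmetric Dirichlet concentrations for the document-topic and
        topic-word priors.  ``alpha`` defaults to ``50 / K``, ``beta`` to
        0.01 — standard collapsed-Gibbs folk defaults.
    vocab
        Optional fixed vocabulary (ordered).  Defaults to the sorted set of
        corpus tokens, which makes the word indexing deterministic.
    """

    def __init__(
        self,
        docs: Docs,
        n_topics: int,
        alpha: float | None = None,
        beta: float = 0.01,
        vocab: Sequence[str] | None = None,
    ):
        docs = [list(d) for d in docs]
        if len(docs) == 0:
            raise DataError("empty corpus")
        for d, doc in enumerate(docs):
            if len(doc) == 0:
                raise DataError(f"document {d} is empty")
        if n_topics < 1:
            raise ConfigurationError("n_topics must be >= 1")
        total_tokens = sum(len(d) for d in docs)
        if n_topics > total_tokens:
            raise ConfigurationError(
                f"n_topics={n_topics} exceeds the corpus size ({total_tokens} tokens)"
            )
        if alpha is None:
            alpha = 50.0 / n_topics
        if not alpha > 0 or not beta > 0:
            raise ConfigurationError("alpha and beta must be > 0")
        if vocab is None:
            vocab = sorted({t for doc in docs for t in doc})
        else:
            vocab = list(vocab)
            missing = {t for doc in docs for t in doc} - set(vocab)
            if missing:
                raise DataError(
                    f"tokens missing from supplied vocabulary: {sorted(missing)[:5]}"
                )
        self.docs = docs
        self.K = int(n_topics)
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.vocab = vocab
        self.word_index = {w: i for i, w in enumerate(vocab)}
        self.doc_ids, self.word_ids = _flatten(docs, self.word_index)
        self.doc_lengths = np.bincount(self.doc_ids, minlength=len(docs))

    def fit(
        self, n_iter: int = 1000, burn_in: int = 500, seed: int = 0
    ) -> "TopicModelResults":
        """Run the collapsed Gibbs sampler; deterministic given ``seed``.

        The point estimate is taken from the final state.  ``burn_in`` is
        recorded for provenance and used by the perplexity-trace helper.
        """
        K, V = self.K, len(self.vocab)
        n_docs = len(self.docs)
        rng = np.random.default_rng(seed)
        z = rng.integers(0, K, size=self.doc_ids.shape[0]).astype(np.int64)
        n_dk = np.zeros((n_docs, K), dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        n_k = np.zeros(K, dtype=np.int64)
        np.add.at(n_dk, (self.doc_ids, z), 1)
        np.add.at(n_kw, (z, self.word_ids), 1)
        np.add.at(n_k, z, 1)

        kernel_seed = int(rng.integers(0, 2**31 - 1))
        trace = {}
        # split the run so a training-perplexity trace point exists after
        # the first sweep without re-running the sampler
        first = min(1, n_iter)
        if first:
            gibbs_train(
                self.doc_ids, self.word_ids, z, n_dk, n_kw, n_k,
                self.alpha, self.beta, first, kernel_seed,
            )
            trace[1] = self._train_perplexity(n_dk, n_kw, n_k)
        remaining = n_iter - first
        if remaining > 0:
            gibbs_train(
                self.doc_ids, self.word_ids, z, n_dk, n_kw, n_k,
                self.alpha, self.beta, remaining,
                (kernel_seed + 1) % (2**31 - 1),
            )
        res = TopicModelResults(
            model=self, z=z, n_dk=n_dk, n_kw=n_kw, n_k=n_k,
            n_iter=n_iter, burn_in=burn_in, seed=seed,
        )
        trace[n_iter] = res.perplexity()
        res.perplexity_trace = trace
        return res

    def _train_perplexity(self, n_dk, n_kw, n_k) -> float:
        theta = (n_dk + self.alpha) / (
            self.doc_lengths[:, None] + self.K * self.alpha
        )
        phi = (n_kw + self.beta) / (n_k[:, None] + len(self.vocab) * self.beta)
        ll = np.log((theta @ phi)[self.doc_ids, self.word_ids]).sum()
        return float(np.exp(-ll / self.doc_ids.shape[0]))


@dataclass
class TopicModelResults:
    """Fitted LDA state and derived quantities."""

    model: LatentDirichletAllocation
    z: np.ndarray
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    n_iter: int
    burn_in: int
    seed: int
    perplexity_trace: dict | None = None

    @property
    def K(self) -> int:
        return self.model.K

    @property
    def vocab(self) -> list[str]:
        return self.model.vocab

    @property
    def theta(self) -> np.ndarray:
        """Document-topic distributions, (n_docs, K); rows sum to 1."""
        m = self.model
        return (self.n_dk + m.alpha) / (
            m.doc_lengths[:, None] + m.K * m.alpha
        )

    @property
    def phi(self) -> np.ndarray:
        """Topic-word distributions, (K, V); rows sum to 1."""
        m = self.model
        return (self.n_kw + m.beta) / (
            self.n_k[:, None] + len(m.vocab) * m.beta
        )

    def check_counts(self) -> None:
        """Count-matrix consistency with the assignment vector."""
        m = self.model
        n_dk = np.zeros_like(self.n_dk)
        n_kw = np.zeros_like(self.n_kw)
        np.add.at(n_dk, (m.doc_ids, self.z), 1)
        np.add.at(n_kw, (self.z, m.word_ids), 1)
        assert (n_dk == self.n_dk).all(), "n_dk inconsistent with z"
        assert (n_kw == self.n_kw).all(), "n_kw inconsistent with z"
        assert (self.n_kw.sum(axis=1) == self.n_k).all(), "n_k inconsistent"
        assert (self.n_dk.sum(axis=1) == m.doc_lengths).all()

    def _foldin_theta(self, docs: Docs, n_iter: int = 50, seed: int = 0):
        m = self.model
        for d, doc in enumerate(docs):
            if len(doc) == 0:
                raise DataError(f"document {d} is empty")
            for tok in doc:
                if tok not in m.word_index:
                    raise DataError(f"out-of-vocabulary token {tok!r}")
        doc_ids, word_ids = _flatten(docs, m.word_index)
        phi = self.phi
        rng = np.random.default_rng(seed)
        z = rng.integers(0, m.K, size=doc_ids.shape[0]).astype(np.int64)
        n_dk = np.zeros((len(docs), m.K), dtype=np.int64)
        np.add.at(n_dk, (doc_ids, z), 1)
        gibbs_foldin(
            doc_ids, word_ids, z, n_dk, phi, m.alpha, n_iter,
            int(rng.integers(0, 2**31 - 1)),
        )
        lengths = np.bincount(doc_ids, minlength=len(docs))
        theta = (n_dk + m.alpha) / (lengths[:, None] + m.K * m.alpha)
        return theta, doc_ids, word_ids

    def perplexity(self, docs: Docs | None = None, foldin_iter: int = 50,
                   seed: int = 0) -> float:
        """exp(-(sum_d sum_w log sum_k theta_dk phi_kw) / n_tokens).

        With ``docs=None`` the training corpus and training theta are used;
        otherwise held-out documents are folded in by Gibbs sampling with
        phi frozen before evaluation.
        """
        m = self.model
        phi = self.phi
        if docs is None:
            theta, doc_ids, word_ids = self.theta, m.doc_ids, m.word_ids
        else:
            theta, doc_ids, word_ids = self._foldin_theta(docs, foldin_iter, seed)
        ll = np.log((theta @ phi)[doc_ids, word_ids]).sum()
        return float(np.exp(-ll / doc_ids.shape[0]))

    def assign_topics(self, theta: np.ndarray | None = None) -> np.ndarray:
        """Dominant topic per document (0-based); ties -> lowest index."""
        return assign_topics(self.theta if theta is None else theta)

    def top_keywords(self, n: int = 7) -> list[list[str]]:
        return top_keywords(self.phi, self.vocab, n)

    def save(self, path) -> None:
        """JSON metadata + .npz count-matrix bundle (two sibling files)."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            z=self.z, n_dk=self.n_dk, n_kw=self.n_kw, n_k=self.n_k,
        )
        meta = {
            "K": self.K, "alpha": self.model.alpha, "beta": self.model.beta,
            "vocab": self.vocab, "n_iter": self.n_iter,
            "burn_in": self.burn_in, "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))


def fit_lda(
    docs: Docs,
    n_topics: int,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
    vocab: Sequence[str] | None = None,
) -> TopicModelResults:
    """Functional wrapper around :class:`LatentDirichletAllocation`."""
    model = LatentDirichletAllocation(
        docs, n_topics, alpha=alpha, beta=beta, vocab=vocab
    )
    return model.fit(n_iter=n_iter, burn_in=burn_in, seed=seed)


def assign_topics(theta: np.ndarray) -> np.ndarray:
    """Argmax per row; ties broken by the lowest topic index."""
    theta = np.asarray(theta)
    return theta.argmax(axis=1)


def top_keywords(phi: np.ndarray, vocab: Sequence[str], n: int) -> list[list[str]]:
    """The n highest-probability tokens per topic; ties by vocabulary order."""
    phi = np.asarray(phi)
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if n > phi.shape[1]:
        raise ConfigurationError(
            f"n={n} exceeds the vocabulary size ({phi.shape[1]})"
        )
    out = []
    for row in phi:
        # stable sort on negated probabilities preserves vocabulary order on ties
        order = np.argsort(-row, kind="stable")[:n]
        out.append([vocab[i] for i in order])
    return out


@dataclass
class PerplexityCurve:
    """Held-out perplexity per candidate topic number."""

    candidates: list[int]
    perplexities: list[float]
    chosen_k: int

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"k": self.candidates, "perplexity": self.perplexities}
        ).to_csv(path, index=False)

    def plot(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(self.candidates, self.perplexities, marker="o")
        ax.axvline(self.chosen_k, color="grey", linestyle="--")
        ax.set_xlabel("number of topics")
        ax.set_ylabel("held-out perplexity")
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig


def select_k(
    docs: Docs,
    candidates: Sequence[int],
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 300,
    burn_in: int = 150,
    seed: int = 0,
    holdout_frac: float = 0.1,
    rel_tol: float = 0.02,
    override: int | None = None,
) -> PerplexityCurve:
    """Scan candidate topic numbers and pick the held-out-perplexity minimum.

    Each candidate is fitted on a seeded 90/10 train/held-out split and
    scored by fold-in perplexity on the held-out documents.  Beyond the
    number of real topics the curve typically flattens into a plateau whose
    wiggles are sampler noise, so candidates within ``rel_tol`` (relative)
    of the minimum are treated as ties and the smallest such K wins —
    a parsimony rule in the spirit of the one-standard-error rule; set
    ``rel_tol=0`` for the raw argmin.  ``override`` forces the choice (it
    must be a candidate) — topic-number selection in practice also weighs
    human judgment of the topics, which no scalar captures.
    """
    candidates = [int(k) for k in candidates]
    if len(candidates) < 1:
        raise ConfigurationError("at least one candidate K is required")
    if any(k <= 0 for k in candidates):
        raise ConfigurationError("candidate K values must be positive")
    docs = [list(d) for d in docs]
    rng = np.random.default_rng(seed)
    n = len(docs)
    n_hold = max(1, int(round(holdout_frac * n))) if n > 1 else 0
    perm = rng.permutation(n)
    hold_idx = set(perm[:n_hold].tolist())
    train = [docs[i] for i in range(n) if i not in hold_idx]
    hold = [docs[i] for i in range(n) if i in hold_idx]
    train_vocab = {t for doc in train for t in doc}
    # held-out docs restricted to the training vocabulary (OOV tokens have
    # no phi estimate); docs emptied by the restriction are dropped
    hold = [[t for t in doc if t in train_vocab] for doc in hold]
    hold = [doc for doc in hold if doc]

    perps = []
    for i, k in enumerate(candidates):
        res = fit_lda(
            train, k, alpha=alpha, beta=beta, n_iter=n_iter,
            burn_in=burn_in, seed=seed + i + 1,
        )
        if hold:
            perps.append(res.perplexity(hold, seed=seed))
        else:
            perps.append(res.perplexity())
    if override is not None:
        if override not in candidates:
            raise ConfigurationError(
                f"override K={override} is not among the candidates"
            )
        chosen = override
    else:
        cutoff = min(perps) * (1.0 + rel_tol)
        chosen = min(k for k, p in zip(candidates, perps) if p <= cutoff)
    return PerplexityCurve(candidates, [float(p) for p in perps], chosen)
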