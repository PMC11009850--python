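"""Synthetic app-review corpus generator.

Emulates the statistical structure the downstream analysis assumes: each
review's text is drawn from an LDA mixture over latent topics, its star
rating is linked to the topic mixture through a censored latent deviation
from the app's overall rating, and the deviation acts through one of two
regimes (positive- or negative-deviating) so that asymmetric topic effects
— the motivational/hygienic distinction — can be planted and later
recovered.  Contamination (duplicates, bot posts, rating–sentiment
contradictions, empty texts) is injected with provenance tags so the
preprocessing filters can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "inject_contamination",
    "sentiment_from_rating",
    "classify_true_factor",
]

#: App-level base ratings are drawn uniformly from this grid; the half-star
#: spacing leaves room for both positive and negative deviations after the
#: 1–5 clamp.
BASE_RATING_GRID = (2.5, 3.0, 3.5, 4.0, 4.5)

CONTAMINATION_KINDS = ("duplicate", "bot", "contradiction", "empty")


def sentiment_from_rating(rating: int) -> str:
    """Polarity label consistent with a star rating (>=4 positive, 3 neutral)."""
    if rating >= 4:
        return "positive"
    if rating == 3:
        return "neutral"
    return "negative"


def classify_true_factor(beta_pd: float, beta_nd: float) -> str:
    """Factor class implied by the signs of the planted deviation effects.

    A topic that raises the positive deviation (satisfaction) without raising
    the negative deviation is motivational; the converse is hygienic; raising
    both is mixed; neither is none.
    """
    pos = beta_pd > 0
    neg = beta_nd > 0
    if pos and not neg:
        return "motivational"
    if neg and not pos:
        return "hygienic"
    if pos and neg:
        return "mixed"
    return "none"


def _default_beta_pd(k: int) -> np.ndarray:
    """Two motivational, two hygienic, rest null (cycled for larger K)."""
    base = [1.2, 0.9, -0.3, -0.4, 0.0]
    return np.array([base[i % 5] for i in range(k)], dtype=float)


def _default_beta_nd(k: int) -> np.ndarray:
    base = [-0.4, -0.2, 1.8, 2.2, 0.0]
    return np.array([base[i % 5] for i in range(k)], dtype=float)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    ``beta_pd``/``beta_nd`` are the latent per-topic effects on the positive
    and negative rating deviations; ``regime_logit`` is ``(intercept,
    coef_1..coef_K)`` for the logistic probability that a review is
    positive-deviating.  ``contamination_rates`` maps each of
    ``duplicate, bot, contradiction, empty`` to the fraction of clean rows
    to inject as that kind of contamination.
    """

    n_apps: int = 20
    reviews_per_app: int | Sequence[int] = 200
    vocab_size: int = 300
    n_topics_true: int = 5
    doc_topic_conc: float = 0.3
    topic_word_conc: float = 0.05
    tokens_per_doc: int = 40
    beta_pd: Sequence[float] | None = None
    beta_nd: Sequence[float] | None = None
    regime_logit: Sequence[float] | None = None
    sigma_noise: float = 0.5
    contamination_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_topics_true
        if self.beta_pd is None:
            self.beta_pd = _default_beta_pd(k)
        if self.beta_nd is None:
            self.beta_nd = _default_beta_nd(k)
        if self.regime_logit is None:
            self.regime_logit = np.zeros(k + 1)
        self.beta_pd = np.asarray(self.beta_pd, dtype=float)
        self.beta_nd = np.asarray(self.beta_nd, dtype=float)
        self.regime_logit = np.asarray(self.regime_logit, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_apps < 1:
            raise ConfigurationError("n_apps must be a positive integer")
        if np.isscalar(self.reviews_per_app):
            if int(self.reviews_per_app) < 1:
                raise ConfigurationError("reviews_per_app must be positive")
        else:
            rpa = list(self.reviews_per_app)
            if len(rpa) != self.n_apps:
                raise ConfigurationError(
                    "reviews_per_app list must have length n_apps"
                )
            if any(int(r) < 1 for r in rpa):
                raise ConfigurationError("reviews_per_app entries must be positive")
        if self.vocab_size < 1:
            raise ConfigurationError("vocab_size must be positive")
        if self.n_topics_true < 1:
            raise ConfigurationError("n_topics_true must be positive")
        if not self.doc_topic_conc > 0:
            raise ConfigurationError("doc_topic_conc must be > 0")
        if not self.topic_word_conc > 0:
            raise ConfigurationError("topic_word_conc must be > 0")
        if self.tokens_per_doc < 1:
            raise ConfigurationError("tokens_per_doc must be positive")
        if len(self.beta_pd) != self.n_topics_true:
            raise ConfigurationError("beta_pd must have length n_topics_true")
        if len(self.beta_nd) != self.n_topics_true:
            raise ConfigurationError("beta_nd must have length n_topics_true")
        if len(self.regime_logit) != self.n_topics_true + 1:
            raise ConfigurationError(
                "regime_logit must have length n_topics_true + 1 (intercept first)"
            )
        if self.sigma_noise < 0:
            raise ConfigurationError("sigma_noise must be non-negative")
        total = 0.0
        for kind, rate in self.contamination_rates.items():
            if kind not in CONTAMINATION_KINDS:
                raise ConfigurationError(
                    f"contamination_rates: unknown kind {kind!r}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"contamination_rates[{kind!r}] must be in [0, 1]"
                )
            total += rate
        if total > 1.0 + 1e-12:
            raise ConfigurationError("contamination fractions must sum to <= 1")

    @property
    def vocabulary(self) -> list[str]:
        """The ordered synthetic token list ("w0001" ... )."""
        return _vocab(self.vocab_size)

    @property
    def reviews_per_app_list(self) -> list[int]:
        if np.isscalar(self.reviews_per_app):
            return [int(self.reviews_per_app)] * self.n_apps
        return [int(r) for r in self.reviews_per_app]


@dataclass
class GroundTruth:
    """Latent state behind the generated corpus, keyed by review_id."""

    topic_word_dists: np.ndarray  # (K, V), rows sum to 1
    review_ids: list[str]
    theta: np.ndarray  # (n_clean, K) true topic mixtures
    regime: np.ndarray  # (n_clean,) 1 = positive-deviating
    latent_deviation: np.ndarray  # (n_clean,) magnitude before censoring
    app_base_rating: dict[str, float]
    factor_class: list[str]
    beta_pd: np.ndarray
    beta_nd: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "topic_word_dists": self.topic_word_dists.tolist(),
            "review_ids": self.review_ids,
            "theta": self.theta.tolist(),
            "regime": self.regime.astype(int).tolist(),
            "latent_deviation": self.latent_deviation.tolist(),
            "app_base_rating": self.app_base_rating,
            "factor_class": self.factor_class,
            "beta_pd": self.beta_pd.tolist(),
            "beta_nd": self.beta_nd.tolist(),
        }


def _round_half_up(x: float) -> int:
    # stars round half away from zero, the way stores display them
    return int(np.floor(x + 0.5))


def _vocab(v: int) -> list[str]:
    width = max(4, len(str(v)))
    return [f"w{i:0{width}d}" for i in range(1, v + 1)]


def generate_corpus(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a review table plus its latent ground truth.

    Per review: theta* ~ Dirichlet(alpha*); tokens from the mixture of
    topic-word distributions; regime ~ Bernoulli(logistic(intercept +
    theta*.coefs)); latent magnitude m = theta*.beta_regime + eps clamped to
    [0, 4]; star rating = round(clamp(base +/- m, 1, 5)); sentiment set
    consistent with the rating.  Contamination is appended afterwards from an
    independent sub-stream, so changing contamination rates does not perturb
    the clean text.  Bit-reproducible for a fixed seed.
    """
    config.validate()
    k = config.n_topics_true
    v = config.vocab_size
    ss = np.random.SeedSequence(config.seed)
    rng_topics, rng_docs, rng_contam = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    phi = rng_topics.dirichlet([config.topic_word_conc] * v, size=k)
    vocab = _vocab(v)
    intercept, regime_coefs = config.regime_logit[0], config.regime_logit[1:]

    rpa = config.reviews_per_app_list
    n = sum(rpa)
    app_ids = [f"app{(a + 1):03d}" for a in range(config.n_apps)]
    base_ratings = {
        app: float(rng_docs.choice(BASE_RATING_GRID)) for app in app_ids
    }
    # alternate store assignment so group-wise analyses always have 2 groups
    countries = {app: ("CN" if a % 2 == 0 else "US") for a, app in enumerate(app_ids)}

    theta = rng_docs.dirichlet([config.doc_topic_conc] * k, size=n)
    doc_app = np.repeat(np.arange(config.n_apps), rpa)
    lengths = np.maximum(1, rng_docs.poisson(config.tokens_per_doc, size=n))

    p_regime = 1.0 / (1.0 + np.exp(-(intercept + theta @ regime_coefs)))
    regime = (rng_docs.random(n) < p_regime).astype(int)
    eps = rng_docs.normal(0.0, config.sigma_noise, size=n)
    mean_effect = np.where(regime == 1, theta @ config.beta_pd, theta @ config.beta_nd)
    latent = np.clip(mean_effect + eps, 0.0, 4.0)

    rows = []
    review_ids = []
    for i in range(n):
        app = app_ids[doc_app[i]]
        base = base_ratings[app]
        if regime[i] == 1:
            rating = _round_half_up(min(max(base + latent[i], 1.0), 5.0))
        else:
            rating = _round_half_up(min(max(base - latent[i], 1.0), 5.0))
        topic_draws = rng_docs.choice(k, size=lengths[i], p=theta[i])
        words = [
            vocab[w]
            for t in topic_draws
            for w in (rng_docs.choice(v, p=phi[t]),)
        ]
        rid = f"r{i + 1:06d}"
        review_ids.append(rid)
        rows.append(
            {
                "review_id": rid,
                "app_id": app,
                "country": countries[app],
                "rating": rating,
                "text": " ".join(words),
                "sentiment": sentiment_from_rating(rating),
                "bot_flag": False,
                "provenance": "clean",
            }
        )
    table = pd.DataFrame(rows)

    truth = GroundTruth(
        topic_word_dists=phi,
        review_ids=review_ids,
        theta=theta,
        regime=regime,
        latent_deviation=latent,
        app_base_rating=base_ratings,
        factor_class=[
            classify_true_factor(config.beta_pd[j], config.beta_nd[j])
            for j in range(k)
        ],
        beta_pd=config.beta_pd,
        beta_nd=config.beta_nd,
    )

    if config.contamination_rates:
        table = inject_contamination(
            table,
            config.contamination_rates,
            rng=rng_contam,
        )
    return table, truth


def _contradicting_sentiment(rating: int) -> str:
    # flip to the opposite pole; a 3-star review gets a positive label
    if rating >= 4:
        return "negative"
    if rating == 3:
        return "positive"
    return "positive"


def inject_contamination(
    table: pd.DataFrame,
    rates: Mapping[str, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Append tagged contamination rows: exact duplicates, bot posts,
    rating–sentiment contradictions, and empty texts.

    Each kind adds ``round(rate * n_clean)`` rows sampled from the clean rows,
    tagged in the ``provenance`` column so filters can be scored exactly.
    The input table is never mutated.
    """
    for kind, rate in rates.items():
        if kind not in CONTAMINATION_KINDS:
            raise ConfigurationError(f"contamination_rates: unknown kind {kind!r}")
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(
                f"contamination_rates[{kind!r}] must be in [0, 1]"
            )
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    n = len(table)
    out = [table]
    next_id = n + 1
    for kind in CONTAMINATION_KINDS:
        rate = float(rates.get(kind, 0.0))
        count = int(np.floor(rate * n + 0.5))
        if count == 0:
            continue
        idx = rng.choice(n, size=count, replace=count > n)
        block = table.iloc[idx].copy().reset_index(drop=True)
        block["review_id"] = [f"r{next_id + j:06d}" for j in range(count)]
        next_id += count
        block["provenance"] = kind
        if kind == "bot":
            block["bot_flag"] = True
        elif kind == "contradiction":
            block["sentiment"] = [
                _contradicting_sentiment(r) for r in block["rating"]
            ]
        elif kind == "empty":
            block["text"] = ""
        out.append(block)
    if len(out) == 1:
        return table.copy()
    return pd.concat(out, ignore_index=True)


def write_corpus(table: pd.DataFrame, truth: GroundTruth, outdir) -> None:
    """Write the review table as CSV + JSONL and the ground truth as JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "corpus.csv", index=False)
    table.to_json(outdir / "corpus.jsonl", orient="records", lines=True)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh)
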