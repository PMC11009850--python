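"""End-to-end orchestration: simulate -> preprocess -> topics -> deviations
-> paired censored fits -> asymmetry classification, as one seeded run that
writes every intermediate artifact plus a machine-readable summary.

A run directory contains::

    corpus.csv / corpus.jsonl / ground_truth.json   (when simulated)
    ledger.json                                     removal bookkeeping
    <group>/perplexity.csv                          when K is selected
    <group>/topic_shares.csv, keywords.csv
    <group>/fit_pd.csv, fit_nd.csv, vif.csv
    <group>/asymmetry.csv
    summary.json

Identical config + seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import deviation as dev
from .asymmetry import TwoFactorAnalysis
from .errors import ConfigurationError, DataError
from .lda import fit_lda, select_k
from .preprocessing import load_stopwords, load_synonym_map, preprocess
from .synthetic import GeneratorConfig, generate_corpus
from .tobit import vif

__all__ = ["RunConfig", "run_pipeline", "report"]

_GROUP_ARTIFACTS = (
    "topic_shares.csv", "keywords.csv", "fit_pd.csv", "fit_nd.csv",
    "vif.csv", "asymmetry.csv",
)


@dataclass
class RunConfig:
    """Declarative configuration for one reproduction run.

    Exactly one of ``generator`` / ``input_path`` supplies the corpus.
    ``group_by`` partitions the analysis (any column; the store-country
    column is just the common case); ``None`` analyzes the pooled table.
    ``k`` fixes the topic number; otherwise ``k_candidates`` are scanned by
    held-out perplexity.
    """

    outdir: str = "run"
    seed: int = 0
    generator: GeneratorConfig | None = None
    input_path: str | None = None
    group_by: str | None = "country"
    stopwords_path: str | None = None
    synonym_path: str | None = None
    run_preprocessing: bool = True
    k: int | None = None
    k_candidates: Sequence[int] | None = None
    lda_alpha: float | None = None
    lda_beta: float = 0.01
    lda_iters: int = 300
    lda_burn_in: int = 150
    exclude_topics: Sequence[int] = field(default_factory=tuple)
    intercept: bool = True
    reference_topic: int | None = None
    alpha: float = 0.05
    min_group_size: int = 30

    def validate(self) -> None:
        if (self.generator is None) == (self.input_path is None):
            raise ConfigurationError(
                "exactly one of generator / input_path must be set"
            )
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input_path does not exist: {self.input_path}")
        for name in ("stopwords_path", "synonym_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")
        if self.k is None and self.k_candidates is None:
            raise ConfigurationError("set k or k_candidates")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _json_clean(obj):
    if isinstance(obj, dict):
        return {k: _json_clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the summary dict (also written to
    ``summary.json``)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        table, truth = generate_corpus(config.generator)
        table.to_csv(out / "corpus.csv", index=False)
        table.to_json(out / "corpus.jsonl", orient="records", lines=True)
        (out / "ground_truth.json").write_text(
            json.dumps(truth.to_json_dict(), sort_keys=True)
        )
    else:
        path = Path(config.input_path)
        if path.suffix == ".jsonl":
            table = pd.read_json(path, orient="records", lines=True)
        else:
            table = pd.read_csv(path)

    stopwords = (
        load_stopwords(config.stopwords_path) if config.stopwords_path else set()
    )
    synonyms = (
        load_synonym_map(config.synonym_path) if config.synonym_path else None
    )
    if config.run_preprocessing:
        clean, ledger = preprocess(
            table, stopwords=stopwords, synonym_map=synonyms
        )
    else:
        from .preprocessing import FilterLedger, tokenize_and_clean

        ledger = FilterLedger(n_in=len(table))
        clean, ledger.removed["empty_after_stopwords"] = tokenize_and_clean(
            table, stopwords=stopwords, synonym_map=synonyms
        )
        ledger.n_out = len(clean)
        ledger.check()
    ledger.to_json(out / "ledger.json")

    if config.group_by is not None:
        if config.group_by not in clean.columns:
            raise DataError(f"group column {config.group_by!r} missing")
        groups = sorted(clean[config.group_by].astype(str).unique())
        parts = {
            g: clean[clean[config.group_by].astype(str) == g].reset_index(drop=True)
            for g in groups
        }
    else:
        parts = {"all": clean}

    summary = {
        "seed": config.seed,
        "ledger": {"n_in": ledger.n_in, "n_out": ledger.n_out,
                   "removed": ledger.removed},
        "groups": {},
    }

    for gi, (gname, gtable) in enumerate(sorted(parts.items())):
        if len(gtable) < config.min_group_size:
            summary["groups"][gname] = {
                "n_reviews": len(gtable),
                "skipped": f"fewer than {config.min_group_size} reviews",
            }
            continue
        gdir = out / gname
        gdir.mkdir(exist_ok=True)
        gseed = (config.seed + 1000 * (gi + 1)) % (2**31 - 1)
        docs = list(gtable["tokens"])

        if config.k is not None:
            chosen_k = int(config.k)
        else:
            curve = select_k(
                docs, config.k_candidates, alpha=config.lda_alpha,
                beta=config.lda_beta, n_iter=config.lda_iters,
                burn_in=config.lda_burn_in, seed=gseed,
            )
            curve.to_csv(gdir / "perplexity.csv")
            chosen_k = curve.chosen_k

        res = fit_lda(
            docs, chosen_k, alpha=config.lda_alpha, beta=config.lda_beta,
            n_iter=config.lda_iters, burn_in=config.lda_burn_in, seed=gseed,
        )
        theta = res.theta
        assignments = res.assign_topics()
        labels = [f"topic_{j}" for j in range(chosen_k)]
        shares = dev.topic_share_table(assignments, labels)
        shares.to_csv(gdir / "topic_shares.csv", index=False)
        pd.DataFrame(
            {"topic": range(chosen_k),
             "keywords": ["|".join(ws) for ws in res.top_keywords(7)]}
        ).to_csv(gdir / "keywords.csv", index=False)

        devs = dev.deviation_table(gtable)
        satisfaction = dev.satisfaction_rate(gtable)

        analysis = TwoFactorAnalysis(
            theta, devs["pd"].to_numpy(), devs["nd"].to_numpy(),
            topic_labels=labels,
            exclude=config.exclude_topics,
            reference=config.reference_topic,
            intercept=config.intercept,
            alpha=config.alpha,
        )
        two = analysis.fit()
        two.fit_pd.to_frame().to_csv(gdir / "fit_pd.csv", index=False)
        two.fit_nd.to_frame().to_csv(gdir / "fit_nd.csv", index=False)
        X, names = analysis._design(theta)
        cols = slice(1, None) if config.intercept else slice(None)
        vif(X[:, cols], names[1:] if config.intercept else names).to_csv(
            gdir / "vif.csv", header=True
        )
        two.table.to_csv(gdir / "asymmetry.csv", index=False)

        summary["groups"][gname] = {
            "n_reviews": int(len(gtable)),
            "satisfaction_rate_pct": satisfaction,
            "chosen_k": chosen_k,
            "loglik_pd": round(two.fit_pd.llf, 6),
            "loglik_nd": round(two.fit_nd.llf, 6),
            "factor_classes": dict(
                zip(two.table["label"], two.table["factor_class"])
            ),
        }

    summary = _json_clean(summary)
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
    return summary


def report(run_dir) -> str:
    """Human-readable digest of a completed run directory."""
    run_dir = Path(run_dir)
    missing = [
        name for name in ("summary.json", "ledger.json")
        if not (run_dir / name).exists()
    ]
    if missing:
        raise DataError(f"incomplete run, missing artifacts: {missing}")
    summary = json.loads((run_dir / "summary.json").read_text())
    lines = ["Review two-factor analysis report", "=" * 34]
    led = summary["ledger"]
    lines.append(
        f"reviews in: {led['n_in']}   out: {led['n_out']}   "
        f"removed: {sum(led['removed'].values())} {led['removed']}"
    )
    for gname, g in sorted(summary["groups"].items()):
        lines.append("")
        lines.append(f"[{gname}]")
        if "skipped" in g:
            lines.append(f"  skipped: {g['skipped']} (n={g['n_reviews']})")
            continue
        missing = [
            a for a in _GROUP_ARTIFACTS if not (run_dir / gname / a).exists()
        ]
        if missing:
            raise DataError(
                f"incomplete run, group {gname!r} missing artifacts: {missing}"
            )
        lines.append(f"  reviews: {g['n_reviews']}")
        lines.append(f"  satisfaction rate: {g['satisfaction_rate_pct']:.2f}%")
        lines.append(f"  topics (K): {g['chosen_k']}")
        lines.append(
            f"  log-likelihood  PD: {g['loglik_pd']:.3f}  ND: {g['loglik_nd']:.3f}"
        )
        shares = pd.read_csv(run_dir / gname / "topic_shares.csv")
        top = shares.iloc[0]
        lines.append(
            f"  largest topic: {top['label']} "
            f"({int(top['count'])}/{g['n_reviews']}, {top['percentage']:.2f}%)"
        )
        for label, cls in g["factor_classes"].items():
            lines.append(f"    {label}: {cls}")
    return "\n".join(lines)
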