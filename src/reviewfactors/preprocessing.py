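"""Review-table cleaning: deduplication, bot and emptiness filters, sentiment
assignment, the sentiment–rating consistency screen, tokenization, stop-word
removal and synonym normalization.

Every removal is counted in a :class:`FilterLedger` so the bookkeeping
``n_in = n_out + sum(removals)`` can always be audited.  The filters run in a
fixed documented order: no-text -> bot -> duplicate/blank/language ->
sentiment consistency -> tokenization/stop-word emptiness.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .errors import DataError

__all__ = [
    "FilterLedger",
    "LexiconSentiment",
    "deduplicate",
    "consistency_filter",
    "tokenize_and_clean",
    "apply_bot_filter",
    "drop_no_text",
    "assign_sentiment",
    "preprocess",
    "load_stopwords",
    "load_synonym_map",
]

LEDGER_STEPS = (
    "no_text",
    "bot",
    "duplicate_blank_language",
    "contradiction",
    "empty_after_stopwords",
)


@dataclass
class FilterLedger:
    """Removal counts per preprocessing step; conserves row counts."""

    n_in: int = 0
    n_out: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {step: 0 for step in LEDGER_STEPS}
    )

    def check(self) -> None:
        total = sum(self.removed.values())
        if self.n_in - total != self.n_out:
            raise AssertionError(
                f"ledger violation: {self.n_in} - {total} != {self.n_out}"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n_in": self.n_in, "n_out": self.n_out, "removed": self.removed},
                fh,
                indent=2,
                sort_keys=True,
            )


# --- sentiment -------------------------------------------------------------

#: Deliberately tiny signed lexicon; the pluggable interface is the point,
#: not lexicon coverage.  Real deployments swap in a trained polarity model.
_DEFAULT_LEXICON = {
    "good": 1, "great": 1, "love": 1, "easy": 1, "simple": 1, "useful": 1,
    "helpful": 1, "accurate": 1, "convenient": 1, "recommend": 1, "excellent": 1,
    "bad": -1, "crash": -1, "crashes": -1, "terrible": -1, "useless": -1,
    "broken": -1, "inaccurate": -1, "slow": -1, "expensive": -1, "awful": -1,
    "bug": -1, "fail": -1, "fails": -1, "scam": -1,
}


class LexiconSentiment:
    """Polarity scorer from a signed word lexicon.

    The sum of word scores maps to negative / neutral / positive.  Any
    callable ``str -> {"negative","neutral","positive"}`` can replace it.
    """

    def __init__(self, lexicon: Mapping[str, int] | None = None):
        self.lexicon = dict(_DEFAULT_LEXICON if lexicon is None else lexicon)

    def __call__(self, text: str) -> str:
        score = sum(self.lexicon.get(w, 0) for w in str(text).lower().split())
        if score > 0:
            return "positive"
        if score < 0:
            return "negative"
        return "neutral"


def assign_sentiment(
    table: pd.DataFrame, scorer: Callable[[str], str] | None = None
) -> pd.DataFrame:
    """Attach a sentiment column; existing labels are kept unless a scorer is
    forced.  The synthetic pipeline emits labels directly and skips scoring."""
    if "sentiment" in table.columns and scorer is None:
        return table
    scorer = scorer or LexiconSentiment()
    out = table.copy()
    out["sentiment"] = [scorer(t) for t in out["text"]]
    return out


# --- filters ---------------------------------------------------------------


def drop_no_text(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove rows whose text is missing or whitespace-only."""
    text = table["text"].fillna("").astype(str).str.strip()
    keep = text != ""
    return table[keep].reset_index(drop=True), int((~keep).sum())


def apply_bot_filter(
    table: pd.DataFrame,
    predicate: Callable[[pd.Series], bool] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Remove rows the bot predicate flags.

    The default predicate trusts a ``bot_flag`` column when present and keeps
    everything otherwise; swap in any row -> bool callable (the upstream
    study used a dedicated bot classifier, which is out of scope here).
    """
    if predicate is None:
        if "bot_flag" not in table.columns:
            return table.reset_index(drop=True), 0
        flags = table["bot_flag"].fillna(False).astype(bool)
    else:
        flags = table.apply(predicate, axis=1).astype(bool)
    keep = ~flags
    return table[keep].reset_index(drop=True), int(flags.sum())


_WS = re.compile(r"\s+")


def _normalize_text(s: str) -> str:
    return _WS.sub(" ", str(s)).strip().casefold()


def deduplicate(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse exact duplicates on (app_id, rating, normalized text).

    The first occurrence in input order survives.  user/review ids are not
    part of the key because stores anonymize them inconsistently.
    """
    key = pd.DataFrame(
        {
            "app_id": table["app_id"],
            "rating": table["rating"],
            "norm_text": table["text"].map(_normalize_text),
        }
    )
    keep = ~key.duplicated(keep="first")
    return table[keep].reset_index(drop=True), int((~keep).sum())


_CONSISTENT = {
    (1, "negative"), (2, "negative"),
    (3, "neutral"),
    (4, "positive"), (5, "positive"),
}


def consistency_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep only rows whose sentiment polarity matches their star rating.

    The matching matrix pairs ratings 1–2 with negative, 3 with neutral and
    4–5 with positive polarity; any other combination is treated as a
    contradiction between the text and the rating and removed.
    """
    if "sentiment" not in table.columns:
        raise DataError("consistency_filter requires a sentiment column")
    missing = table["sentiment"].isna()
    if missing.any():
        rid = table.loc[missing, "review_id"].iloc[0]
        raise DataError(f"missing sentiment for review {rid!r}")
    keep = [
        (int(r), s) in _CONSISTENT
        for r, s in zip(table["rating"], table["sentiment"])
    ]
    keep = pd.Series(keep, index=table.index)
    return table[keep].reset_index(drop=True), int((~keep).sum())


# --- tokenization ----------------------------------------------------------

_NON_WORD = re.compile(r"^[\W\d_]+$", re.UNICODE)


def default_tokenizer(text: str) -> list[str]:
    """Whitespace tokenizer with Latin-script lowercasing."""
    return [t.lower() for t in str(text).split()]


def tokenize_and_clean(
    table: pd.DataFrame,
    tokenizer: Callable[[str], list[str]] | None = None,
    stopwords: Iterable[str] = (),
    synonym_map: Mapping[str, str] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Tokenize, drop stop words and purely numeric/punctuation tokens,
    apply the synonym map token-wise, and drop rows left empty.

    Returns the table with a ``tokens`` column plus the count of rows dropped
    for emptiness after stop-word removal.  An optional lemmatizer is applied
    before the stop-word check (morphological normalization for English).
    """
    tokenizer = tokenizer or default_tokenizer
    stop = set(stopwords)
    syn = dict(synonym_map or {})
    all_tokens = []
    for text in table["text"]:
        toks = []
        for t in tokenizer(text):
            if lemmatizer is not None:
                t = lemmatizer(t)
            if t in stop or _NON_WORD.match(t):
                continue
            toks.append(syn.get(t, t))
        all_tokens.append(toks)
    out = table.copy()
    out["tokens"] = all_tokens
    keep = out["tokens"].map(len) > 0
    return out[keep].reset_index(drop=True), int((~keep).sum())


def load_stopwords(path) -> set[str]:
    """One token per line, UTF-8; blank lines ignored."""
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise DataError(f"cannot read stop-word file {path}: {exc}") from exc
    return {ln.strip() for ln in lines if ln.strip()}


def load_synonym_map(path) -> dict[str, str]:
    """Two-column TSV, variant -> canonical."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise DataError(f"cannot read synonym map {path}: {exc}") from exc
    mapping = {}
    for ln in text.splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise DataError(f"synonym map line is not two-column TSV: {ln!r}")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


# --- the documented pipeline ----------------------------------------------


def preprocess(
    table: pd.DataFrame,
    tokenizer: Callable[[str], list[str]] | None = None,
    stopwords: Iterable[str] = (),
    synonym_map: Mapping[str, str] | None = None,
    bot_predicate: Callable[[pd.Series], bool] | None = None,
    sentiment_scorer: Callable[[str], str] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
) -> tuple[pd.DataFrame, FilterLedger]:
    """Run the full cleaning sequence and return (clean table, ledger)."""
    ledger = FilterLedger(n_in=len(table))
    table, ledger.removed["no_text"] = drop_no_text(table)
    table, ledger.removed["bot"] = apply_bot_filter(table, bot_predicate)
    table, ledger.removed["duplicate_blank_language"] = deduplicate(table)
    table = assign_sentiment(table, sentiment_scorer)
    table, ledger.removed["contradiction"] = consistency_filter(table)
    table, ledger.removed["empty_after_stopwords"] = tokenize_and_clean(
        table, tokenizer, stopwords, synonym_map, lemmatizer
    )
    ledger.n_out = len(table)
    ledger.check()
    return table, ledger
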