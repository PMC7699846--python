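"""Topic modeling of check-in text: LDA with stampede-class keyword mapping.

Documents are bags of atomic tokens. An LDA model with symmetric Dirichlet
priors (alpha on document-topic mixtures theta_d, beta on topic-word
distributions phi_k) is fit by collapsed Gibbs sampling; each record is then
labelled by its dominant topic, each topic is mapped to one of the classes

    crowd_complaint > relief > blessing > unrelated

by intersecting its top-K most probable words with per-class keyword sets
(precedence resolves multi-class hits), and per-class hourly proportion
series summarize how the conversation shifts during a mass-gathering event.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _gibbs
from .records import CheckInRecord
from .spatial import BinSeries, bin_index, time_bins

STAMPEDE_CLASSES = ("crowd_complaint", "relief", "blessing")
UNRELATED = "unrelated"


class CorpusError(ValueError):
    """Raised when a corpus cannot be built or fit."""


@dataclass(frozen=True)
class Vocabulary:
    """Dense token <-> integer id bijection (ids in [0, n_words))."""

    tokens: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index is None:
            object.__setattr__(
                self, "index", {t: i for i, t in enumerate(self.tokens)}
            )
        if len(self.index) != len(self.tokens):
            raise CorpusError("vocabulary tokens must be unique")

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, token: str) -> int:
        return self.index[token]


@dataclass
class PreprocessReport:
    """Bookkeeping from corpus construction (validity accounting)."""

    n_input: int = 0
    n_duplicates: int = 0
    n_empty_after_filtering: int = 0
    n_valid: int = 0


@dataclass
class Corpus:
    """Tokenized documents as id sequences, linked to source records."""

    documents: list[np.ndarray]
    record_ids: list[str]
    timestamps: list[datetime]
    vocabulary: Vocabulary
    report: PreprocessReport = field(default_factory=PreprocessReport)

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.documents))


def preprocess(
    records: Sequence[CheckInRecord],
    stop_tokens: Iterable[str] = (),
    removal_terms: Iterable[str] = (),
) -> tuple[Corpus, Vocabulary]:
    """Deduplicate, filter, and index records into a corpus.

    Exact duplicates (same tokens, timestamp and coordinates) are dropped,
    keeping the first. Stop tokens and removal terms (e.g. the dominant
    holiday-greeting words that would swamp every topic) are deleted;
    records left with no tokens are excluded from the corpus but counted in
    the report. Matching is exact string equality — tokens are atomic.
    """
    drop = set(stop_tokens) | set(removal_terms)
    report = PreprocessReport(n_input=len(records))
    seen: set[tuple] = set()
    kept: list[tuple[CheckInRecord, tuple[str, ...]]] = []
    for rec in records:
        key = (rec.tokens, rec.timestamp, rec.lon, rec.lat)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        tokens = tuple(t for t in rec.tokens if t not in drop)
        if not tokens:
            report.n_empty_after_filtering += 1
            continue
        kept.append((rec, tokens))
    if not kept:
        raise CorpusError(
            "no records remain after deduplication and filtering "
            f"({report.n_duplicates} duplicates, "
            f"{report.n_empty_after_filtering} emptied)"
        )
    report.n_valid = len(kept)
    vocab = Vocabulary(tuple(sorted({t for _, toks in kept for t in toks})))
    corpus = Corpus(
        documents=[
            np.array([vocab[t] for t in toks], dtype=np.int64)
            for _, toks in kept
        ],
        record_ids=[rec.id for rec, _ in kept],
        timestamps=[rec.timestamp for rec, _ in kept],
        vocabulary=vocab,
        report=report,
    )
    return corpus, vocab


def corpus_from_documents(
    documents: Sequence[Sequence[int]],
    vocabulary: Vocabulary,
    timestamps: Sequence[datetime] | None = None,
    record_ids: Sequence[str] | None = None,
) -> Corpus:
    """Wrap pre-tokenized id sequences (e.g. from the synthetic generator)
    as a Corpus without record-level preprocessing."""
    from .records import CST
    from datetime import datetime as _dt

    docs = [np.asarray(d, dtype=np.int64) for d in documents]
    for d in docs:
        if d.size and (d.min() < 0 or d.max() >= len(vocabulary)):
            raise CorpusError("word id outside vocabulary")
    n = len(docs)
    if timestamps is None:
        timestamps = [_dt(2014, 12, 31, tzinfo=CST)] * n
    if record_ids is None:
        record_ids = [f"d{i}" for i in range(n)]
    report = PreprocessReport(n_input=n, n_valid=n)
    return Corpus(docs, list(record_ids), list(timestamps), vocabulary, report)


@dataclass
class LDAModel:
    """Fitted LDA state: phi (topics x words), theta (docs x topics), Z."""

    n_topics: int
    alpha: float
    beta: float
    phi: np.ndarray
    theta: np.ndarray
    z: np.ndarray  # flat per-word assignments, aligned with doc_ids
    doc_ids: np.ndarray
    word_ids: np.ndarray
    seed: int
    n_iterations: int


def fit_lda(
    corpus: Corpus,
    n_topics: int,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iterations: int = 1000,
    seed: int = 0,
) -> LDAModel:
    """Fit LDA by collapsed Gibbs sampling.

    Point estimates come from the final chain state with prior smoothing:
    phi_kv ∝ n_kv + beta, theta_dk ∝ n_dk + alpha. ``alpha`` defaults to
    the common heuristic 50 / n_topics. Identical (corpus, parameters,
    seed) yield an identical model.
    """
    if corpus.n_documents < 1:
        raise CorpusError("corpus is empty")
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    total_words = corpus.n_tokens
    if n_topics > total_words:
        raise ValueError(
            f"n_topics={n_topics} exceeds total word count {total_words}"
        )
    if alpha is None:
        alpha = 50.0 / n_topics
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")

    doc_ids = np.concatenate(
        [np.full(len(d), i, dtype=np.int64) for i, d in enumerate(corpus.documents)]
    )
    word_ids = np.concatenate(corpus.documents)
    n_vocab = len(corpus.vocabulary)
    z, n_dk, n_kv, n_k = _gibbs.run_gibbs(
        doc_ids, word_ids, corpus.n_documents, n_topics, n_vocab,
        alpha, beta, n_iterations, seed,
    )
    phi = (n_kv + beta) / (n_k[:, None] + n_vocab * beta)
    doc_len = n_dk.sum(axis=1)
    theta = (n_dk + alpha) / (doc_len[:, None] + n_topics * alpha)
    return LDAModel(
        n_topics=n_topics,
        alpha=alpha,
        beta=beta,
        phi=phi,
        theta=theta,
        z=z,
        doc_ids=doc_ids,
        word_ids=word_ids,
        seed=seed,
        n_iterations=n_iterations,
    )


def dominant_topic(theta_d: Sequence[float]) -> int:
    """Topic of maximum probability in a document mixture (ties: lowest id)."""
    v = np.asarray(theta_d, dtype=float)
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"theta does not sum to 1 (sum={v.sum()!r})")
    return int(np.argmax(v))


@dataclass(frozen=True)
class TopicClassMap:
    """Keyword sets defining the stampede-related classes.

    Class precedence is the order of :data:`STAMPEDE_CLASSES`; ``unrelated``
    is the keyword-free fallback. Keyword sets must be pairwise disjoint.
    ``top_k`` is the number of most-probable words examined per topic.
    """

    keywords: Mapping[str, frozenset[str]]
    top_k: int = 10

    def __post_init__(self) -> None:
        kw = {c: frozenset(self.keywords.get(c, ())) for c in STAMPEDE_CLASSES}
        object.__setattr__(self, "keywords", kw)
        for a in STAMPEDE_CLASSES:
            for b in STAMPEDE_CLASSES:
                if a < b and kw[a] & kw[b]:
                    raise ValueError(
                        f"keyword sets for {a!r} and {b!r} overlap: "
                        f"{sorted(kw[a] & kw[b])}"
                    )
        if all(not s for s in kw.values()):
            warnings.warn(
                "empty class map: every topic will be classified unrelated",
                stacklevel=3,
            )


def classify_keywords(words: Iterable[str], class_map: TopicClassMap) -> str:
    """Class of a word set: first class whose keywords intersect it."""
    wset = set(words)
    for cls in STAMPEDE_CLASSES:
        if class_map.keywords[cls] & wset:
            return cls
    return UNRELATED


def top_words(model: LDAModel, topic_id: int, vocabulary: Vocabulary, k: int) -> list[str]:
    """The k most probable words of a topic (ties broken by lower word id)."""
    row = model.phi[topic_id]
    order = np.lexsort((np.arange(len(row)), -row))
    return [vocabulary.tokens[i] for i in order[:k]]


def classify_topic(
    model: LDAModel,
    topic_id: int,
    class_map: TopicClassMap,
    vocabulary: Vocabulary,
) -> str:
    """Classify one fitted topic by its top-K word list."""
    if not 0 <= topic_id < model.n_topics:
        raise ValueError(f"topic_id {topic_id} out of range")
    if class_map.top_k <= 0:
        return UNRELATED
    return classify_keywords(
        top_words(model, topic_id, vocabulary, class_map.top_k), class_map
    )


def is_stampede_related(label: str) -> bool:
    return label in STAMPEDE_CLASSES


def class_series(
    labels: Sequence[str],
    timestamps: Sequence[datetime],
    window: tuple[datetime, datetime],
    granularity: str = "hour",
) -> dict[str, BinSeries]:
    """Per-class proportion series over clock-aligned bins.

    In every non-empty bin the proportions over all classes (including
    ``unrelated``) sum to 1; empty bins are undefined (NaN).
    """
    if len(labels) != len(timestamps):
        raise ValueError("labels and timestamps length mismatch")
    starts, width = time_bins(window, granularity)
    classes = list(STAMPEDE_CLASSES) + [UNRELATED]
    counts = {c: np.zeros(len(starts)) for c in classes}
    totals = np.zeros(len(starts))
    for lab, t in zip(labels, timestamps):
        k = bin_index(t, starts, width)
        if k is None:
            continue
        totals[k] += 1
        counts[lab][k] += 1
    out: dict[str, BinSeries] = {}
    for c in classes:
        vals = np.where(totals > 0, counts[c] / np.where(totals > 0, totals, 1), np.nan)
        out[c] = BinSeries(starts, width, vals, f"proportion:{c}")
    return out


# ---------------------------------------------------------------------------
# Exports


def export_phi_csv(model: LDAModel, vocabulary: Vocabulary, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["topic", "word", "probability"])
        for k in range(model.n_topics):
            for v, tok in enumerate(vocabulary.tokens):
                w.writerow([k, tok, repr(float(model.phi[k, v]))])


def export_theta_csv(model: LDAModel, corpus: Corpus, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["doc", "topic", "probability"])
        for d, rid in enumerate(corpus.record_ids):
            for k in range(model.n_topics):
                w.writerow([rid, k, repr(float(model.theta[d, k]))])


def topic_report(
    model: LDAModel,
    corpus: Corpus,
    class_map: TopicClassMap,
) -> list[dict]:
    """Per-topic summary: top-K words, class, share of documents."""
    dom = [dominant_topic(model.theta[d]) for d in range(corpus.n_documents)]
    shares = np.bincount(dom, minlength=model.n_topics) / corpus.n_documents
    out = []
    for k in range(model.n_topics):
        words = top_words(model, k, corpus.vocabulary, class_map.top_k)
        out.append(
            {
                "topic": k,
                "top_words": words,
                "class": classify_keywords(words, class_map),
                "document_share": float(shares[k]),
            }
        )
    return out


def export_topic_report(report: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
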