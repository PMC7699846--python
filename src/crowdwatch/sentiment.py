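"""Lexicon-based sentiment scoring with five-group binning.

Each post receives a score in [0, 1] (high = positive) via a logistic
transform of the mean polarity of its lexicon-covered tokens:

    score = 1 / (1 + exp(-gain * mean_polarity)),   gain = 3 by default.

Tokens absent from the lexicon are excluded from the mean (coverage does
not dilute polarity); documents with no covered tokens score a neutral 0.5.
Scores are binned into five groups of width 0.2 — Group 1 ([0, 0.2), most
negative) through Group 5 ([0.8, 1.0], most positive); bins are half-open
on the left except the last, which is closed so the groups partition [0, 1].
Groups 1-2 together define the negative-sentiment proportion tracked per
hour.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spatial import BinSeries, bin_index, time_bins

NEGATIVE_GROUPS = (1, 2)
DEFAULT_GAIN = 3.0


def load_lexicon(path: str | Path) -> dict[str, float]:
    """Read a ``token,polarity`` CSV lexicon; polarities must be finite."""
    lex: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            w = float(row["polarity"])
            if not math.isfinite(w):
                raise ValueError(f"non-finite polarity for {row['token']!r}")
            lex[row["token"]] = w
    return lex


def save_lexicon(lexicon: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["token", "polarity"])
        for tok, pol in lexicon.items():
            w.writerow([tok, repr(float(pol))])


def check_lexicon(lexicon: Mapping[str, float]) -> None:
    for tok, w in lexicon.items():
        if not math.isfinite(w):
            raise ValueError(f"non-finite polarity for {tok!r}")
    if not any(w != 0 for w in lexicon.values()):
        warnings.warn("lexicon has no nonzero polarity entries", stacklevel=3)


@dataclass(frozen=True)
class SentimentScore:
    """A [0, 1] post score and how many tokens contributed to it."""

    value: float
    n_scored_tokens: int


def score_document(
    tokens: Iterable[str],
    lexicon: Mapping[str, float],
    gain: float = DEFAULT_GAIN,
) -> SentimentScore:
    """Score one document; 0.5 is neutral, > 0.5 positive, < 0.5 negative."""
    weights = [lexicon[t] for t in tokens if t in lexicon]
    if not weights:
        return SentimentScore(0.5, 0)
    mean = sum(weights) / len(weights)
    return SentimentScore(1.0 / (1.0 + math.exp(-gain * mean)), len(weights))


#: Interior group boundaries; comparisons use these literals so boundary
#: scores (exactly 0.2, 0.4, ...) bin deterministically into the upper group.
GROUP_BOUNDS = (0.2, 0.4, 0.6, 0.8)


def sentiment_group(score: float) -> int:
    """Five-group binning: [0,.2) -> 1 ... [.8,1] -> 5."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    from bisect import bisect_right

    return bisect_right(GROUP_BOUNDS, score) + 1


def negative_proportion(
    groups: Sequence[int],
    timestamps: Sequence[datetime],
    window: tuple[datetime, datetime],
    granularity: str = "hour",
) -> BinSeries:
    """Per-bin proportion of posts in Groups 1-2; empty bins are NaN."""
    if len(groups) != len(timestamps):
        raise ValueError("groups and timestamps length mismatch")
    starts, width = time_bins(window, granularity)
    neg = np.zeros(len(starts))
    tot = np.zeros(len(starts))
    for g, t in zip(groups, timestamps):
        if g not in (1, 2, 3, 4, 5):
            raise ValueError(f"invalid sentiment group {g}")
        k = bin_index(t, starts, width)
        if k is None:
            continue
        tot[k] += 1
        if g in NEGATIVE_GROUPS:
            neg[k] += 1
    values = np.where(tot > 0, neg / np.where(tot > 0, tot, 1), np.nan)
    return BinSeries(starts, width, values, "negative_proportion")


def export_scores_csv(
    ids: Sequence[str],
    scores: Sequence[SentimentScore],
    path: str | Path,
) -> None:
    """Write ``id,score,group`` for scored records."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "score", "group"])
        for rid, s in zip(ids, scores):
            w.writerow([rid, repr(float(s.value)), sentiment_group(s.value)])
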