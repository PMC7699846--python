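"""Synthetic check-in scenario generator.

Emulates the data surrounding a mass-gathering emergency — the default
configuration mirrors the night of the 2014 Shanghai New Year's Eve
stampede at the Bund:

* a homogeneous Poisson background of check-ins over a city bounding box;
* an event hotspot around Chen Yi Plaza whose hourly intensity ramps in
  proportion to the reported crowd sizes (120k : 160k : 240k : 310k people
  between 20:00 and midnight), scaled so the peak hour roughly doubles the
  background count;
* post text drawn from the LDA generative process (per-document topic
  mixture theta_d ~ Dirichlet(alpha); each word's topic ~ Multinomial(theta_d),
  word ~ Multinomial(phi_topic)), with event-period mixtures shifted toward
  the crowd topic;
* two polarity tokens appended per post, shifted toward negative polarity
  during the event window.

Randomness is a single seeded stream split into documented substreams
(spatial, temporal, textual), so identical (config, seed) pairs reproduce
byte-identical output.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import CST, CheckInRecord

KM_PER_DEG_LAT = math.pi / 180.0 * 6371.0088


class ScenarioError(ValueError):
    """Raised for invalid scenario configurations."""


@dataclass(frozen=True)
class VocabSpec:
    """Class-tagged synthetic vocabulary.

    ``topic_groups`` lists (class_tag, tokens) per topic; polarity tokens
    are kept separate from the topical vocabulary (they carry zero mass in
    the topic-word distributions and are appended to documents by the
    sentiment substream).
    """

    topic_groups: tuple[tuple[str, tuple[str, ...]], ...]
    positive: tuple[str, ...]
    negative: tuple[str, ...]

    @property
    def tokens(self) -> tuple[str, ...]:
        """All tokens, ids dense: topical words first, then +/- polarity."""
        topical = tuple(t for _, toks in self.topic_groups for t in toks)
        return topical + self.positive + self.negative

    @property
    def n_topics(self) -> int:
        return len(self.topic_groups)

    def class_tags(self) -> dict[str, str]:
        tags = {t: tag for tag, toks in self.topic_groups for t in toks}
        tags.update({t: "positive-polarity" for t in self.positive})
        tags.update({t: "negative-polarity" for t in self.negative})
        return tags

    def crowd_topics(self) -> list[int]:
        return [k for k, (tag, _) in enumerate(self.topic_groups) if tag == "crowd-related"]

    def true_phi(self, own_mass: float = 0.9) -> np.ndarray:
        """Row-stochastic topic-word matrix: ``own_mass`` on the topic's own
        words, the rest spread uniformly over all topical words; zero on
        polarity tokens."""
        topical = [t for _, toks in self.topic_groups for t in toks]
        n_topical = len(topical)
        n_vocab = len(self.tokens)
        phi = np.zeros((self.n_topics, n_vocab))
        offset = 0
        for k, (_, toks) in enumerate(self.topic_groups):
            phi[k, :n_topical] = (1.0 - own_mass) / n_topical
            phi[k, offset : offset + len(toks)] += own_mass / len(toks)
            offset += len(toks)
        return phi


DEFAULT_VOCAB = VocabSpec(
    topic_groups=(
        (
            "crowd-related",
            ("crowd", "stampede", "bund", "squeeze", "push", "crush",
             "danger", "people", "jam", "plaza"),
        ),
        (
            "blessing",
            ("bless", "pray", "peace", "candle", "mourn", "rest",
             "condolence", "heaven", "memorial", "wish"),
        ),
        (
            "relief",
            ("relief", "lucky", "escape", "avoid", "home", "safe",
             "alive", "gloat", "missed", "fortunate"),
        ),
        (
            "neutral",
            ("breakfast", "noodle", "coffee", "restaurant", "dinner",
             "tea", "soup", "rice", "snack", "milk"),
        ),
        (
            "neutral",
            ("work", "office", "meeting", "email", "project", "boss",
             "deadline", "commute", "subway", "report"),
        ),
        (
            "neutral",
            ("newyear", "firework", "countdown", "party", "music",
             "friend", "photo", "night", "city", "lights"),
        ),
    ),
    positive=("good", "happy", "great", "love", "nice", "joy"),
    negative=("sad", "terrible", "cry", "fear", "angry", "awful"),
)

#: Hourly crowd ramp 120k:160k:240k:310k, normalized to the first hour.
EVENT_RAMP = (1.0, 160.0 / 120.0, 2.0, 310.0 / 120.0)

BUND_CENTER = (121.4906, 31.2397)  # Chen Yi Plaza, the Bund


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic scenario.

    Defaults reproduce the Shanghai New Year's Eve setting: a ~27 km box
    of central Shanghai containing the 10-km Bund buffer, 48 hours of a
    120 records/hour background, and a four-hour evening event whose peak
    hour roughly doubles the city-wide hourly count (the Bund-area subset
    shows proportionally stronger contrast). The hotspot spread (2.5 km)
    is chosen to span several 2-arcmin grid cells so aggregation registers
    as spatial autocorrelation rather than a single-cell spike.
    """

    bbox: tuple[float, float, float, float] = (121.35, 31.12, 121.63, 31.36)
    start: datetime = datetime(2014, 12, 30, 12, 0, tzinfo=CST)
    end: datetime = datetime(2015, 1, 1, 12, 0, tzinfo=CST)
    background_rate: float = 120.0  # expected records/hour over bbox
    event_center: tuple[float, float] = BUND_CENTER
    event_sigma_km: float = 2.5
    event_window: tuple[datetime, datetime] | None = (
        datetime(2014, 12, 31, 20, 0, tzinfo=CST),
        datetime(2015, 1, 1, 0, 0, tzinfo=CST),
    )
    event_hourly_multipliers: tuple[float, ...] = EVENT_RAMP
    event_rate_scale: float = 56.0  # records/hour per unit multiplier
    n_topics: int = DEFAULT_VOCAB.n_topics
    vocab: VocabSpec = DEFAULT_VOCAB
    alpha: float = 0.3
    beta: float = 0.01
    doc_length_mean: float = 8.0
    event_topic_shift: float = 0.7
    event_negative_shift: float = 0.35
    n_sentiment_tokens: int = 2
    background_positive_prob: float = 0.5
    seed: int = 0

    def without_event(self) -> "ScenarioConfig":
        """The matching null scenario (background only)."""
        return replace(self, event_window=None)

    def validate(self) -> None:
        lon_min, lat_min, lon_max, lat_max = self.bbox
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ScenarioError(f"degenerate bbox {self.bbox}")
        if self.end <= self.start:
            raise ScenarioError("scenario end must be after start")
        if self.background_rate < 0:
            raise ScenarioError("background_rate must be nonnegative")
        if self.event_window is not None:
            ev_start, ev_end = self.event_window
            if ev_start >= ev_end:
                raise ScenarioError("event_window must be non-empty")
            if ev_start < self.start or ev_end > self.end:
                raise ScenarioError("event_window must lie within [start, end]")
            n_hours = (ev_end - ev_start) / timedelta(hours=1)
            if abs(n_hours - round(n_hours)) > 1e-9:
                raise ScenarioError("event_window must span whole hours")
            if len(self.event_hourly_multipliers) == 0:
                raise ScenarioError(
                    "event_hourly_multipliers empty with a non-empty event_window"
                )
            if len(self.event_hourly_multipliers) != int(round(n_hours)):
                raise ScenarioError(
                    f"{len(self.event_hourly_multipliers)} multipliers for "
                    f"{int(round(n_hours))} event hours"
                )
            if any(m < 0 for m in self.event_hourly_multipliers):
                raise ScenarioError("multipliers must be nonnegative")
        if not 0 <= self.event_topic_shift <= 1:
            raise ScenarioError("event_topic_shift must be in [0, 1]")
        if not 0 <= self.event_negative_shift <= 1:
            raise ScenarioError("event_negative_shift must be in [0, 1]")
        if self.n_topics != self.vocab.n_topics:
            raise ScenarioError("n_topics must match the vocabulary's topic groups")


@dataclass
class GroundTruth:
    """Latent state behind a generated scenario (for recovery tests)."""

    true_phi: np.ndarray  # n_topics x n_vocab, rows sum to 1
    theta: np.ndarray  # n_records x n_topics
    event_flags: np.ndarray  # bool per record
    mean_polarity: np.ndarray  # true mean polarity of appended tokens
    vocab_tokens: tuple[str, ...]


def generate_document(
    theta_d: Sequence[float],
    phi: np.ndarray,
    n_words: int,
    rng: np.random.Generator,
    tokens: Sequence[str] | None = None,
) -> list:
    """Draw one document from the LDA generative process.

    The n-th word's topic is Multinomial(theta_d) and the word itself is
    Multinomial(phi[topic]). Returns token strings if ``tokens`` is given,
    else integer word ids.
    """
    theta = np.asarray(theta_d, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if abs(theta.sum() - 1.0) > 1e-9:
        raise ValueError("theta_d must sum to 1")
    if np.any(np.abs(phi.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("phi rows must sum to 1")
    if n_words < 0:
        raise ValueError("n_words must be nonnegative")
    if n_words == 0:
        return []
    z = rng.choice(len(theta), size=n_words, p=theta)
    words = np.empty(n_words, dtype=np.int64)
    for k in np.unique(z):
        mask = z == k
        words[mask] = rng.choice(phi.shape[1], size=int(mask.sum()), p=phi[k])
    if tokens is None:
        return [int(w) for w in words]
    return [tokens[w] for w in words]


def sample_points(
    n: int,
    bbox: tuple[float, float, float, float],
    rng: np.random.Generator,
    center: tuple[float, float] | None = None,
    sigma_km: float | None = None,
) -> np.ndarray:
    """Sample (lon, lat) points: uniform over bbox, or Gaussian around a
    center with spread ``sigma_km`` (converted to degrees at the center's
    latitude), rejected-and-resampled into the bbox."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    lon_min, lat_min, lon_max, lat_max = bbox
    if n == 0:
        return np.empty((0, 2))
    if center is None:
        lon = rng.uniform(lon_min, lon_max, n)
        lat = rng.uniform(lat_min, lat_max, n)
        return np.column_stack([lon, lat])
    if sigma_km is None or sigma_km <= 0:
        raise ValueError("sigma_km must be positive when center is given")
    cx, cy = center
    sigma_lat = sigma_km / KM_PER_DEG_LAT
    sigma_lon = sigma_km / (KM_PER_DEG_LAT * math.cos(math.radians(cy)))
    pts = np.empty((n, 2))
    need = np.ones(n, dtype=bool)
    for _ in range(200):
        m = int(need.sum())
        if m == 0:
            break
        lon = rng.normal(cx, sigma_lon, m)
        lat = rng.normal(cy, sigma_lat, m)
        pts[need, 0] = lon
        pts[need, 1] = lat
        inside = (
            (pts[:, 0] >= lon_min)
            & (pts[:, 0] <= lon_max)
            & (pts[:, 1] >= lat_min)
            & (pts[:, 1] <= lat_max)
        )
        need = ~inside
    # pathological hotspots far outside the box: clip the stragglers
    np.clip(pts[:, 0], lon_min, lon_max, out=pts[:, 0])
    np.clip(pts[:, 1], lat_min, lat_max, out=pts[:, 1])
    return pts


def _hour_edges(start: datetime, end: datetime) -> list[tuple[datetime, datetime]]:
    edges = []
    t = start
    while t < end:
        t2 = min(t + timedelta(hours=1), end)
        edges.append((t, t2))
        t = t2
    return edges


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[list[CheckInRecord], GroundTruth]:
    """Generate one scenario: records sorted by timestamp, plus ground truth.

    Substream order: spatial, temporal, textual — three independent child
    streams of the config seed, so each stage is individually reproducible.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    child_spatial, child_temporal, child_text = ss.spawn(3)
    rng_spatial = np.random.default_rng(child_spatial)
    rng_temporal = np.random.default_rng(child_temporal)
    rng_text = np.random.default_rng(child_text)

    # --- temporal draws: per-hour Poisson counts and within-hour offsets
    hours = _hour_edges(config.start, config.end)
    times: list[datetime] = []
    flags: list[bool] = []
    for h_start, h_end in hours:
        frac = (h_end - h_start) / timedelta(hours=1)
        n_bg = rng_temporal.poisson(config.background_rate * frac)
        offs = rng_temporal.uniform(0.0, frac * 3600.0, n_bg)
        times.extend(h_start + timedelta(seconds=float(o)) for o in offs)
        flags.extend([False] * n_bg)
    if config.event_window is not None:
        ev_hours = _hour_edges(*config.event_window)
        for (h_start, h_end), mult in zip(
            ev_hours, config.event_hourly_multipliers
        ):
            n_ev = rng_temporal.poisson(config.event_rate_scale * mult)
            offs = rng_temporal.uniform(0.0, 3600.0, n_ev)
            times.extend(h_start + timedelta(seconds=float(o)) for o in offs)
            flags.extend([True] * n_ev)

    # --- spatial draws, in the same generation order
    n_bg_total = sum(1 for f in flags if not f)
    n_ev_total = len(flags) - n_bg_total
    bg_pts = sample_points(n_bg_total, config.bbox, rng_spatial)
    ev_pts = sample_points(
        n_ev_total,
        config.bbox,
        rng_spatial,
        center=config.event_center,
        sigma_km=config.event_sigma_km,
    )
    pts = np.empty((len(flags), 2))
    fl = np.asarray(flags, dtype=bool)
    pts[~fl] = bg_pts
    pts[fl] = ev_pts

    # --- sort by timestamp (stable in generation order)
    order = sorted(range(len(times)), key=lambda i: (times[i], i))
    times = [times[i] for i in order]
    fl = fl[order]
    pts = pts[order]

    # --- textual draws, in sorted record order
    vocab = config.vocab
    phi = vocab.true_phi()
    tokens_list = vocab.tokens
    crowd = vocab.crowd_topics()
    n_topics = config.n_topics
    n_rec = len(times)
    theta = np.empty((n_rec, n_topics))
    polarity = np.zeros(n_rec)
    records: list[CheckInRecord] = []
    pos_tokens, neg_tokens = vocab.positive, vocab.negative
    for i in range(n_rec):
        th = rng_text.dirichlet(np.full(n_topics, config.alpha))
        if fl[i] and crowd and config.event_topic_shift > 0:
            bump = np.zeros(n_topics)
            bump[crowd] = 1.0 / len(crowd)
            th = (1.0 - config.event_topic_shift) * th + config.event_topic_shift * bump
        theta[i] = th
        n_words = max(1, int(rng_text.poisson(config.doc_length_mean)))
        doc = generate_document(th, phi, n_words, rng_text, tokens=tokens_list)
        if config.n_sentiment_tokens > 0 and pos_tokens and neg_tokens:
            p_pos = config.background_positive_prob - (
                config.event_negative_shift if fl[i] else 0.0
            )
            p_pos = min(1.0, max(0.0, p_pos))
            is_pos = rng_text.random(config.n_sentiment_tokens) < p_pos
            for flag_pos in is_pos:
                pool = pos_tokens if flag_pos else neg_tokens
                doc.append(pool[int(rng_text.integers(len(pool)))])
            polarity[i] = (2.0 * is_pos.mean()) - 1.0
        records.append(
            CheckInRecord(
                id=f"r{i:06d}",
                timestamp=times[i],
                lon=float(pts[i, 0]),
                lat=float(pts[i, 1]),
                tokens=tuple(doc),
            )
        )
    truth = GroundTruth(
        true_phi=phi,
        theta=theta,
        event_flags=fl,
        mean_polarity=polarity,
        vocab_tokens=tokens_list,
    )
    return records, truth


def default_lexicon(vocab: VocabSpec = DEFAULT_VOCAB) -> dict[str, float]:
    """Polarity lexicon matching the vocabulary's polarity tags."""
    lex = {t: 1.0 for t in vocab.positive}
    lex.update({t: -1.0 for t in vocab.negative})
    return lex


def write_ground_truth_csv(
    records: Sequence[CheckInRecord], truth: GroundTruth, path: str | Path
) -> None:
    """Sidecar CSV: per-record event flag, true polarity, true theta."""
    n_topics = truth.theta.shape[1]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "event", "mean_polarity"]
            + [f"theta_{k}" for k in range(n_topics)]
        )
        for i, rec in enumerate(records):
            w.writerow(
                [rec.id, int(truth.event_flags[i]), repr(float(truth.mean_polarity[i]))]
                + [repr(float(v)) for v in truth.theta[i]]
            )
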