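"""Pipeline orchestration and the three-signal event detector.

The detector combines, per hourly bin:

* count anomaly — bin count / median count of all other bins >= count_ratio
  (default 2, from the observation that mass-gathering nights roughly
  double the city's check-in volume);
* Moran's I peak — the bin holds the series maximum of Moran's I and that
  maximum exceeds mean + moran_z * sd of the defined bins;
* sentiment shift — the bin's negative-sentiment proportion exceeds the
  baseline mean by at least negative_shift (default 0.10).

A bin raises an alert iff count_anomaly AND (moran_peak OR sentiment_shift).
The individual signals mirror the three analysis dimensions (aggregation
level, topics, sentiment); the combined rule is this package's
operationalization, with every threshold exposed in config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from . import sentiment as senti
from . import spatial, topics
from .records import CST, CheckInRecord, read_records_csv, write_records_csv
from .simulate import (
    ScenarioConfig,
    ScenarioError,
    default_lexicon,
    generate_scenario,
    write_ground_truth_csv,
)

log = logging.getLogger("crowdwatch")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass(frozen=True)
class DetectionThresholds:
    count_ratio: float = 2.0
    moran_z: float = 1.0
    negative_shift: float = 0.10

    def validate(self) -> None:
        if self.count_ratio < 1:
            raise ConfigError("count_ratio must be >= 1")
        if not all(
            np.isfinite([self.count_ratio, self.moran_z, self.negative_shift])
        ):
            raise ConfigError("thresholds must be finite")
        if not 0 <= self.negative_shift <= 1:
            raise ConfigError("negative_shift must be in [0, 1]")


def detect_count_anomaly(
    series: spatial.BinSeries, thresholds: DetectionThresholds
) -> np.ndarray:
    """Flag bins whose count is >= count_ratio times the median of the
    other bins (baseline excludes the bin under test; inclusive rule)."""
    if len(series) == 0:
        raise ValueError("empty count series")
    counts = series.values
    flags = np.zeros(len(counts), dtype=bool)
    idx = np.arange(len(counts))
    for k in idx:
        baseline = np.median(counts[idx != k]) if len(counts) > 1 else 0.0
        if baseline == 0:
            if counts[k] > 0:
                log.warning(
                    "count baseline is all-zero at bin %d; flagging positive bin", k
                )
                flags[k] = True
            continue
        flags[k] = counts[k] / baseline >= thresholds.count_ratio
    return flags


def detect_moran_peak(
    series: spatial.BinSeries, thresholds: DetectionThresholds
) -> np.ndarray:
    """Flag the series-maximum bin when it exceeds mean + z*sd of defined
    bins; requires sd > 0 and at least 3 defined values."""
    flags = np.zeros(len(series), dtype=bool)
    defined = series.defined()
    if defined.sum() < 3:
        warnings.warn(
            "moran series has fewer than 3 defined values; no peaks flagged",
            stacklevel=2,
        )
        return flags
    vals = series.values[defined]
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    if sd == 0:
        return flags
    k = series.argmax_defined()
    if k is not None and series.values[k] >= mean + thresholds.moran_z * sd:
        flags[k] = True
    return flags


def detect_sentiment_shift(
    series: spatial.BinSeries,
    thresholds: DetectionThresholds,
    candidate_window: Sequence[int] | np.ndarray = (),
) -> np.ndarray:
    """Flag bins whose negative proportion exceeds the baseline mean by at
    least negative_shift (inclusive). Baseline = defined bins outside the
    candidate window."""
    flags = np.zeros(len(series), dtype=bool)
    candidate = np.zeros(len(series), dtype=bool)
    candidate[np.asarray(list(candidate_window), dtype=int)] = True
    base_mask = series.defined() & ~candidate
    if not base_mask.any():
        warnings.warn("empty sentiment baseline; no shift flags", stacklevel=2)
        return flags
    baseline = float(series.values[base_mask].mean())
    defined = series.defined()
    # small slack so the inclusive rule is robust to float representation
    flags[defined] = (
        series.values[defined] - baseline >= thresholds.negative_shift - 1e-12
    )
    return flags


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs: input, geometry, models, thresholds."""

    scenario: ScenarioConfig | None = None  # simulate directive
    input_csv: str | None = None  # or load records from CSV
    buffer_center: tuple[float, float] | None = None  # default: scenario event center
    buffer_radius_km: float = 10.0
    cell_size_arcmin: float = 2.0
    contiguity: str = "queen"
    granularity: str = "hour"
    n_topics: int | None = None  # default: scenario n_topics, else 10
    lda_alpha: float | None = None
    lda_beta: float = 0.01
    lda_iterations: int = 300
    stop_tokens: tuple[str, ...] = ()
    removal_terms: tuple[str, ...] = ()
    class_map: topics.TopicClassMap | None = None
    lexicon: dict[str, float] | None = None
    sentiment_gain: float = senti.DEFAULT_GAIN
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    seed: int = 0

    def validate(self) -> None:
        if (self.scenario is None) == (self.input_csv is None):
            raise ConfigError(
                "exactly one of scenario (simulate directive) and input_csv required"
            )
        if self.contiguity not in ("queen", "rook"):
            raise ConfigError(f"unknown contiguity {self.contiguity!r}")
        if self.buffer_radius_km <= 0:
            raise ConfigError("buffer_radius_km must be positive")
        self.thresholds.validate()


def default_class_map() -> topics.TopicClassMap:
    """Class map matching the synthetic vocabulary's class tags."""
    from .simulate import DEFAULT_VOCAB

    kw = {"crowd_complaint": set(), "relief": set(), "blessing": set()}
    tag_to_class = {
        "crowd-related": "crowd_complaint",
        "relief": "relief",
        "blessing": "blessing",
    }
    for tag, toks in DEFAULT_VOCAB.topic_groups:
        if tag in tag_to_class:
            kw[tag_to_class[tag]].update(toks)
    return topics.TopicClassMap(
        keywords={c: frozenset(s) for c, s in kw.items()}, top_k=10
    )


@dataclass
class DetectionReport:
    """Per-bin statistics and flags plus run metadata."""

    bin_starts: list[datetime]
    counts: np.ndarray
    count_ratio: np.ndarray
    moran_i: np.ndarray
    negative_proportion: np.ndarray
    count_anomaly: np.ndarray
    moran_peak: np.ndarray
    sentiment_shift: np.ndarray
    alert: np.ndarray
    metadata: dict

    def alert_bins(self) -> list[datetime]:
        return [t for t, a in zip(self.bin_starts, self.alert) if a]

    def to_dict(self) -> dict:
        def clean(v: float) -> float | None:
            return None if np.isnan(v) else float(v)

        return {
            "metadata": self.metadata,
            "bins": [
                {
                    "bin_start": t.isoformat(),
                    "count": float(c),
                    "count_ratio_vs_baseline": clean(r),
                    "moran_i": clean(m),
                    "negative_proportion": clean(p),
                    "count_anomaly": bool(ca),
                    "moran_peak": bool(mp),
                    "sentiment_shift": bool(ss),
                    "alert": bool(a),
                }
                for t, c, r, m, p, ca, mp, ss, a in zip(
                    self.bin_starts,
                    self.counts,
                    self.count_ratio,
                    self.moran_i,
                    self.negative_proportion,
                    self.count_anomaly,
                    self.moran_peak,
                    self.sentiment_shift,
                    self.alert,
                )
            ],
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, datetime):
            return o.isoformat()
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(map(str, o))
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: DetectionReport
    records: list[CheckInRecord]
    buffered: list[CheckInRecord]
    count_series: spatial.BinSeries
    moran_series: spatial.BinSeries
    negative_series: spatial.BinSeries
    class_series: dict[str, spatial.BinSeries]
    topic_report: list[dict]
    corpus_report: topics.PreprocessReport
    truth: object | None = None


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full analysis: ingest -> filter -> buffer -> count/Moran
    series -> topics -> sentiment -> detection.

    ``config`` may be a :class:`PipelineConfig` or a path to a TOML file.
    When ``out_dir`` is given, every stage artifact (records, series CSVs,
    topic report, scored posts, detection report JSON) is written there.
    The run is fully deterministic given config + seed.
    """
    if isinstance(config, (str, Path)):
        config = load_pipeline_config(config)
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- ingest
    truth = None
    try:
        if config.scenario is not None:
            scenario = dataclasses.replace(config.scenario, seed=config.seed)
            records, truth = generate_scenario(scenario)
            window = (scenario.start, scenario.end)
            bbox = scenario.bbox
            center = config.buffer_center or scenario.event_center
        else:
            records = read_records_csv(config.input_csv)
            if not records:
                raise StageError("ingest", "empty-input", "no records in input CSV")
            t0 = min(r.timestamp for r in records)
            t1 = max(r.timestamp for r in records)
            window = (t0, t1 + timedelta(microseconds=1))
            bbox = (
                min(r.lon for r in records),
                min(r.lat for r in records),
                max(r.lon for r in records),
                max(r.lat for r in records),
            )
            center = config.buffer_center or (
                (bbox[0] + bbox[2]) / 2,
                (bbox[1] + bbox[3]) / 2,
            )
    except (ScenarioError, OSError) as e:
        raise StageError("ingest", "bad-input", str(e)) from e
    if out is not None:
        write_records_csv(records, out / "records.csv")
        if truth is not None:
            write_ground_truth_csv(records, truth, out / "ground_truth.csv")

    # --- buffer subset
    buffered = spatial.buffer_filter(records, center, config.buffer_radius_km)
    if not buffered:
        raise StageError("buffer", "empty-buffer", "no records inside buffer zone")

    # --- spatial series
    try:
        grid = spatial.build_grid(bbox, config.cell_size_arcmin)
        weights = (
            spatial.queen_weights(grid)
            if config.contiguity == "queen"
            else spatial.rook_weights(grid)
        )
        count_series = spatial.series_by_bin(
            buffered, config.granularity, "count", window=window
        )
        moran_series = spatial.series_by_bin(
            buffered,
            config.granularity,
            "moran",
            grid=grid,
            weights=weights,
            window=window,
        )
    except (spatial.GridError, ValueError) as e:
        raise StageError("spatial", "grid", str(e)) from e

    # --- topics
    try:
        corpus, vocab = topics.preprocess(
            buffered, config.stop_tokens, config.removal_terms
        )
        n_topics = config.n_topics or (
            config.scenario.n_topics if config.scenario is not None else 10
        )
        model = topics.fit_lda(
            corpus,
            n_topics,
            alpha=config.lda_alpha,
            beta=config.lda_beta,
            n_iterations=config.lda_iterations,
            seed=config.seed,
        )
        class_map = config.class_map or default_class_map()
        topic_classes = [
            topics.classify_topic(model, k, class_map, vocab)
            for k in range(n_topics)
        ]
        doc_labels = [
            topic_classes[topics.dominant_topic(model.theta[d])]
            for d in range(corpus.n_documents)
        ]
        cls_series = topics.class_series(
            doc_labels, corpus.timestamps, window, config.granularity
        )
        t_report = topics.topic_report(model, corpus, class_map)
    except topics.CorpusError as e:
        raise StageError("topics", "corpus", str(e)) from e

    # --- sentiment
    lexicon = config.lexicon if config.lexicon is not None else default_lexicon()
    senti.check_lexicon(lexicon)
    scores = [
        senti.score_document(r.tokens, lexicon, config.sentiment_gain)
        for r in buffered
    ]
    groups = [senti.sentiment_group(s.value) for s in scores]
    negative_series = senti.negative_proportion(
        groups, [r.timestamp for r in buffered], window, config.granularity
    )

    # --- detection
    th = config.thresholds
    count_flags = detect_count_anomaly(count_series, th)
    moran_flags = detect_moran_peak(moran_series, th)
    senti_flags = detect_sentiment_shift(
        negative_series, th, np.flatnonzero(count_flags)
    )
    alert = count_flags & (moran_flags | senti_flags)

    counts = count_series.values
    ratios = np.full(len(counts), np.nan)
    idx = np.arange(len(counts))
    for k in idx:
        base = np.median(counts[idx != k]) if len(counts) > 1 else 0.0
        if base > 0:
            ratios[k] = counts[k] / base
    report = DetectionReport(
        bin_starts=count_series.starts,
        counts=counts,
        count_ratio=ratios,
        moran_i=moran_series.values,
        negative_proportion=negative_series.values,
        count_anomaly=count_flags,
        moran_peak=moran_flags,
        sentiment_shift=senti_flags,
        alert=alert,
        metadata={
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_records": len(records),
            "n_buffered": len(buffered),
            "n_valid_documents": corpus.report.n_valid,
            "thresholds": dataclasses.asdict(th),
        },
    )

    if out is not None:
        count_series.to_csv(out / "count_series.csv")
        moran_series.to_csv(out / "moran_series.csv")
        negative_series.to_csv(out / "negative_series.csv")
        for name, s in cls_series.items():
            s.to_csv(out / f"class_series_{name}.csv")
        topics.export_topic_report(t_report, out / "topic_report.json")
        senti.export_scores_csv([r.id for r in buffered], scores, out / "scores.csv")
        report.write_json(out / "detection_report.json")

    return PipelineResult(
        report=report,
        records=records,
        buffered=buffered,
        count_series=count_series,
        moran_series=moran_series,
        negative_series=negative_series,
        class_series=cls_series,
        topic_report=t_report,
        corpus_report=corpus.report,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# TOML config loading


def _parse_dt(v) -> datetime:
    if isinstance(v, datetime):
        return v if v.tzinfo else v.replace(tzinfo=CST)
    dt = datetime.fromisoformat(v)
    return dt if dt.tzinfo else dt.replace(tzinfo=CST)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from TOML.

    Recognized tables: ``[scenario]`` (ScenarioConfig fields; presence acts
    as the simulate directive), ``[thresholds]``, and top-level keys
    ``input_csv``, ``seed``, ``buffer_radius_km``, ``cell_size_arcmin``,
    ``contiguity``, ``n_topics``, ``lda_iterations``.
    """
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as e:
        raise ConfigError(f"cannot read config {path}: {e}") from e
    kwargs: dict = {}
    if "scenario" in raw:
        sc = dict(raw["scenario"])
        for key in ("start", "end"):
            if key in sc:
                sc[key] = _parse_dt(sc[key])
        if "event_window" in sc:
            sc["event_window"] = tuple(_parse_dt(v) for v in sc["event_window"])
        if "event" in sc:  # event = false disables the hotspot
            if not sc.pop("event"):
                sc["event_window"] = None
        for key in ("bbox", "event_center", "event_hourly_multipliers"):
            if key in sc:
                sc[key] = tuple(sc[key])
        try:
            kwargs["scenario"] = ScenarioConfig(**sc)
        except TypeError as e:
            raise ConfigError(f"bad [scenario] table: {e}") from e
    if "thresholds" in raw:
        try:
            kwargs["thresholds"] = DetectionThresholds(**raw["thresholds"])
        except TypeError as e:
            raise ConfigError(f"bad [thresholds] table: {e}") from e
    for key in (
        "input_csv",
        "seed",
        "buffer_radius_km",
        "cell_size_arcmin",
        "contiguity",
        "granularity",
        "n_topics",
        "lda_iterations",
        "sentiment_gain",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "buffer_center" in raw:
        kwargs["buffer_center"] = tuple(raw["buffer_center"])
    if "lexicon_csv" in raw:
        kwargs["lexicon"] = senti.load_lexicon(raw["lexicon_csv"])
    try:
        return PipelineConfig(**kwargs)
    except TypeError as e:
        raise ConfigError(str(e)) from e
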