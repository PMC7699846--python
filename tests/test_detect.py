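"""Detection signals, the combined alert rule, pipeline orchestration,
and the CLI shell."""

from datetime import datetime, timedelta

import numpy as np
import pytest

import crowdwatch as cw
from crowdwatch.detect import ConfigError, default_class_map
from crowdwatch.records import CST
from crowdwatch.spatial import BinSeries


def series(values, label=""):
    t0 = datetime(2014, 12, 31, 0, 0, tzinfo=CST)
    width = timedelta(hours=1)
    starts = [t0 + k * width for k in range(len(values))]
    return BinSeries(starts, width, np.asarray(values, dtype=float), label)


TH = cw.DetectionThresholds()


class TestCountAnomaly:
    def test_single_spike_flagged(self):
        flags = cw.detect_count_anomaly(series([100, 100, 210, 100]), TH)
        assert list(flags) == [False, False, True, False]

    def test_constant_series_unflagged(self):
        assert not cw.detect_count_anomaly(series([50, 50, 50, 50]), TH).any()

    def test_exactly_double_is_inclusive(self):
        flags = cw.detect_count_anomaly(series([100, 100, 200, 100]), TH)
        assert flags[2]

    def test_all_zero_baseline_flags_positive_bin(self):
        flags = cw.detect_count_anomaly(series([0, 0, 5, 0]), TH)
        assert list(flags) == [False, False, True, False]


class TestMoranPeak:
    def test_peak_above_one_sd_flagged(self):
        # mean 0.3, sd ~0.346: 0.9 >= 0.646
        flags = cw.detect_moran_peak(series([0.1, 0.1, 0.9, 0.1]), TH)
        assert list(flags) == [False, False, True, False]

    def test_constant_series_unflagged(self):
        assert not cw.detect_moran_peak(series([0.2, 0.2, 0.2, 0.2]), TH).any()

    def test_all_undefined_warns_and_unflagged(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            flags = cw.detect_moran_peak(series([np.nan] * 4), TH)
        assert not flags.any()

    def test_undefined_bins_excluded_from_baseline(self):
        flags = cw.detect_moran_peak(
            series([0.1, np.nan, 0.1, 0.9, 0.1]), TH
        )
        assert list(flags) == [False, False, False, True, False]


class TestSentimentShift:
    def test_shift_above_baseline_flagged(self):
        # baseline mean 0.28 on non-candidate bins; 0.41 - 0.28 >= 0.10
        s = series([0.28, 0.28, 0.41, 0.28])
        flags = cw.detect_sentiment_shift(s, TH, candidate_window=[2])
        assert list(flags) == [False, False, True, False]

    def test_exact_threshold_inclusive(self):
        s = series([0.20, 0.20, 0.30, 0.20])
        flags = cw.detect_sentiment_shift(s, TH, candidate_window=[2])
        assert flags[2]

    def test_undefined_bin_not_flagged(self):
        s = series([0.2, np.nan, 0.5, 0.2])
        flags = cw.detect_sentiment_shift(s, TH, candidate_window=[2])
        assert not flags[1] and flags[2]

    def test_empty_baseline_warns(self):
        s = series([0.5, 0.5])
        with pytest.warns(UserWarning, match="baseline"):
            flags = cw.detect_sentiment_shift(s, TH, candidate_window=[0, 1])
        assert not flags.any()


class TestThresholds:
    def test_count_ratio_below_one_rejected(self):
        with pytest.raises(ConfigError):
            cw.DetectionThresholds(count_ratio=0.5).validate()

    def test_defaults_valid(self):
        TH.validate()


@pytest.fixture(scope="module")
def small_scenario_cls():
    return cw.ScenarioConfig(
        start=datetime(2014, 12, 31, 12, 0, tzinfo=CST),
        end=datetime(2015, 1, 1, 0, 0, tzinfo=CST),
        background_rate=60.0,
        event_window=(
            datetime(2014, 12, 31, 20, 0, tzinfo=CST),
            datetime(2014, 12, 31, 22, 0, tzinfo=CST),
        ),
        event_hourly_multipliers=(1.0, 2.0),
        event_rate_scale=60.0,
    )


@pytest.fixture(scope="module")
def event_result(small_scenario_cls):
    cfg = cw.PipelineConfig(
        scenario=small_scenario_cls, seed=7, lda_iterations=100
    )
    return cw.run_pipeline(cfg)


class TestPipeline:
    def test_event_alerts_inside_event_window(self, event_result, small_scenario_cls):
        alerts = event_result.report.alert_bins()
        assert alerts, "event scenario should raise an alert"
        ev0, ev1 = small_scenario_cls.event_window
        assert all(ev0 <= t < ev1 for t in alerts)

    def test_null_scenario_raises_no_alert(self, small_scenario_cls):
        cfg = cw.PipelineConfig(
            scenario=small_scenario_cls.without_event(),
            seed=7,
            lda_iterations=100,
        )
        res = cw.run_pipeline(cfg)
        assert res.report.alert_bins() == []

    def test_determinism(self, small_scenario_cls, event_result):
        cfg = cw.PipelineConfig(
            scenario=small_scenario_cls, seed=7, lda_iterations=100
        )
        again = cw.run_pipeline(cfg)
        assert again.report.to_dict() == event_result.report.to_dict()

    def test_flags_recomputable_from_report_series(self, event_result):
        """Internal consistency: the report's flags follow from its own
        series columns under the documented rules."""
        rep = event_result.report
        th = cw.DetectionThresholds(**rep.metadata["thresholds"])
        counts = series(rep.counts)
        assert list(cw.detect_count_anomaly(counts, th)) == list(rep.count_anomaly)
        moran = series(rep.moran_i)
        assert list(cw.detect_moran_peak(moran, th)) == list(rep.moran_peak)
        neg = series(rep.negative_proportion)
        senti = cw.detect_sentiment_shift(
            neg, th, np.flatnonzero(rep.count_anomaly)
        )
        assert list(senti) == list(rep.sentiment_shift)
        assert list(rep.alert) == list(
            rep.count_anomaly & (rep.moran_peak | rep.sentiment_shift)
        )

    def test_stage_artifacts_written(self, small_scenario_cls, tmp_path):
        cfg = cw.PipelineConfig(
            scenario=small_scenario_cls, seed=7, lda_iterations=50
        )
        cw.run_pipeline(cfg, out_dir=tmp_path)
        for name in (
            "records.csv",
            "ground_truth.csv",
            "count_series.csv",
            "moran_series.csv",
            "negative_series.csv",
            "topic_report.json",
            "scores.csv",
            "detection_report.json",
        ):
            assert (tmp_path / name).exists(), name

    def test_config_requires_exactly_one_input(self):
        with pytest.raises(ConfigError):
            cw.PipelineConfig().validate()
        with pytest.raises(ConfigError):
            cw.PipelineConfig(
                scenario=cw.ScenarioConfig(), input_csv="x.csv"
            ).validate()

    def test_default_class_map_matches_vocabulary_tags(self):
        cm = default_class_map()
        assert "crowd" in cm.keywords["crowd_complaint"]
        assert "pray" in cm.keywords["blessing"]
        assert "gloat" in cm.keywords["relief"]


CONFIG_TOML = """
seed = 5
lda_iterations = 50

[scenario]
start = 2014-12-31T12:00:00+08:00
end = 2015-01-01T00:00:00+08:00
background_rate = 60.0
event_window = [2014-12-31T20:00:00+08:00, 2014-12-31T22:00:00+08:00]
event_hourly_multipliers = [1.0, 2.0]
event_rate_scale = 60.0

[thresholds]
count_ratio = 2.0
moran_z = 1.0
negative_shift = 0.10
"""


class TestCLI:
    def test_run_all_exit_zero(self, tmp_path):
        from click.testing import CliRunner
        from crowdwatch.cli import main

        cfg = tmp_path / "config.toml"
        cfg.write_text(CONFIG_TOML)
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["run-all", "--config", str(cfg), "--out-dir", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "detection_report.json").exists()

    def test_bad_config_exit_two(self, tmp_path):
        from click.testing import CliRunner
        from crowdwatch.cli import main

        cfg = tmp_path / "bad.toml"
        cfg.write_text("this is not { toml\n")
        runner = CliRunner()
        result = runner.invoke(main, ["detect", "--config", str(cfg)])
        assert result.exit_code == 2

    def test_simulate_writes_records(self, tmp_path):
        from click.testing import CliRunner
        from crowdwatch.cli import main

        cfg = tmp_path / "config.toml"
        cfg.write_text(CONFIG_TOML)
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "simulate",
                "--config", str(cfg),
                "--seed", "3",
                "--out-dir", str(tmp_path / "sim"),
            ],
        )
        assert result.exit_code == 0, result.output
        recs = cw.read_records_csv(tmp_path / "sim" / "records.csv")
        assert len(recs) > 0
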