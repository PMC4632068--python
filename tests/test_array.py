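"""IP/total array enrichment calling pipeline."""

import numpy as np
import pandas as pd
import pytest

from pbodykit import array
from pbodykit.simulate import SimulationConfig, simulate_array


def _probes(raw_total, raw_ip, n_neg=40, neg_level=40.0):
    n = len(raw_total)
    main = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "transcript_id": [f"t{i}" for i in range(n)],
            "is_negative_control": False,
            "raw_total": raw_total,
            "raw_ip": raw_ip,
        }
    )
    neg = pd.DataFrame(
        {
            "probe_id": [f"neg{i}" for i in range(n_neg)],
            "transcript_id": pd.Series([pd.NA] * n_neg, dtype="object"),
            "is_negative_control": True,
            "raw_total": neg_level,
            "raw_ip": neg_level,
        }
    )
    return pd.concat([main, neg], ignore_index=True)


class TestBackgroundSubtraction:
    def test_median_subtraction_arithmetic(self):
        probes = _probes([100.0], [100.0], neg_level=40.0)
        out = array.subtract_background(probes)
        assert out["bg_sub_total"].iloc[0] == pytest.approx(60.0)

    def test_values_below_background_floored(self):
        probes = _probes([30.0], [30.0], neg_level=40.0)
        out = array.subtract_background(probes, floor=1.0)
        assert out["bg_sub_total"].iloc[0] == 1.0
        assert out["log_total"].iloc[0] == 0.0

    def test_no_negative_controls_is_error(self):
        probes = _probes([100.0], [100.0]).query("~is_negative_control")
        with pytest.raises(ValueError):
            array.subtract_background(probes)


class TestLoessNormalization:
    def test_identical_arrays_are_fixed_point(self):
        rng = np.random.default_rng(1)
        x = rng.normal(8, 1, 200)
        lt, li = array.loess_normalize_pair(x, x)
        assert np.allclose(lt, x) and np.allclose(li, x)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(8, 1, 200)
        lt, li = array.loess_normalize_pair(x, x + 1.5)
        m = li - lt
        assert np.allclose(m, 0.0, atol=1e-6)
        # A values untouched
        assert np.allclose((li + lt) / 2, x + 0.75, atol=1e-6)

    def test_curved_trend_flattened(self):
        rng = np.random.default_rng(3)
        x = rng.normal(8, 1, 500)
        trend = 0.5 * (x - 8) ** 2 / 2
        li = x + trend + rng.normal(0, 0.02, 500)
        lt, li2 = array.loess_normalize_pair(x, li)
        from statsmodels.nonparametric.smoothers_lowess import lowess

        def fitted_trend(a, b):
            return lowess(b - a, (a + b) / 2, frac=0.4, it=2, return_sorted=False)

        m_before = np.abs(fitted_trend(x, li)).mean()
        m_after = np.abs(fitted_trend(lt, li2)).mean()
        assert m_after < 0.1 * m_before

    def test_too_few_points_pass_through(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning):
            lt, li = array.loess_normalize_pair(x, x + 2.0)
        assert np.allclose(li - lt, 2.0)


class TestProbeAveraging:
    def test_mean_of_probe_logs(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c", "n1"],
                "transcript_id": ["t1", "t1", "t1", pd.NA],
                "is_negative_control": [False, False, False, True],
                "raw_total": [1.0] * 4,
                "raw_ip": [1.0] * 4,
                "bg_sub_total": [4.0, 8.0, 16.0, 1.0],
                "bg_sub_ip": [4.0, 8.0, 16.0, 1.0],
                "log_total": [2.0, 3.0, 4.0, 0.0],
                "log_ip": [2.0, 3.0, 4.0, 0.0],
            }
        )
        out = array.average_probes(probes).set_index("transcript_id")
        assert out.loc["t1", "mean_log_total"] == pytest.approx(3.0)
        assert out.loc["t1", "n_probes_used"] == 3

    def test_flooring_one_probe_shifts_mean_exactly(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c"],
                "transcript_id": ["t1"] * 3,
                "is_negative_control": [False] * 3,
                "raw_total": [1.0] * 3,
                "raw_ip": [1.0] * 3,
                "bg_sub_total": [4.0, 8.0, 1.0],
                "bg_sub_ip": [4.0, 8.0, 16.0],
                "log_total": [2.0, 3.0, 0.0],  # third probe floored to log 0
                "log_ip": [2.0, 3.0, 4.0],
            }
        )
        out = array.average_probes(probes)
        assert out["mean_log_total"].iloc[0] == pytest.approx(5.0 / 3.0)


class TestTranscriptFilter:
    def _signals(self):
        return pd.DataFrame(
            {
                "transcript_id": ["good", "dim", "noisy", "hot"],
                "mean_log_total": [8.0, 0.5, 8.0, 8.0],
                "mean_log_ip": [8.0, 0.5, 8.0, 8.0],
                "n_probes_used": [3] * 4,
                "probe_cv_total": [0.1, 0.1, 0.9, 0.1],
                "probe_cv_ip": [0.1, 0.1, 0.1, 0.1],
                "max_raw_total": [500.0, 500.0, 500.0, 65535.0],
            }
        )

    def test_each_drop_reason(self):
        neg_log = np.full(100, 1.0)
        kept, report = array.filter_transcripts(self._signals(), neg_log)
        assert list(kept["transcript_id"]) == ["good"]
        assert report["n_low_abundance"] == 1
        assert report["n_high_cv"] == 1
        assert report["n_saturated"] == 1

    def test_designed_saturated_transcripts_dropped(self):
        reps, mock, truth = simulate_array(
            SimulationConfig(seed=9, n_transcripts=200, n_spiked=0, n_saturated=10,
                             n_neg_probes=200)
        )
        probes = array.subtract_background(reps["rep1"])
        signals = array.average_probes(probes)
        neg_log = probes.loc[probes["is_negative_control"], "log_total"].to_numpy()
        kept, report = array.filter_transcripts(signals, neg_log)
        assert report["n_saturated"] == 10
        assert set(truth.saturated_transcript_ids).isdisjoint(kept["transcript_id"])


class TestRegressionBand:
    def test_perfect_line_recovered(self):
        x = np.linspace(2, 12, 50)
        signals = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(50)],
             "mean_log_total": x, "mean_log_ip": 2 * x + 1}
        )
        fit = array.fit_regression_band(signals)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)
        calls = array.call_enrichment(fit, signals)
        assert not calls["enriched"].any()

    def test_null_calibration_near_nominal(self):
        rng = np.random.default_rng(11)
        x = rng.normal(8, 1.5, 1000)
        y = x + rng.normal(0, 0.2, 1000)
        signals = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(1000)],
             "mean_log_total": x, "mean_log_ip": y}
        )
        fit = array.fit_regression_band(signals, level=0.95, band_kind="prediction")
        frac = array.call_enrichment(fit, signals)["enriched"].mean()
        assert 0.01 <= frac <= 0.05  # nominal upper-tail rate 0.025

    def test_mean_ci_band_is_narrower(self):
        rng = np.random.default_rng(11)
        x = rng.normal(8, 1.5, 1000)
        y = x + rng.normal(0, 0.2, 1000)
        signals = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(1000)],
             "mean_log_total": x, "mean_log_ip": y}
        )
        pred = array.fit_regression_band(signals, band_kind="prediction")
        mean_ci = array.fit_regression_band(signals, band_kind="mean_ci")
        n_pred = array.call_enrichment(pred, signals)["enriched"].sum()
        n_mean = array.call_enrichment(mean_ci, signals)["enriched"].sum()
        assert n_mean > n_pred

    def test_boundary_point_not_enriched(self):
        x = np.linspace(2, 12, 50)
        signals = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(50)],
             "mean_log_total": x, "mean_log_ip": x + 0.0}
        )
        rng = np.random.default_rng(0)
        signals["mean_log_ip"] += rng.normal(0, 0.1, 50)
        fit = array.fit_regression_band(signals)
        probe = pd.DataFrame(
            {"transcript_id": ["edge"], "mean_log_total": [8.0],
             "mean_log_ip": fit.upper([8.0])}
        )
        assert not array.call_enrichment(fit, probe)["enriched"].iloc[0]

    def test_degenerate_regressor_rejected(self):
        signals = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(20)],
             "mean_log_total": 5.0, "mean_log_ip": np.arange(20.0)}
        )
        with pytest.raises(ValueError):
            array.fit_regression_band(signals)


class TestConsensus:
    def _calls(self, mapping):
        return pd.DataFrame(
            {"transcript_id": list(mapping), "enriched": list(mapping.values())}
        )

    def test_two_replicates_not_mock_reaches_consensus(self):
        reps = {
            "r1": self._calls({"a": True, "b": True}),
            "r2": self._calls({"a": True, "b": False}),
            "r3": self._calls({"a": False, "b": False}),
        }
        mock = self._calls({"a": False, "b": False})
        out = array.consensus_calls(reps, mock).set_index("transcript_id")
        assert bool(out.loc["a", "consensus"])
        assert not bool(out.loc["b", "consensus"])

    def test_mock_enrichment_vetoes_consensus(self):
        reps = {"r1": self._calls({"a": True}), "r2": self._calls({"a": True})}
        mock = self._calls({"a": True})
        out = array.consensus_calls(reps, mock).set_index("transcript_id")
        assert not bool(out.loc["a", "consensus"])

    def test_missing_mock_warns_and_is_vacuous(self):
        reps = {"r1": self._calls({"a": True}), "r2": self._calls({"a": True})}
        with pytest.warns(UserWarning):
            out = array.consensus_calls(reps, None).set_index("transcript_id")
        assert bool(out.loc["a", "consensus"])

    def test_spike_in_recovery_end_to_end(self):
        reps, mock, truth = simulate_array(SimulationConfig(seed=3))
        consensus, per_calls, qc = array.run_array_pipeline(reps, mock)
        spiked = set(truth.spiked_transcript_ids)
        called = set(consensus.loc[consensus["consensus"], "transcript_id"])
        assert len(called & spiked) / len(spiked) >= 0.9
        assert len(called - spiked) <= 5
        assert not (
            consensus["consensus"] & consensus["enriched_in_mock"]
        ).any()

    def test_flat_degenerate_input_gives_no_enrichments(self):
        # all probes equal to the control median -> everything floored
        probes = _probes([40.0] * 50, [40.0] * 50, neg_level=40.0)
        bg = array.subtract_background(probes)
        assert (bg["log_total"] == 0.0).all()
        signals = array.average_probes(bg)
        with pytest.raises(ValueError):
            array.fit_regression_band(signals)  # degenerate by design
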