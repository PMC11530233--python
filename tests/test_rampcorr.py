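import numpy as np
import pandas as pd
import pytest

from optocorr import pipelines as pl
from optocorr import rampcorr as rc
from optocorr.traces import CurrentTrace


def _sine(freq_hz, duration_ms=4000.0, dt_ms=0.05, amp=1.0, phase=0.0):
    t = np.arange(0.0, duration_ms, dt_ms)
    return CurrentTrace(amp * np.sin(2 * np.pi * freq_hz * t / 1000.0 + phase),
                        dt_ms)


class TestBandpassFilter:
    def test_passband_tone_preserved(self):
        """A 50 Hz tone inside the 10-120 Hz band keeps its amplitude
        within 5% and its phase within one sample."""
        raw = _sine(50.0)
        filt = rc.bandpass_filter(raw)
        mid = slice(20000, 60000)  # avoid edge transients
        assert abs(filt.samples[mid].std() / raw.samples[mid].std() - 1) < 0.05
        xc = np.correlate(filt.samples[mid], raw.samples[mid], mode="same")
        lag = int(np.argmax(xc)) - len(xc) // 2
        assert abs(lag) <= 1

    def test_dc_removed(self):
        raw = CurrentTrace(np.full(80000, 3.7), 0.05)
        filt = rc.bandpass_filter(raw)
        assert np.abs(filt.samples[20000:60000]).mean() < 1e-6 * 3.7

    def test_stopband_tone_attenuated(self):
        raw = _sine(500.0)
        filt = rc.bandpass_filter(raw)
        mid = slice(20000, 60000)
        assert filt.samples[mid].std() < 0.1 * raw.samples[mid].std()

    def test_trace_shorter_than_warmup_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            rc.bandpass_filter(CurrentTrace(np.zeros(10), 0.05))

    def test_invalid_band_rejected(self):
        tr = _sine(50.0, duration_ms=100.0)
        with pytest.raises(ValueError, match="band"):
            rc.bandpass_filter(tr, low_hz=120.0, high_hz=10.0)


class TestWindowedCrosscorr:
    def test_autocorrelation_identity(self):
        rng = np.random.default_rng(0)
        tr = CurrentTrace(rng.normal(size=2000), 1.0)
        wcc = rc.windowed_crosscorr(tr, tr)
        assert np.allclose(wcc.table["peak_coeff"], 1.0, atol=1e-6)
        assert np.allclose(wcc.table["peak_lag_ms"], 0.0, atol=1e-6)

    def test_pure_delay_recovered_in_every_window(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2100)
        a = CurrentTrace(x[:2000], 1.0)
        b = CurrentTrace(np.r_[np.zeros(5), x[:1995]], 1.0)  # b lags a by 5 ms
        wcc = rc.windowed_crosscorr(a, b)
        assert np.allclose(wcc.table["peak_lag_ms"], 5.0, atol=0.5)
        assert (wcc.table["peak_coeff"] > 0.9).all()

    def test_independent_noise_stays_below_reported_threshold(self):
        """Mean window peak for independent white-noise traces falls below
        0.27 in at least 95% of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = CurrentTrace(rng.normal(size=2000), 1.0)
            b = CurrentTrace(rng.normal(size=2000), 1.0)
            wcc = rc.windowed_crosscorr(a, b)
            if wcc.table["peak_coeff"].mean() < 0.27:
                hits += 1
        assert hits >= 95

    def test_zero_variance_window_flagged_as_zero(self):
        a = CurrentTrace(np.zeros(600), 1.0)
        rng = np.random.default_rng(2)
        b = CurrentTrace(rng.normal(size=600), 1.0)
        wcc = rc.windowed_crosscorr(a, b)
        assert wcc.table["zero_variance"].all()
        assert (wcc.table["peak_coeff"] == 0.0).all()

    def test_mismatched_traces_rejected(self):
        a = CurrentTrace(np.zeros(600), 1.0)
        with pytest.raises(ValueError, match="length"):
            rc.windowed_crosscorr(a, CurrentTrace(np.zeros(500), 1.0))
        with pytest.raises(ValueError, match="sampling"):
            rc.windowed_crosscorr(a, CurrentTrace(np.zeros(600), 0.5))

    def test_symmetry_up_to_lag_sign(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        a = CurrentTrace(x, 1.0)
        b = CurrentTrace(np.roll(x, 7) + 0.5 * rng.normal(size=2000), 1.0)
        ab = rc.windowed_crosscorr(a, b)
        ba = rc.windowed_crosscorr(b, a)
        assert np.allclose(ab.table["peak_coeff"], ba.table["peak_coeff"],
                           atol=1e-3)
        assert np.allclose(ab.table["peak_lag_ms"],
                           -ba.table["peak_lag_ms"], atol=0.5)


def _constant_wcc(peak, lags, n_windows=40):
    table = pd.DataFrame({
        "window_start_ms": np.arange(n_windows) * 10.0,
        "peak_coeff": np.full(n_windows, peak),
        "peak_lag_ms": np.full(n_windows, float(lags)),
        "zero_variance": False,
    })
    return rc.WindowedCC(table, 250.0, 10.0, 25.0)


class TestSummarizePair:
    def test_constant_trials(self):
        wccs = [_constant_wcc(0.6, 2.0) for _ in range(5)]
        m = rc.summarize_pair(wccs)
        assert np.isclose(m.cc_peak_mean, 0.6)
        assert np.isclose(m.cc_lag_var, 0.0)

    def test_alternating_lags_give_unit_variance(self):
        """Lags of +1/-1 ms across trials have population SD 1 ms in every
        window, hence a lag variance of exactly 1 ms^2."""
        wccs = [_constant_wcc(0.5, 1.0 if k % 2 == 0 else -1.0)
                for k in range(4)]
        m = rc.summarize_pair(wccs)
        assert np.isclose(m.cc_lag_var, 1.0)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError, match="two trials"):
            rc.summarize_pair([_constant_wcc(0.5, 0.0)])

    def test_unequal_window_counts_rejected(self):
        with pytest.raises(ValueError, match="window count"):
            rc.summarize_pair([_constant_wcc(0.5, 0.0, 40),
                               _constant_wcc(0.5, 0.0, 41)])

    def test_photo_window_restricts_extrema(self):
        peaks = np.zeros(40)
        peaks[35] = 0.9  # excitation after the photo-stimulation window
        table = pd.DataFrame({
            "window_start_ms": np.arange(40) * 10.0,
            "peak_coeff": peaks, "peak_lag_ms": 0.0, "zero_variance": False})
        wcc = rc.WindowedCC(table, 250.0, 10.0, 25.0)
        m_all = rc.summarize_pair([wcc, wcc], smooth_windows=1)
        m_cut = rc.summarize_pair([wcc, wcc], smooth_windows=1,
                                  photo_window_ms=(0.0, 300.0))
        assert np.isclose(m_all.cc_peak_mean, 0.9)
        assert m_cut.cc_peak_mean < 0.9


class TestPipelineDelayPreservation:
    def test_filter_window_chain_preserves_pure_delay(self):
        """Filtering, decimation and windowed correlation report a pure
        5 ms delay between simulated traces to within one sample (1 ms)."""
        traces, _ = pl.simulate_ramp_pair(8, seed=3)
        tr = traces[("post00", 0)]
        shift = int(round(5.0 / tr.dt_ms))
        delayed = tr.copy_with(np.r_[np.zeros(shift), tr.samples[:-shift]])
        cfg = rc.RampAnalysisConfig()
        a = rc.preprocess_trace(tr, cfg)
        b = rc.preprocess_trace(delayed, cfg)
        wcc = rc.windowed_crosscorr(a, b, max_lag_ms=25.0)
        good = wcc.table[~wcc.table["zero_variance"]]
        median_lag = good["peak_lag_ms"].median()
        assert abs(median_lag - 5.0) <= 1.0


class TestShuffleNull:
    def test_percentile_of_uniform_metrics(self):
        """95th percentile of 1000 uniform(0, 0.2) draws lies in the
        order-statistic band [0.185, 0.195]."""
        rng = np.random.default_rng(0)
        peaks = rng.uniform(0.0, 0.2, 1000)
        lvars = rng.uniform(0.0, 30.0, 1000)
        thr = rc.thresholds_from_metrics(peaks, lvars)
        assert 0.185 <= thr.peak_threshold <= 0.195
        assert 0.5 <= thr.lag_var_threshold <= 2.5

    def test_identical_metrics_give_that_value(self):
        thr = rc.thresholds_from_metrics(np.full(100, 0.4), np.full(100, 2.0))
        assert thr.peak_threshold == 0.4
        assert thr.lag_var_threshold == 2.0

    def test_requires_two_recordings(self):
        with pytest.raises(ValueError, match="two recordings"):
            rc.shuffle_null([rc.RecordingSession("only", {})], n_pairs=10)

    def test_pairs_cross_recordings_only(self, null_sessions):
        _, metrics = rc.shuffle_null(null_sessions[:4], n_pairs=20, seed=3,
                                     stim_duration_ms=8000.0,
                                     return_metrics=True)
        for cond in metrics["condition"]:
            a, b = cond.split("|")
            assert a != b

    def test_seed_determinism(self, null_sessions):
        t1 = rc.shuffle_null(null_sessions[:4], n_pairs=15, seed=9,
                             stim_duration_ms=8000.0)
        t2 = rc.shuffle_null(null_sessions[:4], n_pairs=15, seed=9,
                             stim_duration_ms=8000.0)
        assert t1 == t2


class TestClassification:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["cc_peak_mean", "cc_lag_var"])

    def test_threshold_rule(self):
        thr = rc.PV_INPUT_PRESET  # peak > 0.27 and lag var < 0.22
        m = self._frame([(0.50, 0.05), (0.26, 0.05), (0.50, 0.30)])
        labels = rc.classify_pairs(m, thr)
        assert labels.tolist() == ["coordinated", "uncoordinated",
                                   "uncoordinated"]

    def test_boundary_is_strict(self):
        thr = rc.NullThresholds(0.27, 0.22)
        m = self._frame([(0.27, 0.05), (0.50, 0.22)])
        assert (rc.classify_pairs(m, thr) == "uncoordinated").all()

    def test_kmeans_separable_blobs(self):
        rng = np.random.default_rng(0)
        coord = np.column_stack([rng.normal(0.8, 0.02, 30),
                                 rng.normal(0.1, 0.02, 30)])
        uncoord = np.column_stack([rng.normal(0.2, 0.02, 30),
                                   rng.normal(15.0, 1.0, 30)])
        m = self._frame(np.vstack([coord, uncoord]))
        labels, degenerate = rc.classify_pairs_kmeans(m, seed=1)
        assert not degenerate
        assert (labels[:30] == "coordinated").all()
        assert (labels[30:] == "uncoordinated").all()

    def test_kmeans_degenerate_input(self):
        m = self._frame([(0.5, 1.0)] * 10)
        labels, degenerate = rc.classify_pairs_kmeans(m, seed=0)
        assert degenerate
        assert len(labels) == 10

    def test_kmeans_requires_k_points(self):
        with pytest.raises(ValueError):
            rc.classify_pairs_kmeans(self._frame([(0.5, 1.0)]), k=2)


class TestConditionDelta:
    def _metrics(self, pair_ids, peaks):
        return pd.DataFrame({
            "pair_id": pair_ids, "cc_peak_mean": peaks,
            "cc_lag_var": [0.1] * len(pair_ids),
            "distance_um": [100.0] * len(pair_ids),
            "classification": ["coordinated"] * len(pair_ids)})

    def test_identical_conditions_zero_delta(self):
        m = self._metrics(["p0", "p1"], [0.5, 0.7])
        out = rc.condition_delta(m, m.copy())
        assert np.allclose(out["delta_cc_peak_mean"], 0.0)
        assert (out["status"] == "paired").all()

    def test_missing_pair_reported_absent(self):
        c = self._metrics(["p0", "p1"], [0.5, 0.7])
        t = self._metrics(["p0"], [0.4])
        out = rc.condition_delta(c, t).set_index("pair_id")
        assert out.loc["p1", "status"] == "missing_in_treatment"
        assert np.isnan(out.loc["p1", "delta_cc_peak_mean"])
        assert np.isclose(out.loc["p0", "delta_cc_peak_mean"], -0.1)

    def test_weakened_shared_input_reduces_peak(self):
        """Halving the shared-connection weights lowers the peak
        correlation in most simulated pairs (10 seeds)."""
        deltas = []
        for seed in range(10):
            ctrl, treat = pl.ramp_condition_pair(seed, n_shared=4)
            deltas.append(treat.cc_peak_mean - ctrl.cc_peak_mean)
        assert np.median(deltas) < 0


class TestDistanceDependence:
    def test_exact_line_recovered(self):
        x = np.linspace(0.0, 600.0, 20)
        m = pd.DataFrame({"distance_um": x, "cc_peak_mean": 0.5 - 0.001 * x})
        fit = rc.fit_distance_dependence(m)
        assert np.isclose(fit.slope, -0.001)
        assert np.isclose(fit.r2_adj, 1.0)

    def test_constant_metric_gives_flat_fit(self):
        m = pd.DataFrame({"distance_um": [0.0, 100.0, 200.0],
                          "cc_peak_mean": [0.4, 0.4, 0.4]})
        fit = rc.fit_distance_dependence(m)
        assert fit.slope == 0.0
        assert fit.r2_adj <= 0.0

    def test_requires_three_pairs(self):
        m = pd.DataFrame({"distance_um": [0.0, 1.0], "cc_peak_mean": [0, 1]})
        with pytest.raises(ValueError, match="three pairs"):
            rc.fit_distance_dependence(m)

    def test_noisy_slope_recovery(self):
        """With slope -5e-4/µm and realistic scatter (n=40), the mean
        recovered slope over 20 seeds is within 20% of truth."""
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.0, 800.0, 40)
            y = 0.6 - 5e-4 * x + rng.normal(0.0, 0.05, 40)
            m = pd.DataFrame({"distance_um": x, "cc_peak_mean": y})
            slopes.append(rc.fit_distance_dependence(m).slope)
        assert abs(np.mean(slopes) - (-5e-4)) < 0.2 * 5e-4
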