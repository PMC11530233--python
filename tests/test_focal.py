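import numpy as np
import pandas as pd
import pytest
from scipy import stats

from optocorr import focal as fc
from optocorr import pipelines as pl
from optocorr.kernels import SynapticKernelParams, sampled_kernel
from optocorr.protocols import FocalGridProtocol
from optocorr.traces import CurrentTrace


def _event_table(rows, grid):
    df = pd.DataFrame(rows, columns=fc.EVENT_COLUMNS)
    return fc.EventTable(df, (grid.rows, grid.cols))


class TestEventTemplate:
    def test_waveform_normalized(self):
        w = fc.EventTemplate().waveform(0.05)
        assert np.isclose(w.max(), 1.0)
        assert w[0] == 0.0

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            fc.EventTemplate(rise_ms=2.0, decay_ms=1.0).waveform(0.05)


class TestDetectEvents:
    def _trace_with_templates(self, times_ms, amps, noise_sd=0.0, seed=0,
                              duration_ms=1000.0, dt=0.05):
        w = fc.EventTemplate().waveform(dt)
        n = int(duration_ms / dt)
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        for t, a in zip(times_ms, amps):
            i = int(round(t / dt))
            x[i:i + len(w)] -= a * w  # inward events
        return CurrentTrace(x, dt)

    def test_noiseless_self_detection(self):
        """A single inserted template is recovered at its onset within
        0.5 ms and within 1% of the inserted amplitude."""
        tr = self._trace_with_templates([200.0], [80.0])
        det = fc.detect_events(tr)
        assert len(det) == 1
        assert abs(det.loc[0, "time_ms"] - 200.0) <= 0.5
        assert abs(det.loc[0, "amplitude"] - 80.0) <= 0.8

    def test_flat_trace_yields_no_events(self):
        det = fc.detect_events(CurrentTrace(np.zeros(20000), 0.05))
        assert len(det) == 0
        det = fc.detect_events(CurrentTrace(np.full(20000, 5.0), 0.05))
        assert len(det) == 0

    def test_overlapping_events_resolved(self):
        """Two templates 3 ms apart (100 and 60 pA) with 5 pA noise are
        both recovered in at least 90% of 20 seeded runs."""
        hits = 0
        for seed in range(20):
            tr = self._trace_with_templates([300.0, 303.0], [100.0, 60.0],
                                            noise_sd=5.0, seed=seed)
            det = fc.detect_events(tr, min_amplitude=15.0)
            near = det[(det.time_ms > 295) & (det.time_ms < 310)]
            if len(near) == 2:
                hits += 1
        assert hits >= 18

    def test_amplitude_floor_suppresses_noise_detections(self):
        rng = np.random.default_rng(3)
        tr = CurrentTrace(rng.normal(0.0, 5.0, 200000), 0.05)
        raw = fc.detect_events(tr)
        floored = fc.detect_events(tr, min_amplitude=15.0)
        assert len(floored) < max(len(raw), 1) * 0.2

    def test_template_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            fc.detect_events(CurrentTrace(np.zeros(10), 0.05))

    def test_array_template_accepted(self):
        k = np.abs(sampled_kernel(SynapticKernelParams(), 0.05))
        tr = self._trace_with_templates([100.0], [50.0])
        det = fc.detect_events(tr, template=k)
        assert len(det) >= 1


class TestAssignEventsToSites:
    def test_evoked_window_and_site_mapping(self):
        grid = FocalGridProtocol(repeats=2)
        order = grid.site_order(0, seed=5)
        events = pd.DataFrame({
            "time_ms": [0.0 * 200 + 10.0, 3 * 200 + 5.0, 7 * 200 + 150.0],
            "amplitude": [0.05, 0.08, 0.02]})
        out = fc.assign_events_to_sites(events, grid, repeat=0,
                                        protocol_seed=5, cell_id="c",
                                        amplitude_scale=1000.0)
        assert len(out) == 2  # the 150 ms latency event is spontaneous
        assert out.loc[0, "site_row"] == order[0] // grid.cols
        assert out.loc[1, "site_col"] == order[3] % grid.cols
        assert np.isclose(out.loc[0, "amplitude_pa"], 50.0)
        assert np.isclose(out.loc[1, "time_ms"], 5.0)


class TestEventTable:
    def test_rejects_nonpositive_amplitudes(self):
        grid = FocalGridProtocol()
        with pytest.raises(ValueError, match="positive"):
            _event_table([("c", 0, 1, 1, 5.0, 0.0)], grid)

    def test_rejects_site_outside_grid(self):
        grid = FocalGridProtocol()
        with pytest.raises(ValueError, match="outside"):
            _event_table([("c", 0, 10, 1, 5.0, 10.0)], grid)

    def test_csv_round_trip(self, tmp_path):
        grid = FocalGridProtocol()
        t = _event_table([("c", 0, 1, 1, 5.0, 10.0)], grid)
        t.to_csv(tmp_path / "ev.csv")
        back = fc.EventTable.from_csv(tmp_path / "ev.csv",
                                      (grid.rows, grid.cols))
        assert len(back) == 1


class TestCorrelationProbability:
    def _staggered_tables(self, grid):
        """One event per site and trial, latency stepped 2.5 ms per trial
        so cross-trial differences always exceed the central bin."""
        rows = []
        for r in range(grid.rows):
            for c in range(grid.cols):
                for tr in range(grid.repeats):
                    rows.append(("x", tr, r, c, 3.0 + 2.5 * tr, 50.0))
        return _event_table(rows, grid)

    def test_identical_events_give_unit_pc(self):
        grid = FocalGridProtocol(rows=4, cols=4, repeats=5)
        ev = self._staggered_tables(grid)
        res = fc.correlation_probability(ev, ev, grid)
        assert res.shifted_central_count == 0
        assert abs(res.pc - 1.0) < 0.05

    def test_disjoint_site_sets_give_zero_pc(self):
        grid = FocalGridProtocol(repeats=10)
        rng = np.random.default_rng(0)
        rows_a = [("a", tr, r, c, rng.uniform(2, 28), 50.0)
                  for tr in range(10) for r in range(5) for c in range(7)]
        rows_b = [("b", tr, r, c, rng.uniform(2, 28), 50.0)
                  for tr in range(10) for r in range(5, 10)
                  for c in range(7)]
        res = fc.correlation_probability(_event_table(rows_a, grid),
                                         _event_table(rows_b, grid), grid)
        assert abs(res.pc) < 0.05

    def test_shift_predictor_removes_rate_confound(self):
        """Independent cells with matched site-locked event rates give
        |Pc| < 0.05: the shifted correlogram absorbs the stimulus-locked
        coincidences (mean over 20 seeds)."""
        grid = FocalGridProtocol(repeats=10)
        pcs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tables = []
            for cell in "ab":
                rows = [(cell, tr, r, c, rng.uniform(2.0, 28.0), 50.0)
                        for tr in range(10) for r in range(grid.rows)
                        for c in range(grid.cols)]
                tables.append(_event_table(rows, grid))
            pcs.append(fc.correlation_probability(*tables, grid).pc)
        assert np.mean(np.abs(pcs)) < 0.05

    def test_zero_evoked_events_reported_missing(self):
        grid = FocalGridProtocol()
        empty = _event_table([], grid)
        res = fc.correlation_probability(empty, empty, grid)
        assert res.missing and np.isnan(res.pc)

    def test_spontaneous_correction_shrinks_normalizer(self):
        grid = FocalGridProtocol(rows=2, cols=2, repeats=2)
        rows = [("a", tr, r, c, 5.0, 50.0) for tr in range(2)
                for r in range(2) for c in range(2)]
        ev = _event_table(rows, grid)
        res0 = fc.correlation_probability(ev, ev, grid,
                                          spontaneous_rate_hz=0.0)
        res1 = fc.correlation_probability(ev, ev, grid,
                                          spontaneous_rate_hz=10.0)
        assert res1.normalizer < res0.normalizer

    def test_pc_increases_with_shared_inputs_small_cohort(self):
        """End-to-end focal pipeline: mean Pc grows with the number of
        shared presynaptic inputs (small seeded cohort)."""
        means = []
        for n_shared in (0, 8):
            pcs = [pl.focal_pc(n_shared, 500 + k).pc for k in range(3)]
            means.append(np.mean(pcs))
        assert means[1] > means[0] + 0.2


class TestResponseMap:
    def test_empty_events_zero_map(self):
        grid = FocalGridProtocol()
        m = fc.build_response_map(_event_table([], grid), grid)
        assert m.data.shape == (10, 7)
        assert not m.data.any()

    def test_single_event_placement(self):
        grid = FocalGridProtocol()
        m = fc.build_response_map(
            _event_table([("c", 0, 3, 2, 5.0, 50.0)], grid), grid)
        assert m.data[3, 2] == 50.0
        assert m.data.sum() == 50.0

    def test_repeats_are_additive(self):
        grid = FocalGridProtocol()
        single = [("c", 0, 1, 1, 5.0, 20.0), ("c", 0, 4, 3, 6.0, 30.0)]
        ten = [(c, tr, r, co, t, a) for tr in range(10)
               for (c, _, r, co, t, a) in single]
        m1 = fc.build_response_map(_event_table(single, grid), grid)
        m10 = fc.build_response_map(_event_table(ten, grid), grid)
        assert np.allclose(m10.data, 10.0 * m1.data)


class TestMapCorrelation:
    def test_identical_maps_perfect_r(self):
        rng = np.random.default_rng(0)
        m = fc.ResponseMap(rng.uniform(0, 100, (10, 7)))
        res = fc.map_correlation(m, m, seed=1)
        assert np.isclose(res.r, 1.0)
        assert res.percentile >= 99.0

    def test_mean_reflected_map_anticorrelated(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, (10, 7))
        b = 2 * a.mean() - a
        res = fc.map_correlation(fc.ResponseMap(a), fc.ResponseMap(b), seed=1)
        assert np.isclose(res.r, -1.0)

    def test_zero_variance_map_missing(self):
        a = fc.ResponseMap(np.zeros((10, 7)))
        b = fc.ResponseMap(np.random.default_rng(0).uniform(0, 1, (10, 7)))
        res = fc.map_correlation(a, b)
        assert res.missing and np.isnan(res.r)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fc.map_correlation(fc.ResponseMap(np.ones((2, 2))),
                               fc.ResponseMap(np.ones((3, 2))))

    def test_null_percentile_uniform_for_independent_maps(self):
        """For independent random maps the observed shuffle percentile is
        approximately uniform (KS test over 100 seeds)."""
        pct = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = fc.ResponseMap(rng.uniform(0, 100, (10, 7)))
            b = fc.ResponseMap(rng.uniform(0, 100, (10, 7)))
            pct.append(fc.map_correlation(a, b, seed=seed + 1000).percentile)
        ks = stats.kstest(np.array(pct) / 100.0, "uniform")
        assert ks.pvalue > 0.01


class TestSelectIntensity:
    def test_reported_operating_range(self):
        """Counts {1x: 40, 7x: 500} with the 335-908 range select the 7x
        level, the documented operating point of the focal analysis."""
        sel = fc.select_intensity({1.0: 40, 7.0: 500})
        assert sel.intensity == 7.0 and sel.in_range

    def test_no_level_in_range_flagged(self):
        sel = fc.select_intensity({1.0: 40, 2.0: 120})
        assert not sel.in_range
        assert sel.intensity == 2.0

    def test_tie_break_prefers_threshold_multiple(self):
        sel = fc.select_intensity({1.0: 10, 6.0: 400, 10.0: 600},
                                  threshold_multiple=7.0)
        assert sel.intensity == 6.0
        assert sel.preferred_intensity == 7.0

    def test_requires_two_levels(self):
        with pytest.raises(ValueError):
            fc.select_intensity({1.0: 10})


class TestSpatialTemporalAssociation:
    def test_map_correlation_tracks_pc_across_cohort(self):
        """Across pairs with graded shared input, spatial map correlation
        and temporal correlation probability rank together."""
        pcs, rs = [], []
        for n_shared in (0, 4, 8):
            for k in range(4):
                ev_a, ev_b, grid, _ = pl.focal_pair_events(n_shared, 700 + k)
                pcs.append(fc.correlation_probability(ev_a, ev_b, grid).pc)
                ma = fc.build_response_map(ev_a, grid)
                mb = fc.build_response_map(ev_b, grid)
                rs.append(fc.map_correlation(ma, mb, seed=k).r)
        rho = stats.spearmanr(pcs, rs).statistic
        assert rho > 0
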