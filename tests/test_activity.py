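import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meanet.activity import (association_stats, band_power, classify_cell_types,
                             classify_rate_change, cohens_d, detect_bursts,
                             find_burst_events, ks_compare, paired_compare,
                             unit_rates)
from meanet.spike_io import LfpTrace, SpikeTrainSet, Unit, bin_raster


class TestRates:
    def test_simple_rate(self):
        sts = SpikeTrainSet("s", "b",
                            [Unit("u", "SUA", np.linspace(0, 59999, 600))],
                            duration_ms=60000.0)
        assert unit_rates(sts)["u"] == pytest.approx(10.0)

    def test_empty_train_zero(self):
        sts = SpikeTrainSet("s", "b", [Unit("u", "SUA", np.array([]))],
                            duration_ms=1000.0)
        assert unit_rates(sts)["u"] == 0.0

    def test_zero_length_window_rejected(self, tiny_set):
        with pytest.raises(ValueError):
            unit_rates(tiny_set, window_ms=(10.0, 10.0))


class TestBursts:
    def test_constant_popsum_no_events(self):
        res = find_burst_events(np.full(100, 7.0))
        assert res.count == 0

    def test_injected_peaks_counted_by_hand_arithmetic(self):
        popsum = np.full(1200, 4.0)
        peaks = [100, 300, 500, 700, 900]
        popsum[peaks] = 60.0
        res = find_burst_events(popsum, k_sd=5.0)
        # mean = 4 + 5*56/1200; rms ~ 3.6; 60 - mean >> 5*rms
        assert res.count == 5
        assert [b for b, _h in res.events] == peaks
        assert all(h >= res.threshold for _b, h in res.events)

    def test_event_count_monotone_in_sd_multiplier(self):
        rng = np.random.default_rng(0)
        popsum = rng.poisson(10.0, size=2000).astype(float)
        popsum[::200] += 40
        counts = [find_burst_events(popsum, k_sd=k).count for k in (2, 3, 5, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_generator_burst_rate_recovered(self):
        from meanet.synthetic import (ConditionEffect, PopulationConfig,
                                      apply_condition, generate_baseline)
        cfg = PopulationConfig(n_sua=60, n_mua=0, duration_s=600.0, seed=21)
        base, gtb = generate_baseline(cfg)
        eff = ConditionEffect(burst_rate_per_min=1.0)
        treated, _ = apply_condition(base, eff, seed=22, base_truth=gtb)
        res = detect_bursts(bin_raster(treated, 1.0))
        assert abs(res.count - 10) <= 2

    def test_short_recording_rejected(self):
        sts = SpikeTrainSet("s", "b", [Unit("u", "SUA", np.array([1.0]))],
                            duration_ms=100.0)
        with pytest.raises(ValueError):
            detect_bursts(bin_raster(sts, 1.0), bin_ms=500.0)


class TestRateChange:
    def test_identical_rates_all_unchanged(self):
        r = pd.Series({"a": 2.0, "b": 5.0})
        _d, props = classify_rate_change(r, r.copy())
        assert props["unchanged"] == 1.0

    def test_mixed_directions(self):
        base = pd.Series({"a": 2.0, "b": 1.0, "c": 5.0})
        treated = pd.Series({"a": 1.0, "b": 2.0, "c": 5.0})
        d, props = classify_rate_change(base, treated, rel_tol=0.01)
        assert d["a"] == "decrease" and d["b"] == "increase" and d["c"] == "unchanged"
        assert props.sum() == pytest.approx(1.0)

    def test_mismatched_units_excluded_with_warning(self, caplog):
        import logging
        base = pd.Series({"a": 1.0, "b": 2.0})
        treated = pd.Series({"a": 1.5})
        with caplog.at_level(logging.WARNING):
            d, _ = classify_rate_change(base, treated)
        assert list(d.index) == ["a"]
        assert any("only one condition" in r.message for r in caplog.records)

    def test_generator_fractions_recovered(self):
        from meanet.synthetic import (ConditionEffect, PopulationConfig,
                                      apply_condition, generate_baseline)
        cfg = PopulationConfig(n_sua=96, n_mua=4, duration_s=600.0, seed=31)
        base, gtb = generate_baseline(cfg)
        eff = ConditionEffect(burst_rate_per_min=0.0)
        treated, gtt = apply_condition(base, eff, seed=32, base_truth=gtb)
        d, props = classify_rate_change(unit_rates(base), unit_rates(treated))
        agreement = np.mean([d[u] == t for u, t in
                             zip(base.unit_ids, gtt.true_change)])
        assert agreement >= 0.90
        assert abs(props["decrease"] - 0.62) <= 0.05
        assert abs(props["increase"] - 0.37) <= 0.05


class TestCellTyping:
    @staticmethod
    def _two_clusters(n=500, seed=0):
        rng = np.random.default_rng(seed)
        n_pyr = int(0.789 * n)
        ttp = np.concatenate([rng.normal(0.76, 0.12, n_pyr),
                              rng.normal(0.22, 0.05, n - n_pyr)])
        rate = np.concatenate([10 ** rng.normal(np.log10(3.2), 0.25, n_pyr),
                               10 ** rng.normal(np.log10(6.9), 0.25, n - n_pyr)])
        truth = np.array(["PPyrN"] * n_pyr + ["PIN"] * (n - n_pyr))
        df = pd.DataFrame({"trough_to_peak_ms": ttp, "rate_hz": rate})
        return df, truth

    def test_well_separated_clusters_recovered(self):
        df, truth = self._two_clusters()
        res = classify_cell_types(df, seed=0)
        assert np.mean(res.labels.to_numpy() == truth) >= 0.95
        assert res.stats.loc["trough_to_peak_ms", "p"] < 1e-6

    def test_labels_anchored_to_waveform_not_cluster_index(self):
        df, truth = self._two_clusters(seed=3)
        mirrored = df.iloc[::-1].reset_index(drop=True)
        res = classify_cell_types(mirrored, seed=0)
        wide = mirrored["trough_to_peak_ms"] > 0.5
        assert (res.labels[wide.to_numpy()] == "PPyrN").mean() > 0.95

    def test_label_invariance_to_row_order_and_uniform_scaling(self):
        df, _ = self._two_clusters(n=200, seed=5)
        res1 = classify_cell_types(df, seed=0)
        perm = np.random.default_rng(1).permutation(len(df))
        res2 = classify_cell_types(df.iloc[perm].reset_index(drop=True), seed=0)
        assert (res1.labels.to_numpy()[perm] == res2.labels.to_numpy()).all()
        scaled = df.copy()
        scaled["trough_to_peak_ms"] *= 10.0
        res3 = classify_cell_types(scaled, seed=0)
        assert (res1.labels.to_numpy() == res3.labels.to_numpy()).all()

    def test_cohens_d_definition_case(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 1.0, 20000)
        b = rng.normal(0.0, 1.0, 20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_degenerate_features_rejected(self):
        df = pd.DataFrame({"trough_to_peak_ms": [0.5] * 10,
                           "rate_hz": [2.0] * 10})
        with pytest.raises(ValueError, match="degenerate"):
            classify_cell_types(df)


class TestAssociation:
    def test_hand_computed_chi_square(self):
        out = association_stats(np.array([[10, 20], [20, 10]]))
        assert out["statistic"] == pytest.approx(20.0 / 3.0, abs=1e-9)
        assert out["df"] == 1
        assert out["p"] == pytest.approx(0.0098, abs=5e-4)

    def test_identical_rows_zero_statistic(self):
        out = association_stats(np.array([[5, 5], [5, 5]]))
        assert out["statistic"] == 0.0

    def test_transpose_invariance(self):
        t = np.array([[3, 9, 2], [7, 1, 6]])
        assert association_stats(t)["statistic"] == \
            pytest.approx(association_stats(t.T)["statistic"])

    def test_fisher_exact_option(self):
        out = association_stats(np.array([[10, 20], [20, 10]]), exact=True)
        assert out["test"] == "fisher_exact"
        assert 0 < out["p"] < 1


class TestBandPower:
    def test_zero_trace_all_zero(self):
        tr = LfpTrace(fs=500.0, samples=np.zeros(40000))
        bp = band_power(tr)
        assert all(v == 0.0 for v in bp.values())

    def test_six_hz_sinusoid_in_theta(self):
        t = np.arange(0, 70.0, 1 / 500.0)
        tr = LfpTrace(fs=500.0, samples=np.sin(2 * np.pi * 6.0 * t))
        bp = band_power(tr)
        assert bp["theta"] >= 0.9 * bp["broadband"]

    def test_equal_amplitude_lines_equal_power(self):
        t = np.arange(0, 70.0, 1 / 500.0)
        x = np.sin(2 * np.pi * 2.0 * t) + np.sin(2 * np.pi * 30.0 * t)
        bp = band_power(LfpTrace(fs=500.0, samples=x))
        assert bp["delta"] == pytest.approx(bp["gamma"], rel=0.05)

    def test_broadband_decomposition(self):
        tr = LfpTrace(fs=500.0, samples=np.random.default_rng(0).normal(size=40000))
        bp = band_power(tr)
        four = bp["delta"] + bp["theta"] + bp["beta"] + bp["gamma"]
        assert four <= bp["broadband"] + 1e-12  # plus the 0-0.5 Hz remainder

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            band_power(LfpTrace(fs=50.0, samples=np.zeros(10000)))


class TestPairedCompare:
    def test_equal_vectors_no_change_convention(self):
        out = paired_compare([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert out.test == "no_change"
        assert out.p == 1.0 and out.statistic == 0.0

    def test_constant_shift_extreme_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10)
        out = paired_compare(a, a + 10.0)
        assert out.test == "paired_t"
        assert out.p == 0.0

    def test_normal_shift_chooses_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        out = paired_compare(a, a + 10.0 + rng.normal(0, 0.5, 10))
        assert out.test == "paired_t"
        assert out.p < 0.001

    def test_heavy_tailed_differences_choose_wilcoxon(self):
        rng = np.random.default_rng(4)
        a = np.zeros(60)
        diffs = rng.normal(0, 0.1, 60)
        diffs[::6] += rng.normal(0, 20.0, 10)  # contaminated normal
        out = paired_compare(a, a + diffs + 1.0)
        assert out.test == "wilcoxon"

    def test_ks_compare_detects_shift(self):
        rng = np.random.default_rng(5)
        out = ks_compare(rng.normal(0, 1, 500), rng.normal(1, 1, 500))
        assert out["p"] < 1e-6
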