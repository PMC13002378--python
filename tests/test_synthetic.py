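import numpy as np
import pytest

from meanet.activity import band_power, unit_rates
from meanet.spike_io import LfpTrace
from meanet.synthetic import (ConditionEffect, PopulationConfig,
                              apply_condition, community_coupling,
                              generate_baseline, generate_lfp)


def isi_min(sts):
    return min((np.diff(u.timestamps_ms).min() for u in sts.units
                if u.n_spikes > 1), default=np.inf)


class TestBaseline:
    def test_poisson_count_oracle(self):
        # 10 Hz for 600 s: count within 3*sqrt(6000) of 6000
        cfg = PopulationConfig(n_sua=1, n_mua=0, fraction_pyr=1.0,
                               rate_pyr_hz=10.0, rate_log10_sd=0.0, seed=7)
        sts, _ = generate_baseline(cfg)
        count = sts.units[0].n_spikes
        assert abs(count - 6000) <= 3 * np.sqrt(6000)

    def test_same_seed_bit_identical(self):
        cfg = PopulationConfig(n_sua=5, n_mua=1, duration_s=30.0, seed=9)
        a, _ = generate_baseline(cfg)
        b, _ = generate_baseline(cfg)
        for ua, ub in zip(a.units, b.units):
            np.testing.assert_array_equal(ua.timestamps_ms, ub.timestamps_ms)

    def test_refractory_respected_everywhere(self):
        C = community_coupling(12, seed=0)
        cfg = PopulationConfig(n_sua=10, n_mua=2, duration_s=60.0,
                               refractory_ms=2.0, seed=3)
        sts, _ = generate_baseline(cfg, C)
        assert isi_min(sts) >= 2.0

    def test_rate_recovery_within_3se(self):
        cfg = PopulationConfig(n_sua=20, n_mua=0, duration_s=300.0,
                               rate_log10_sd=0.0, seed=5)
        sts, gt = generate_baseline(cfg)
        rates = unit_rates(sts)
        for uid, target in zip(sts.unit_ids, gt.target_rates_hz):
            se = np.sqrt(target / 300.0)
            assert abs(rates[uid] - target) <= 3 * se

    def test_nonsymmetric_coupling_rejected(self):
        cfg = PopulationConfig(n_sua=3, n_mua=0, duration_s=10.0)
        C = np.zeros((3, 3))
        C[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            generate_baseline(cfg, C)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_sua=0)
        with pytest.raises(ValueError):
            PopulationConfig(fraction_pyr=1.5)
        with pytest.raises(ValueError):
            PopulationConfig(duration_s=-1.0)

    def test_mua_units_flagged_without_waveform(self):
        cfg = PopulationConfig(n_sua=4, n_mua=3, duration_s=20.0, seed=1)
        sts, gt = generate_baseline(cfg)
        mua = [u for u in sts.units if u.kind == "MUA"]
        assert len(mua) == 3
        assert all(u.trough_to_peak_ms is None for u in mua)
        assert gt.true_labels.count("MUA") == 3


class TestCondition:
    def test_thinning_oracle_half_rate(self):
        cfg = PopulationConfig(n_sua=20, n_mua=0, duration_s=600.0,
                               rate_log10_sd=0.0, seed=2)
        base, gtb = generate_baseline(cfg)
        eff = ConditionEffect(frac_decrease=1.0, frac_increase=0.0,
                              frac_unchanged=0.0, decrease_scale=0.5,
                              burst_rate_per_min=0.0)
        treated, _ = apply_condition(base, eff, seed=3, base_truth=gtb)
        rb = unit_rates(base).to_numpy()
        rt = unit_rates(treated).to_numpy()
        ratio = rt / rb
        # binomial thinning: ratio ~ 0.5 with SE ~ sqrt(0.25/N)
        assert np.all(np.abs(ratio - 0.5) < 5 * np.sqrt(0.25 / (rb * 600)))

    def test_identity_effect_keeps_timestamps(self):
        cfg = PopulationConfig(n_sua=5, n_mua=0, duration_s=60.0, seed=4)
        base, gtb = generate_baseline(cfg)
        eff = ConditionEffect(frac_decrease=0.0, frac_increase=0.0,
                              frac_unchanged=1.0, burst_rate_per_min=0.0)
        treated, _ = apply_condition(base, eff, seed=5, base_truth=gtb)
        for ua, ub in zip(base.units, treated.units):
            np.testing.assert_array_equal(ua.timestamps_ms, ub.timestamps_ms)

    def test_assigned_directions_recorded_and_fractions_match(self):
        cfg = PopulationConfig(n_sua=96, n_mua=4, duration_s=30.0, seed=6)
        base, gtb = generate_baseline(cfg)
        eff = ConditionEffect(burst_rate_per_min=0.0)
        _, gtt = apply_condition(base, eff, seed=7, base_truth=gtb)
        n = len(gtt.true_change)
        assert gtt.true_change.count("decrease") == round(0.62 * n)
        assert gtt.true_change.count("increase") == round(0.37 * n)

    def test_empty_input_rejected(self):
        from meanet.spike_io import SpikeTrainSet
        empty = SpikeTrainSet("s", "baseline", [], duration_ms=1000.0)
        with pytest.raises(ValueError, match="empty"):
            apply_condition(empty, ConditionEffect(), seed=0)

    def test_determinism(self):
        cfg = PopulationConfig(n_sua=8, n_mua=0, duration_s=60.0, seed=8)
        base, gtb = generate_baseline(cfg)
        eff = ConditionEffect()
        a, _ = apply_condition(base, eff, seed=9, base_truth=gtb)
        b, _ = apply_condition(base, eff, seed=9, base_truth=gtb)
        for ua, ub in zip(a.units, b.units):
            np.testing.assert_array_equal(ua.timestamps_ms, ub.timestamps_ms)

    def test_burst_epochs_injected_and_refractory_kept(self):
        cfg = PopulationConfig(n_sua=30, n_mua=0, duration_s=600.0, seed=10)
        base, gtb = generate_baseline(cfg)
        eff = ConditionEffect(burst_rate_per_min=1.0)
        treated, gtt = apply_condition(base, eff, seed=11, base_truth=gtb)
        assert len(gtt.burst_epochs_ms) == 10
        assert all(100.0 <= d <= 500.0 for _s, d in gtt.burst_epochs_ms)
        assert isi_min(treated) >= 2.0


class TestLfp:
    def test_zero_weights_zero_trace(self):
        trace = generate_lfp({"delta": 0, "theta": 0, "beta": 0, "gamma": 0},
                             fs=500.0, duration_s=70.0, seed=0)
        assert np.allclose(trace.samples, 0.0)
        bp = band_power(trace)
        assert all(bp[b] == 0.0 for b in ("delta", "theta", "beta", "gamma"))

    def test_theta_only_concentrates_power(self):
        trace = generate_lfp({"theta": 1.0}, fs=500.0, duration_s=70.0, seed=1)
        bp = band_power(trace)
        assert bp["theta"] >= 0.9 * bp["broadband"]

    def test_requested_relative_weights_recovered(self):
        w = {"delta": 1.0, "theta": 2.0, "beta": 0.5, "gamma": 1.5}
        trace = generate_lfp(w, fs=500.0, duration_s=90.0, seed=2)
        bp = band_power(trace)
        total_w = sum(w.values())
        total_p = sum(bp[b] for b in w)
        for b in w:
            assert bp[b] / total_p == pytest.approx(w[b] / total_w, rel=0.10)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            generate_lfp(fs=500.0, duration_s=2.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            generate_lfp(fs=100.0, duration_s=70.0)
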