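import numpy as np
import pytest
from scipy import stats

from latewave.roc import (
    AUCSeries,
    CodingFraction,
    auc_timecourse,
    bootstrap_onset,
    classify_coder,
    coding_fraction,
    laminar_map,
    onset_from_fraction,
    onset_rt_regression,
    session_onset,
)


def _series(sig, times=None, variable="hitmiss"):
    sig = np.asarray(sig, dtype=bool)
    if times is None:
        times = np.arange(len(sig)) * 0.025
    return AUCSeries(
        auc_per_bin=np.where(sig, 0.8, 0.5), p_per_bin=np.where(sig, 0.001, 0.5),
        sig_mask=sig, times=np.asarray(times, dtype=float), variable=variable,
    )


class TestAUC:
    def test_equals_mann_whitney_u_exactly(self, rng):
        """Brute-force pairwise-comparison oracle, including midrank ties."""
        for _ in range(200):
            n1, n0 = rng.integers(10, 25, 2)
            x1 = rng.integers(0, 6, n1).astype(float)  # discrete -> many ties
            x0 = rng.integers(0, 6, n0).astype(float)
            rates = np.r_[x1, x0][:, None]
            labels = np.r_[np.ones(n1), np.zeros(n0)]
            series = auc_timecourse(rates, labels, n_shuffles=10, seed=0)
            # oracle: all pairwise comparisons with 0.5 for ties
            diff = x1[:, None] - x0[None, :]
            u = (diff > 0).sum() + 0.5 * (diff == 0).sum()
            auc = u / (n1 * n0)
            assert series.auc_per_bin[0] == pytest.approx(max(auc, 1 - auc))

    def test_perfect_separation_gives_one(self):
        rates = np.r_[np.zeros(12), np.ones(12)][:, None]
        labels = np.r_[np.zeros(12), np.ones(12)]
        s = auc_timecourse(rates, labels, n_shuffles=100, seed=0)
        assert s.auc_per_bin[0] == 1.0
        assert s.sig_mask[0]

    def test_null_false_positive_rate_near_alpha(self, rng):
        """Per-bin significance on label-exchangeable data fires ~1% of the time."""
        hits = 0
        total = 0
        for rep in range(20):
            rates = rng.normal(size=(30, 25))
            labels = np.r_[np.ones(15), np.zeros(15)]
            s = auc_timecourse(rates, labels, n_shuffles=1000, seed=rep)
            hits += s.sig_mask.sum()
            total += len(s.sig_mask)
        rate = hits / total
        assert 0.002 <= rate <= 0.025

    def test_small_class_rejected(self, rng):
        with pytest.raises(ValueError):
            auc_timecourse(rng.normal(size=(15, 4)),
                           np.r_[np.ones(5), np.zeros(10)])

    def test_pvalue_never_zero(self, rng):
        rates = np.r_[np.zeros(12), np.ones(12)][:, None]
        labels = np.r_[np.zeros(12), np.ones(12)]
        s = auc_timecourse(rates, labels, n_shuffles=100, seed=0)
        assert s.p_per_bin[0] >= 1.0 / 101.0

    def test_rectified_to_upper_half(self, rng):
        rates = rng.normal(size=(40, 50))
        labels = rng.integers(0, 2, 40)
        labels[:10] = 1
        labels[10:20] = 0
        s = auc_timecourse(rates, labels, n_shuffles=10, seed=1)
        assert np.all(s.auc_per_bin >= 0.5)


class TestCoderClassification:
    def test_three_consecutive_bins_make_a_coder(self):
        sig = np.zeros(60, bool)
        sig[25:28] = True
        assert classify_coder(_series(sig, times=np.arange(60) * 0.025 - 0.5))

    def test_alternating_significance_is_not_coding(self):
        sig = np.zeros(60, bool)
        sig[24:40:2] = True
        assert not classify_coder(_series(sig, times=np.arange(60) * 0.025 - 0.5))

    def test_significance_outside_window_ignored(self):
        sig = np.zeros(60, bool)
        sig[:3] = True  # pre-stimulus run
        assert not classify_coder(_series(sig, times=np.arange(60) * 0.025 - 0.5))


class TestCodingFraction:
    def test_counting_single_significant_neuron(self):
        sig = np.zeros(40, bool)
        sig[20:30] = True
        series = [_series(sig)] + [_series(np.zeros(40, bool)) for _ in range(9)]
        frac = coding_fraction(series)
        assert frac.fraction_per_bin[25] == pytest.approx(0.1)
        assert frac.fraction_per_bin[5] == 0.0

    def test_normalization_skipped_below_ten_percent_rise(self):
        series = [_series(np.zeros(40, bool)) for _ in range(10)]
        frac = coding_fraction(series)
        assert frac.normalized_per_bin is None

    def test_normalization_applied_on_clear_rise(self):
        sig = np.zeros(40, bool)
        sig[20:] = True
        series = [_series(sig) for _ in range(6)] + [
            _series(np.zeros(40, bool)) for _ in range(4)
        ]
        times = np.arange(40) * 0.025 - 0.5
        frac = coding_fraction([_series(s.sig_mask, times) for s in series])
        assert frac.normalized_per_bin is not None
        assert frac.normalized_per_bin.max() == pytest.approx(1.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            coding_fraction([])


class TestOnsets:
    @staticmethod
    def _fraction(frac, times, n=100):
        return CodingFraction(fraction_per_bin=np.asarray(frac, float),
                              normalized_per_bin=None,
                              times=np.asarray(times, float), n_neurons=n)

    def test_flat_series_has_no_onset(self):
        times = np.arange(60) * 0.025 - 0.5
        est = onset_from_fraction(self._fraction(np.full(60, 0.01), times))
        assert est.onset_ms is None

    def test_exact_step_onset(self):
        times = np.arange(60) * 0.025 - 0.5
        frac = np.where(times >= 0.3, 0.5, 0.0)
        est = onset_from_fraction(self._fraction(frac, times))
        assert est.onset_ms == pytest.approx(300.0)
        assert est.extra["robustness"][1.0] == pytest.approx(300.0)

    def test_scale_invariance_of_onset(self, rng):
        # onset depends only on which bins are significant, so multiplying
        # all underlying rates by a constant cannot move it
        rates = rng.normal(5.0, 1.0, size=(40, 60))
        rates[20:, 30:] += 3.0
        labels = np.r_[np.zeros(20), np.ones(20)]
        times = np.arange(60) * 0.025 - 0.5
        s1 = auc_timecourse(rates, labels, times=times, n_shuffles=300, seed=0)
        s2 = auc_timecourse(rates * 7.3, labels, times=times, n_shuffles=300, seed=0)
        np.testing.assert_array_equal(s1.sig_mask, s2.sig_mask)

    def test_bootstrap_identical_neurons_zero_width_ci(self):
        sig = np.zeros(60, bool)
        sig[30:45] = True
        times = np.arange(60) * 0.025 - 0.5
        series = [_series(sig, times) for _ in range(25)]
        est = bootstrap_onset(series, n_boot=100, seed=0)
        assert est.ci95[0] == est.ci95[1] == est.onset_ms

    def test_bootstrap_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        times = np.arange(60) * 0.025 - 0.5
        series = []
        for _ in range(25):
            sig = np.zeros(60, bool)
            sig[rng.integers(25, 35):] = True
            series.append(_series(sig, times))
        a = bootstrap_onset(series, n_boot=200, seed=9)
        b = bootstrap_onset(series, n_boot=200, seed=9)
        assert a.onset_ms == b.onset_ms and a.ci95 == b.ci95

    def test_bootstrap_needs_enough_neurons(self):
        with pytest.raises(ValueError):
            bootstrap_onset([_series(np.zeros(10, bool))] * 5)

    def test_session_onset_requires_ten_neurons(self, rng):
        with pytest.raises(ValueError):
            session_onset(rng.normal(size=(9, 30, 20)), rng.integers(0, 2, 30),
                          np.arange(20) * 0.025)

    def test_session_onset_none_without_modulation(self, rng):
        rates = rng.normal(size=(12, 40, 40))
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        est = session_onset(rates, labels, np.arange(40) * 0.025 - 0.5,
                            n_shuffles=300, seed=0)
        assert est.onset_ms is None


class TestLaminarMap:
    def test_map_dimensions(self, rng):
        times = np.arange(40) * 0.025 - 0.5
        series = [_series(rng.random(40) < 0.1, times) for _ in range(30)]
        depths = rng.uniform(0, 1150, 30)
        m = laminar_map(series, depths)
        assert m["fraction"].shape == (23, 40)

    def test_smoothing_conserves_interior_mass(self):
        times = np.arange(40) * 0.025 - 0.5
        rng = np.random.default_rng(1)
        series = [_series(rng.random(40) < 0.3, times) for _ in range(200)]
        depths = rng.uniform(0, 1150, 200)
        m = laminar_map(series, depths)
        raw = np.nan_to_num(m["fraction"])
        assert m["smoothed"][3:-3].sum() == pytest.approx(raw[3:-3].sum(), rel=0.15)

    def test_zone_ordering_from_generator_structure(self):
        """Early (occurrence) coding strongest granular/supragranular; late
        hit/miss coding strongest infragranular, per the generator gains."""
        from latewave.analysis import session_auc_series
        from latewave.simulate import CohortConfig, simulate_session

        cfg = CohortConfig.MST(n_trials=400, n_neurons=30, seed=21)
        s = simulate_session(cfg)
        depths = s.neurons["depth_um"].to_numpy()
        zones = np.select([depths < 400, depths <= 550], ["SG", "G"], "IG")

        occ = session_auc_series(s, variable="occurrence", saliency="max",
                                 n_shuffles=500, seed=0)
        hm = session_auc_series(s, variable="hitmiss", n_shuffles=500, seed=0)
        times = occ[0].times

        def zone_fraction(series, zone, t0, t1):
            sel = [sr for sr, z in zip(series, zones) if z == zone]
            mask = (times >= t0) & (times < t1)
            return np.mean([sr.sig_mask[mask].mean() for sr in sel])

        # early sensory window: granular exceeds infragranular
        assert zone_fraction(occ, "G", 0.0, 0.2) > zone_fraction(occ, "IG", 0.0, 0.2)
        # late report window: infragranular exceeds granular
        assert zone_fraction(hm, "IG", 0.3, 1.0) > zone_fraction(hm, "G", 0.3, 1.0)


class TestOnsetRTRegression:
    def test_exact_lag_recovers_fixed_slope_offset(self):
        rts = np.linspace(0.3, 0.8, 10)
        onsets = rts - 0.28
        out = onset_rt_regression(onsets, rts, fixed_slope=1.0)
        assert out["offset_ms"] == pytest.approx(280.0)

    def test_constant_onsets_have_zero_slope(self):
        rts = np.linspace(0.3, 0.8, 10)
        out = onset_rt_regression(np.full(10, 0.2), rts)
        assert out["ols_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            onset_rt_regression([0.1, 0.2], [0.3, 0.4])
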