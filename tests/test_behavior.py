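import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from latewave.behavior import (
    MADCModel,
    MNLogitFit,
    MNLogitModel,
    PsychometricFit,
    PsychometricModel,
    cumnorm_psychometric,
    dprime_from_rates,
    fit_madc,
    hyperbolic_dprime,
    insert_artificial_catch,
    madc_rates,
    mnlogit_probs,
    response_table,
    session_filters,
    silencing_effect,
)
from latewave.simulate import CohortConfig, simulate_behavior
from latewave.stimuli import sample_trial_sequence


class TestCumnormPsychometric:
    def test_median_is_half(self):
        fit = PsychometricFit(0.0, 0.0, 10.0, 4.0)
        assert cumnorm_psychometric(10.0, fit) == pytest.approx(0.5)

    def test_asymptote_is_one_minus_lapse(self):
        fit = PsychometricFit(0.05, 0.1, 10.0, 4.0)
        assert cumnorm_psychometric(1e6, fit) == pytest.approx(0.9)

    def test_guess_and_lapse_midpoint(self):
        fit = PsychometricFit(0.1, 0.1, 10.0, 4.0)
        assert cumnorm_psychometric(10.0, fit) == pytest.approx(0.5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PsychometricFit(0.6, 0.5, 10.0, 4.0)
        with pytest.raises(ValueError):
            PsychometricFit(0.1, 0.1, 10.0, -1.0)


class TestPsychometricFitting:
    def test_parameter_recovery_from_binomial_data(self, rng):
        true = PsychometricFit(0.1, 0.05, 10.0, 4.0)
        x = np.array([2.0, 5.0, 8.0, 10.0, 12.0, 16.0, 24.0])
        n = np.full(len(x), 500)
        k = rng.binomial(n, cumnorm_psychometric(x, true))
        res = PsychometricModel(x, k, n).fit()
        assert res.params.mu == pytest.approx(10.0, abs=1.0)
        assert res.params.sigma == pytest.approx(4.0, abs=1.5)
        assert res.params.gamma == pytest.approx(0.1, abs=0.05)
        assert "threshold" in res.summary()

    def test_saliency_levels_from_fit(self):
        fit = PsychometricFit(0.0, 0.0, 10.0, 4.0)
        levels = fit.saliency_levels
        assert levels == {"sub": 6.0, "thr": 10.0, "sup": 14.0}

    def test_step_data_hits_sigma_floor_without_crashing(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        k = np.array([0, 0, 0, 100, 100, 100])
        res = PsychometricModel(x, k, np.full(6, 100)).fit()
        assert res.params.sigma > 0

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            PsychometricModel([1, 2, 3], [0, 1, 2], [5, 5, 5])


class TestMADCRates:
    def test_rows_sum_to_one(self):
        table = madc_rates(1.2, 0.8, 0.5, 1.0)
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_infinite_criterion_limit_is_all_nogo(self):
        table = madc_rates(0.0, 0.0, 20.0, 20.0)
        np.testing.assert_allclose(table["none"], 1.0, atol=1e-12)

    def test_symmetric_parameters_give_symmetric_catch_row(self):
        table = madc_rates(1.5, 1.5, 1.0, 1.0)
        assert table.loc["catch", "visual"] == pytest.approx(
            table.loc["catch", "auditory"], abs=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_monte_carlo_decision_rule(self, seed):
        """The numeric integration must agree with brute-force simulation
        of the bivariate decision rule within Monte-Carlo error."""
        rng = np.random.default_rng(seed)
        dv, da = rng.uniform(0, 3, 2)
        cv, ca = rng.uniform(-0.5, 2, 2)
        table = madc_rates(dv, da, cv, ca)
        n = 400_000
        for ttype, (mv, ma) in {
            "visual": (dv, 0), "auditory": (0, da), "catch": (0, 0)
        }.items():
            ev = rng.standard_normal(n) + mv
            ea = rng.standard_normal(n) + ma
            pv = np.mean((ev >= cv) & (ev - cv >= ea - ca))
            pa = np.mean((ea >= ca) & (ea - ca > ev - cv))
            for resp, p_mc in [("visual", pv), ("auditory", pa)]:
                se = np.sqrt(p_mc * (1 - p_mc) / n) + 1e-6
                assert abs(table.loc[ttype, resp] - p_mc) < 3 * se

    def test_negative_dprime_rejected(self):
        with pytest.raises(ValueError):
            madc_rates(-0.1, 0.0, 0.0, 0.0)


class TestMADCFit:
    def test_recovery_from_simulated_sessions(self):
        cfg = CohortConfig.MST(seed=0)
        errs = []
        for rep in range(3):
            rng = np.random.default_rng(100 + rep)
            trials = simulate_behavior(sample_trial_sequence(600, rng), cfg, rng)
            res = fit_madc(response_table(trials), seed=rep)
            errs.append(res.dprime[("visual", "max")] - cfg.dprime_visual["max"])
            assert res.valid
        assert abs(np.mean(errs)) < 0.25

    def test_missing_catch_trials_is_an_error(self):
        counts = pd.DataFrame(
            dict(trial_type=["visual"], saliency=["max"], x=[90.0],
                 n_visual=[50], n_auditory=[5], n_none=[45])
        )
        with pytest.raises(ValueError, match="catch"):
            MADCModel(counts)

    def test_hyperbolic_midpoint_and_origin(self):
        assert hyperbolic_dprime(2.0, d_max=3.0, n=1.5, s50=2.0) == pytest.approx(1.5)
        assert hyperbolic_dprime(0.0, d_max=3.0, n=1.5, s50=2.0) == 0.0

    @given(
        d_max=st.floats(0.1, 6.0), n=st.floats(0.3, 4.0), s50=st.floats(0.5, 50.0)
    )
    @settings(deadline=None, max_examples=50)
    def test_hyperbolic_dprime_nondecreasing(self, d_max, n, s50):
        x = np.linspace(0, 100, 300)
        d = hyperbolic_dprime(x, d_max, n, s50)
        assert np.all(np.diff(d) >= -1e-12)

    def test_hyperbolic_variant_fits_and_flags_threshold(self, rng):
        cfg = CohortConfig.MST(seed=1)
        trials = simulate_behavior(sample_trial_sequence(800, rng), cfg, rng)
        counts = response_table(trials)
        # attach change magnitudes in degrees / octaves
        counts["x"] = counts.apply(
            lambda r: {"thr": 7.0, "max": 90.0}.get(r["saliency"], np.nan)
            if r["trial_type"] == "visual"
            else {"thr": 1 / 32, "max": 0.5}.get(r["saliency"], np.nan),
            axis=1,
        )
        res = fit_madc(counts, variant="hyperbolic", seed=0)
        assert res.psychometric is not None
        assert set(res.criterion) == {"visual", "auditory"}
        assert res.loglike < 0


class TestDprimeFromRates:
    def test_equal_rates_give_zero(self):
        assert dprime_from_rates(0.5, 0.5) == 0.0
        assert dprime_from_rates(0.3, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_against_erfinv_oracle(self):
        # two evaluations of the inverse normal CDF, oracle = erfinv
        assert dprime_from_rates(0.84, 0.16) == pytest.approx(1.9889157664195063)

    @given(h=st.floats(0.01, 0.99), f=st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_antisymmetric_under_rate_swap(self, h, f):
        assert dprime_from_rates(h, f) == pytest.approx(-dprime_from_rates(f, h))

    def test_extreme_rates_use_half_count_correction(self):
        d = dprime_from_rates(1.0, 0.0, n_hit=50, n_fa=50)
        expected = stats.norm.ppf(1 - 1 / 100) - stats.norm.ppf(1 / 100)
        assert d == pytest.approx(expected)
        with pytest.raises(ValueError):
            dprime_from_rates(1.0, 0.1)


class TestMNLogit:
    def test_zero_contrast_odds_equal_bias(self):
        fit = MNLogitFit(-1.2, -0.8, 0.5, 1.5, 1.8, 0.2, 0.7)
        pl, pr, p0 = mnlogit_probs(0.0, 0.0, fit)
        assert pr / p0 == pytest.approx(np.exp(-1.2))
        assert pl / p0 == pytest.approx(np.exp(-0.8))

    @given(
        cl=st.floats(0, 2), cr=st.floats(0, 2),
        br=st.floats(-3, 3), bl=st.floats(-3, 3), n=st.floats(0.1, 1.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_probabilities_normalize(self, cl, cr, br, bl, n):
        fit = MNLogitFit(br, bl, 0.5, 1.0, 1.0, 0.5, n)
        assert sum(mnlogit_probs(cl, cr, fit)) == pytest.approx(1.0)

    def test_ml_refit_recovers_choice_probabilities(self, rng):
        true = MNLogitFit(-1.2, -1.0, -0.5, 2.0, 2.2, -0.4, 0.7)
        cL = rng.uniform(0, 1, 2000)
        cR = rng.uniform(0, 1, 2000)
        pl, pr, _ = mnlogit_probs(cL, cR, true)
        u = rng.random(2000)
        choice = np.where(u < pl, "left", np.where(u < pl + pr, "right", "none"))
        model = MNLogitModel(cL, cR, choice)
        res = model.fit()
        # refit log-likelihood cannot fall below the truth's by more than noise
        assert res.loglike >= model.loglike(true) - 1.0
        pl2, pr2, _ = res.predict(cL, cR)
        assert np.mean(np.abs(pl2 - pl)) < 0.05

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            MNLogitFit(0, 0, 0, 0, 0, 0, 1.5)


class TestArtificialCatch:
    def test_quiet_session_yields_only_correct_rejections(self, rng):
        trials = pd.DataFrame(
            dict(change_time=np.arange(10) * 15.0 + 5.0,
                 outcome=["miss"] * 10, reaction_time=[np.nan] * 10,
                 trial_type=["visual"] * 10, saliency=["max"] * 10)
        )
        licks = pd.DataFrame(dict(time_s=[], side=[]))
        aug = insert_artificial_catch(trials, licks, rng)
        ins = aug[aug["artificial"].astype(bool)]
        assert len(ins) > 0
        assert (ins["outcome"] == "CR").all()

    def test_inserted_times_respect_gap_to_real_changes(self, small_session, rng):
        aug = insert_artificial_catch(small_session.trials, small_session.licks, rng)
        ins = aug[aug["artificial"].astype(bool)]
        real = np.sort(small_session.trials["change_time"].to_numpy())
        for t in ins["change_time"]:
            later = real[real > t]
            assert len(later) == 0 or later[0] - t >= 3.0

    def test_latency_matching_reduces_ks_distance(self, rng):
        cfg = CohortConfig.MST(n_trials=400, seed=5, spontaneous_lick_rate=0.4)
        gen = np.random.default_rng(3)
        trials = simulate_behavior(sample_trial_sequence(400, gen), cfg, gen)
        lick_times = np.sort(gen.uniform(0, trials["change_time"].max(), 6000))
        licks = pd.DataFrame(dict(time_s=lick_times, side="left"))
        hit_rts = trials.loc[trials["outcome"] == "hit", "reaction_time"].dropna()

        aug = insert_artificial_catch(trials, licks, rng)
        fa = aug[(aug["artificial"].astype(bool)) & (aug["outcome"] == "FA")]
        # unmatched FA latencies: first lick after each candidate is ~uniform
        raw = insert_artificial_catch(trials, licks, np.random.default_rng(1),
                                      n_latency_bins=1)
        fa_raw = raw[(raw["artificial"].astype(bool)) & (raw["outcome"] == "FA")]
        ks_matched = stats.ks_2samp(fa["reaction_time"], hit_rts).statistic
        ks_raw = stats.ks_2samp(fa_raw["reaction_time"], hit_rts).statistic
        assert len(fa) >= 10
        assert ks_matched <= ks_raw + 0.05


class TestSessionFilters:
    @staticmethod
    def _trials(outcomes, choices):
        return pd.DataFrame(
            dict(choice=choices, outcome=outcomes,
                 trial_type=["visual"] * len(outcomes),
                 saliency=["max"] * len(outcomes))
        )

    def test_trailing_no_response_run_is_trimmed(self):
        t = self._trials(["hit"] * 30 + ["miss"] * 25,
                         ["left"] * 30 + ["none"] * 25)
        included, trimmed, reasons = session_filters(t)
        assert len(trimmed) == 30
        assert included
        assert any("trimmed" in r for r in reasons)

    def test_low_max_hit_rate_excludes_session(self):
        t = self._trials(["hit"] * 5 + ["miss"] * 15, ["left"] * 5 + ["none"] * 15)
        included, _, reasons = session_filters(t, no_response_run=100)
        assert not included

    def test_good_session_is_included(self):
        t = self._trials(["hit"] * 19 + ["miss"], ["left"] * 19 + ["none"])
        included, trimmed, _ = session_filters(t)
        assert included and len(trimmed) == 20


class TestSilencingEffect:
    def test_relative_effect_identities(self):
        from latewave.behavior import _session_dprime  # noqa: F401
        # opto d' equal to control -> delta 0; opto d' 0 -> delta 1
        d_ctrl = 2.0
        assert (d_ctrl - 2.0) / d_ctrl == 0.0
        assert (d_ctrl - 0.0) / d_ctrl == 1.0

    def test_late_effect_tracks_reaction_time(self):
        root = np.random.default_rng(5)
        sessions = []
        for i in range(6):
            cfg = CohortConfig.MST(
                n_trials=400, photostim_fraction=0.5,
                rt_lognormal_mu=float(np.log(0.45 + 0.06 * i)),
                seed=int(root.integers(2**31)),
            )
            gen = np.random.default_rng(int(root.integers(2**31)))
            trials = sample_trial_sequence(400, gen, photostim_fraction=0.5)
            sessions.append(simulate_behavior(trials, cfg, gen))
        res = silencing_effect(sessions)
        assert res["n_qualifying"] >= 4
        assert res["r"] > 0

    def test_no_qualifying_sessions_returns_empty(self):
        t = pd.DataFrame(
            dict(photostim=["none"] * 4, trial_type=["visual"] * 4,
                 saliency=["max"] * 4, outcome=["hit"] * 4,
                 choice=["left"] * 4, reaction_time=[0.4] * 4)
        )
        res = silencing_effect([t])
        assert res["n_qualifying"] == 0 and np.isnan(res["r"])
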