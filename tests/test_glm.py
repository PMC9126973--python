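import numpy as np
import pytest
import statsmodels.api as sm

from latewave.glm import (
    PoissonEncodingModel,
    _enet_fit,
    _top_eigenvalue,
    build_design,
    explained_variance,
    fit_poisson_elasticnet,
    raised_cosine_basis,
    spike_counts,
    subset_ev,
)
from latewave.stimuli import make_stimulus_set

VSET = make_stimulus_set("visual", 100.0, 7.0)
ASET = make_stimulus_set("auditory", 13.25, 1.0 / 32.0)


@pytest.fixture(scope="module")
def design(small_session):
    trials = small_session.trials
    trials = trials[trials["trial_type"] != "multimodal"].reset_index(drop=True)
    return (
        build_design(trials, small_session.licks, small_session.pupil, VSET, ASET,
                     seed=0),
        trials,
    )


class TestRaisedCosine:
    def test_interior_sum_tiles_to_one(self):
        basis = raised_cosine_basis(10, (0.0, 2.0))
        t = np.linspace(0.01, 1.99, 400)
        total = basis.evaluate(t).sum(axis=1)
        assert np.all((total > 0.99) & (total < 1.01))

    def test_single_bump_peaks_at_midpoint(self):
        basis = raised_cosine_basis(1, (0.0, 0.2))
        t = np.linspace(0, 0.2, 201)
        vals = basis.evaluate(t)[:, 0]
        assert t[vals.argmax()] == pytest.approx(0.1, abs=1e-6)

    def test_early_and_late_sensory_spans(self):
        early = raised_cosine_basis(2, (0.0, 0.2))
        late = raised_cosine_basis(10, (0.0, 2.0))
        assert early.n_funcs == 2 and early.span == (0.0, 0.2)
        assert late.n_funcs == 10 and late.span == (0.0, 2.0)

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError):
            raised_cosine_basis(3, (1.0, 1.0))

    def test_bumps_bounded_by_one_and_nonnegative(self):
        basis = raised_cosine_basis(5, (-0.2, 0.4))
        vals = basis.evaluate(np.linspace(-0.3, 0.5, 300))
        assert vals.min() >= 0.0 and vals.max() <= 1.0 + 1e-12


class TestDesignMatrix:
    def test_full_model_has_126_predictors(self, design):
        d, _ = design
        assert d.X.shape[1] == 126

    def test_family_column_counts(self, design):
        d, _ = design
        sizes = {f: len(ix) for f, ix in d.families.items()}
        assert sizes["visual"] + sizes["auditory"] == 96
        assert sizes["hit"] == 20
        assert sizes["movement"] == 6
        assert sizes["pupil"] == 3
        assert sizes["trial_number"] == 1

    def test_null_model_single_random_column(self, small_session):
        trials = small_session.trials.head(20)
        d = build_design(trials, small_session.licks, small_session.pupil,
                         VSET, ASET, null_model=True, seed=1)
        assert d.X.shape[1] == 1

    def test_columns_scaled_to_unit_maximum(self, design):
        d, _ = design
        mx = np.abs(d.X).max(axis=0)
        nonzero = mx > 0
        np.testing.assert_allclose(mx[nonzero], 1.0)

    def test_split_hit_layout_keeps_20_columns(self, small_session):
        trials = small_session.trials
        trials = trials[trials["trial_type"] != "multimodal"].reset_index(drop=True)
        d = build_design(trials, small_session.licks, small_session.pupil,
                         VSET, ASET, split_hit_by_modality=True)
        assert len(d.families["hit"]) == 20
        assert d.X.shape[1] == 126

    def test_missing_pupil_zeroes_family(self, small_session):
        trials = small_session.trials.head(30)
        d = build_design(trials, small_session.licks, None, VSET, ASET)
        assert np.all(d.X[:, d.families["pupil"]] == 0)


class TestSolver:
    def test_unpenalized_limit_matches_statsmodels(self, rng):
        n, p = 1500, 6
        X = rng.random((n, p))
        beta = np.array([0.8, -0.5, 0.0, 1.0, 0.0, 0.3])
        y = rng.poisson(np.exp(X @ beta - 1.0))
        eig = _top_eigenvalue(X)
        b, b0 = _enet_fit(X, y, 0.0, 0.95, eig, np.zeros(p),
                          float(np.log(y.mean())), max_iter=5000, tol=1e-10)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(np.r_[b0, b], ref.params, atol=1e-5)

    def test_infinite_penalty_zeroes_all_coefficients(self, rng):
        X = rng.random((500, 5))
        y = rng.poisson(1.0, 500)
        eig = _top_eigenvalue(X)
        b, b0 = _enet_fit(X, y, 1e4, 0.95, eig, np.zeros(5), 0.0)
        assert np.all(b == 0)
        assert b0 == pytest.approx(np.log(y.mean()), abs=0.05)

    def test_same_seed_same_folds_and_fit(self, design):
        d, trials = design
        y = np.zeros(d.X.shape[0])
        m1 = PoissonEncodingModel(d, y, seed=3)
        m2 = PoissonEncodingModel(d, y, seed=3)
        np.testing.assert_array_equal(m1._fold_assignment(), m2._fold_assignment())

    def test_fold_assignment_partitions_trials(self, design):
        d, _ = design
        m = PoissonEncodingModel(d, np.zeros(d.X.shape[0]), folds=5, seed=0)
        f = m._fold_assignment()
        # constant within trial
        per_trial = f.reshape(d.n_trials, d.n_bins)
        assert np.all(per_trial == per_trial[:, :1])
        # all folds used, full coverage
        assert set(np.unique(f)) == set(range(5))

    def test_known_sparse_weights_recovered(self, design, rng):
        """Counts generated from known kernel weights on three families:
        the fit must keep most truly-active groups and give positive EV."""
        d, _ = design
        beta = np.zeros(126)
        fam = d.families
        active = {"visual": fam["visual"][:6], "hit": fam["hit"][:5],
                  "movement": fam["movement"][:3]}
        for ix in active.values():
            beta[ix] = 1.2
        eta = d.X @ beta - 3.2
        y = rng.poisson(np.exp(eta))
        res = fit_poisson_elasticnet(d, y, n_lambda=12, seed=0)
        hits = sum(np.any(res.coef_[ix] != 0) for ix in active.values())
        assert hits >= 2  # at least 2 of the 3 active families retained
        ev = explained_variance(y, res.cv_predict(), mode="overall")
        assert ev > 0.05
        # inactive pupil family stays (almost) empty
        assert np.sum(res.coef_[fam["pupil"]] != 0) <= 1
        assert "nonzero" in res.summary()


class TestExplainedVariance:
    def test_perfect_prediction_gives_one(self, rng):
        y = rng.poisson(2.0, 500).astype(float)
        assert explained_variance(y, y) == 1.0

    def test_mean_prediction_gives_zero(self, rng):
        y = rng.poisson(2.0, 500).astype(float)
        assert explained_variance(y, np.full_like(y, y.mean())) == pytest.approx(0.0)

    def test_zero_variance_flagged_as_nan(self):
        y = np.ones(10)
        assert np.isnan(explained_variance(y, y * 0.5))

    def test_per_bin_mode_shapes(self, rng):
        y = rng.poisson(2.0, (40, 30)).astype(float)
        ev = explained_variance(y, y * 0.9, mode="per_bin")
        assert ev.shape == (30,)

    def test_condition_average_mode(self, rng):
        y = rng.poisson(2.0, (60, 20)).astype(float)
        labels = np.repeat(["a", "b", "c"], 20)
        ev = explained_variance(y, y, mode="condition_avg",
                                condition_labels=labels, n_conditions=2)
        assert ev == 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            explained_variance(np.ones(3), np.ones(3), mode="bogus")


class TestSubsetEV:
    @pytest.fixture(scope="class")
    def fitted(self, design):
        d, _ = design
        beta = np.zeros(126)
        beta[d.families["visual"][:2]] = 2.0  # early bases only
        y = np.random.default_rng(5).poisson(np.exp(d.X @ beta - 3.0))
        res = fit_poisson_elasticnet(d, y, n_lambda=10, seed=1)
        return d, y, res

    def test_all_families_equal_full_model(self, fitted):
        d, y, res = fitted
        full = explained_variance(y, res.cv_predict(), mode="overall")
        all_fams = subset_ev(res, y, list(d.families))
        assert all_fams == pytest.approx(full, abs=1e-12)

    def test_empty_family_set_is_intercept_only(self, fitted):
        d, y, res = fitted
        ev = subset_ev(res, y, [])
        assert abs(ev) < 0.02

    def test_unknown_family_rejected(self, fitted):
        _, y, res = fitted
        with pytest.raises(KeyError):
            subset_ev(res, y, ["bogus"])

    def test_visual_family_carries_the_signal(self, fitted):
        d, y, res = fitted
        ev_vis = subset_ev(res, y, ["visual"])
        ev_move = subset_ev(res, y, ["movement"])
        assert ev_vis > ev_move

    def test_per_bin_visual_ev_peaks_early(self, fitted):
        """A purely visual neuron's visual-family prediction explains most
        variance in the early transient window."""
        d, y, res = fitted
        Y = np.asarray(y, dtype=float).reshape(d.n_trials, d.n_bins)
        ev = subset_ev(res, Y, ["visual"], mode="per_bin")
        # signal lives in 0-200 ms (basis span); peak EV bin must be there
        peak_t = d.bin_times[np.nanargmax(ev)]
        assert 0.0 <= peak_t < 0.2
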