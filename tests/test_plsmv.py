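import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movecomp import accel, plsmv, synthdata
from movecomp.plsmv import (McCvPlan, fit_pls, mc_cross_validate, predict,
                            predict_tp, selectivity_profile,
                            selectivity_ratios, target_project)


def signal_data(rng, n=80, p=33, snr=10.0, informative=0):
    """One informative column, the rest independent noise."""
    X = rng.normal(size=(n, p))
    y = snr * X[:, informative] + rng.normal(size=n)
    return X, y


def one_component_data(rng, n=60, p=33, noise=0.1):
    """Near-rank-1 predictor block sharing a single latent factor with y."""
    t = rng.normal(size=n)
    load = rng.uniform(0.5, 1.5, size=p)
    X = np.outer(t, load) + noise * rng.normal(size=(n, p))
    y = 2.0 * t + noise * rng.normal(size=n)
    return X, y


class TestFitPls:
    def test_weight_concentrates_on_informative_column(self, rng):
        X, y = signal_data(rng, n=400)
        model = fit_pls(X, y, 1)
        w = np.abs(model.weights[:, 0])
        assert w[0] / np.sort(w[1:])[-1] > 5.0

    def test_duplicate_columns_share_weights(self, rng):
        X, y = signal_data(rng)
        X[:, 5] = X[:, 0]
        model = fit_pls(X, y, 2)
        np.testing.assert_allclose(model.weights[5], model.weights[0], atol=1e-10)
        np.testing.assert_allclose(model.coef[5], model.coef[0], atol=1e-10)

    def test_orthogonal_response_near_zero_explained(self, rng):
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        # project out every predictor direction: y orthogonal to X by construction
        Xc = X - X.mean(axis=0)
        y = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        y = y + 1e-6 * rng.normal(size=50)  # keep the weight vector defined
        model = fit_pls(X, y, 1)
        assert model.explained_y_variance < 1e-6

    def test_scores_orthogonal(self, rng):
        X, y = signal_data(rng)
        model = fit_pls(X, y, 3)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_explained_variance_nondecreasing(self, rng):
        X, y = signal_data(rng)
        ev = [fit_pls(X, y, k).explained_y_variance for k in (1, 2, 3, 4)]
        assert np.all(np.diff(ev) >= -1e-12)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        with pytest.raises(ValueError):
            fit_pls(X, y, 4)

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = signal_data(rng, n=60)
        for k in (1, 2, 3):
            ours = predict(fit_pls(X, y, k), X)
            ref = sklearn.PLSRegression(n_components=k, scale=True).fit(X, y)
            np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-6)


class TestTargetProjection:
    def test_single_component_collapse(self, rng):
        X, y = signal_data(rng)
        model = fit_pls(X, y, 1)
        tp = target_project(model, X)
        t1 = model.scores[:, 0]
        sign = np.sign(t1 @ tp.scores)
        np.testing.assert_allclose(tp.scores * sign, t1, atol=1e-8)

    def test_predictions_match_full_model(self, rng):
        for k in (1, 2, 3):
            X, y = signal_data(rng, n=70)
            model = fit_pls(X, y, k)
            tp = target_project(model, X)
            np.testing.assert_allclose(predict_tp(model, tp), predict(model, X),
                                       atol=1e-8)

    def test_orthonormal_single_predictor_unit_loading(self, rng):
        # orthonormal X with y along one column: TP loadings form a unit vector
        q, _ = np.linalg.qr(rng.normal(size=(60, 8)))
        X = q * np.sqrt(59)  # unit variance columns, mutually orthogonal
        y = X[:, 2].copy()
        model = fit_pls(X, y, 1, scale=False)
        tp = target_project(model, X)
        expected = np.zeros(8)
        expected[2] = 1.0
        # centering perturbs the orthogonality of the QR columns slightly
        np.testing.assert_allclose(np.abs(tp.x_loadings), expected, atol=0.1)
        assert abs(tp.x_loadings[2]) > 0.98

    def test_zero_coef_rejected(self, rng):
        X, y = signal_data(rng)
        model = fit_pls(X, y, 1)
        model.coef = np.zeros_like(model.coef)
        with pytest.raises(ValueError):
            target_project(model, X)


class TestSelectivityRatios:
    def test_collinear_band_attains_bound(self, rng):
        t = rng.normal(size=60)
        X = np.column_stack([t, -t, rng.normal(size=(60, 4))])
        y = t + 0.01 * rng.normal(size=60)
        model = fit_pls(X, y, 1)
        sr = selectivity_ratios(target_project(model, X), X, model)
        assert sr[0] == pytest.approx(1.0, abs=0.05)
        assert sr[1] == pytest.approx(-1.0, abs=0.05)
        assert sr[0] == -sr[1]

    def test_orthogonal_band_near_zero(self, rng):
        X, y = signal_data(rng, n=500)
        model = fit_pls(X, y, 1)
        sr = selectivity_ratios(target_project(model, X), X, model)
        assert np.abs(sr[1:]).max() < 0.1

    def test_zero_variance_band_missing(self, rng):
        X, y = signal_data(rng)
        X[:, 7] = 3.0
        model = fit_pls(X, y, 1)
        sr = selectivity_ratios(target_project(model, X), X, model)
        assert np.isnan(sr[7])
        assert np.nanmax(np.abs(sr)) <= 1.0 + 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_bounds_hold_universally(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(10, 40), rng.integers(2, 12)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        try:
            model = fit_pls(X, y, min(3, p))
        except ValueError:
            return
        sr = selectivity_ratios(target_project(model, X), X, model)
        assert np.nanmax(np.abs(sr)) <= 1.0 + 1e-9

    def test_explained_le_total_variance(self, rng):
        X, y = signal_data(rng)
        model = fit_pls(X, y, 2)
        tp = target_project(model, X)
        Xc = (X - model.x_mean) / model.x_scale
        v_exp = np.outer(tp.scores, tp.x_loadings).var(axis=0, ddof=1)
        v_tot = Xc.var(axis=0, ddof=1)
        assert (v_exp <= v_tot + 1e-9).all()

    def test_planted_sign_pattern(self, rng):
        # negative effect at low bands, positive at high bands
        n = 200
        X = np.abs(rng.normal(size=(n, 33))) + 0.1
        beta = np.zeros(33)
        beta[1] = -1.0
        beta[14] = 1.0
        y = X @ beta + 0.1 * rng.normal(size=n)
        model = fit_pls(X, y, 2)
        sr = selectivity_ratios(target_project(model, X), X, model)
        assert sr[1] < -0.3
        assert sr[14] > 0.3
        assert np.max(np.abs(np.delete(sr, [1, 14]))) < 0.1


class TestMcCrossValidate:
    def test_pure_noise_no_model(self, rng):
        X = rng.normal(size=(60, 33))
        y = rng.normal(size=60)
        cv = mc_cross_validate(X, y, McCvPlan(n_repetitions=100, seed=5), k_max=3)
        assert cv.selected_k == 0
        assert not cv.has_model

    def test_strong_signal_selects_one_component(self, rng):
        X, y = one_component_data(rng, n=60)
        cv = mc_cross_validate(X, y, McCvPlan(n_repetitions=100, seed=5), k_max=3)
        assert cv.selected_k == 1

    def test_single_repetition_warns_but_runs(self, rng):
        X, y = signal_data(rng, n=30)
        with pytest.warns(UserWarning, match="repetitions"):
            cv = mc_cross_validate(X, y, McCvPlan(n_repetitions=1, seed=0), k_max=2)
        assert cv.errors.shape == (1, 3)

    def test_seeded_bit_reproducible(self, rng):
        X, y = signal_data(rng, n=40)
        plan = McCvPlan(n_repetitions=50, seed=123)
        a = mc_cross_validate(X, y, plan, k_max=3)
        b = mc_cross_validate(X, y, plan, k_max=3)
        assert (a.errors == b.errors).all()
        assert a.selected_k == b.selected_k

    def test_too_small_sample_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            mc_cross_validate(X, rng.normal(size=5), McCvPlan(n_repetitions=10), 2)

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            McCvPlan(holdout_fraction=1.5)
        with pytest.raises(ValueError):
            McCvPlan(n_repetitions=0)


class TestSelectivityProfile:
    def test_ci_contains_point_estimate_mostly(self, rng):
        X, y = signal_data(rng, n=100, snr=5.0)
        prof = selectivity_profile(X, y, 1, plan=McCvPlan(n_repetitions=50, seed=3))
        ok = (prof.ci_low <= prof.sr) & (prof.sr <= prof.ci_high)
        assert ok.mean() > 0.8
        assert np.nanmax(np.abs(prof.sr)) <= 1.0

    def test_frame_schema(self, rng):
        X, y = signal_data(rng, n=50)
        frame = selectivity_profile(X, y, 1).to_frame()
        assert list(frame.columns) == ["band", "band_low_mg", "band_high_mg",
                                       "sr", "ci_low", "ci_high"]
        assert len(frame) == accel.N_BANDS


class TestAnalyzeSpectrum:
    def test_planted_spectrum_effect_recovered(self):
        # outcome loads negatively on low bands, positively on mid bands
        cfg = synthdata.GeneratorConfig(n_participants=120, seed=44,
                                        outcome_noise_sd=0.0)
        df = synthdata.cohort_to_frame(synthdata.generate_cohort(cfg))
        X = df[accel.band_labels()].to_numpy()
        rng = np.random.default_rng(0)
        df["gmv_right_hippocampus"] = (3500.0 - 2.0 * X[:, 1] + 8.0 * X[:, 14]
                                       + rng.normal(0, 5.0, len(df)))
        plan = McCvPlan(n_repetitions=100, seed=9)
        cv, prof = plsmv.analyze_spectrum(df, "right_hippocampus", plan=plan)
        assert cv.has_model
        assert prof is not None
        assert prof.sr[1] < 0 < prof.sr[14]

    def test_null_spectrum_no_model(self, cohort_df):
        plan = McCvPlan(n_repetitions=100, seed=2)
        cv, prof = plsmv.analyze_spectrum(cohort_df, "right_hippocampus", plan=plan)
        assert prof is None or cv.selected_k <= 1


def test_residualize_removes_covariate_signal(rng):
    C = rng.normal(size=(100, 3))
    y = C @ np.array([2.0, -1.0, 0.5]) + rng.normal(size=100)
    resid = plsmv.residualize(y, C)
    Cc = np.column_stack([np.ones(100), C])
    np.testing.assert_allclose(Cc.T @ resid, 0.0, atol=1e-8)
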