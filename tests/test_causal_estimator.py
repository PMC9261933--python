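import numpy as np
import pandas as pd
import pytest

from latentpls.causal_estimator import (EstimatorConfig, RawOutcome,
                                        bootstrap_ci, estimate_lce,
                                        estimate_lce_arrays,
                                        fit_outcome_regression,
                                        infer_latent_treatment, pca_baseline)
from latentpls.data_prep import standardize
from latentpls.outcome_prep import OutcomeSpec
from latentpls.synthetic_data import SimulationConfig, simulate_dataset


def strong_signal(n=500, seed=0, **kw):
    return simulate_dataset(SimulationConfig(n=n, seed=seed, **kw))


def std(mat, **kw):
    return standardize(mat, **kw).values


class TestInferLatentTreatment:
    def test_recovers_latent_on_strong_signal(self):
        ds = strong_signal(n=2000, seed=3)
        scores = infer_latent_treatment(std(ds.U), std(ds.X), 1)
        xg = ds.X @ ds.config.resolved().gamma
        assert abs(np.corrcoef(scores.z_hat, xg)[0, 1]) > 0.99
        assert abs(scores.z_hat.mean()) < 1e-10
        assert abs(scores.z_hat.var(ddof=1) - 1.0) < 1e-10

    def test_single_confounder_score_is_that_confounder(self, rng):
        x = rng.standard_normal((50, 1))
        u = x @ rng.standard_normal((1, 5)) + 0.1 * rng.standard_normal((50, 5))
        scores = infer_latent_treatment(std(u), std(x), 1)
        xs = std(x)[:, 0]
        assert min(np.abs(scores.z_hat - xs).max(),
                   np.abs(scores.z_hat + xs).max()) < 1e-8

    def test_deterministic_given_inputs(self):
        ds = strong_signal(seed=5)
        a = infer_latent_treatment(std(ds.U), std(ds.X), 1)
        b = infer_latent_treatment(std(ds.U), std(ds.X), 1)
        assert np.array_equal(a.z_hat, b.z_hat)


class TestOutcomeRegression:
    def test_constant_response_gives_exactly_zero_slope(self, rng):
        z = rng.standard_normal(20)
        fit = fit_outcome_regression(np.full(20, 3.7), z)
        assert fit.slope == 0.0

    def test_exact_linear_case(self, rng):
        z = rng.standard_normal(20)
        fit = fit_outcome_regression(2.0 * z, z)
        assert abs(fit.slope - 2.0) < 1e-12
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_simple_regression(self, rng):
        y, z = rng.standard_normal(40), rng.standard_normal(40)
        fit = fit_outcome_regression(y, z)
        expected = np.cov(y, z, ddof=1)[0, 1] / np.var(z, ddof=1)
        assert abs(fit.slope - expected) < 1e-12
        assert abs(fit.intercept - (y.mean() - expected * z.mean())) < 1e-12

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_outcome_regression([1.0, 2.0], [0.0, 1.0])


class TestEstimateLCEArrays:
    def test_matches_oracle_on_strong_signal(self):
        from latentpls.synthetic_data import oracle_slope

        ds = strong_signal(n=2000, seed=17)
        est = estimate_lce_arrays(ds.U, ds.X, ds.raw_outcome(),
                                  EstimatorConfig(seed=1, n_boot=50))
        oracle = oracle_slope(ds)
        # sampling sd of the estimate ~ sd(Z)/sqrt(2n); allow 3 of them
        mc_se = np.sqrt(ds.Z_true.var() / (2 * 2000))
        assert abs(est.lce - oracle) < 3 * mc_se + 0.05

    def test_permuted_outcome_is_null(self):
        ds = strong_signal(n=200, seed=23)
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(100):
            y_perm = rng.permutation(ds.y)
            out = RawOutcome(kind="continuous", values=y_perm)
            U_std = std(ds.U)
            X_std = std(ds.X, on_constant="error")
            scores = infer_latent_treatment(U_std, X_std, 1)
            estimates.append(fit_outcome_regression(y_perm, scores).slope)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / 10.0
        assert abs(estimates.mean()) < 3 * se

    def test_constant_outcome_degenerates_to_zero(self):
        ds = strong_signal(n=100, seed=2)
        out = RawOutcome(kind="continuous", values=np.ones(100))
        est = estimate_lce_arrays(ds.U, ds.X, out,
                                  EstimatorConfig(seed=3, n_boot=60))
        assert est.lce == 0.0
        assert (est.ci_lower, est.ci_upper) == (0.0, 0.0)

    def test_same_seed_reproduces_interval(self):
        ds = strong_signal(n=150, seed=4)
        cfg = EstimatorConfig(seed=11, n_boot=80)
        a = estimate_lce_arrays(ds.U, ds.X, ds.raw_outcome(), cfg)
        b = estimate_lce_arrays(ds.U, ds.X, ds.raw_outcome(), cfg)
        assert (a.lce, a.ci_lower, a.ci_upper) == (b.lce, b.ci_lower, b.ci_upper)
        assert np.array_equal(a.boot_replicates, b.boot_replicates)

    def test_feature_scale_equivariance(self):
        ds = strong_signal(n=120, seed=6)
        cfg = EstimatorConfig(seed=7, n_boot=60)
        base = estimate_lce_arrays(ds.U, ds.X, ds.raw_outcome(), cfg)
        scales = np.random.default_rng(0).uniform(0.1, 50.0, size=ds.U.shape[1])
        scaled = estimate_lce_arrays(ds.U * scales, ds.X, ds.raw_outcome(), cfg)
        assert abs(base.lce - scaled.lce) < 1e-10
        assert abs(base.ci_lower - scaled.ci_lower) < 1e-10

    def test_feature_sign_flip_preserves_magnitude_and_width(self):
        ds = strong_signal(n=120, seed=8)
        cfg = EstimatorConfig(seed=9, n_boot=60)
        base = estimate_lce_arrays(ds.U, ds.X, ds.raw_outcome(), cfg)
        flipped = estimate_lce_arrays(-ds.U, ds.X, ds.raw_outcome(), cfg)
        assert abs(abs(base.lce) - abs(flipped.lce)) < 1e-10
        assert abs((base.ci_upper - base.ci_lower)
                   - (flipped.ci_upper - flipped.ci_lower)) < 1e-10

    def test_interval_width_shrinks_with_n(self):
        widths = {}
        for n in (200, 800):
            reps = []
            for seed in range(8):
                ds = strong_signal(n=n, seed=100 + seed)
                est = estimate_lce_arrays(ds.U, ds.X, ds.raw_outcome(),
                                          EstimatorConfig(seed=seed, n_boot=100))
                reps.append(est.ci_upper - est.ci_lower)
            widths[n] = np.median(reps)
        assert widths[800] < widths[200]

    def test_multi_component_reports_per_component_slopes(self):
        ds = strong_signal(n=200, seed=12)
        est = estimate_lce_arrays(ds.U, ds.X, ds.raw_outcome(),
                                  EstimatorConfig(seed=1, n_boot=50, l=2))
        assert len(est.per_component_lce) == 2
        assert est.per_component_lce[0] == est.lce


class TestBootstrapCI:
    def test_small_n_boot_warns(self):
        calls = []

        def fit_once(idx):
            return float(idx.sum() % 7), np.array([1.0])

        with pytest.warns(UserWarning, match="n_boot < 50"):
            bootstrap_ci(fit_once, n=30, n_boot=10, ci_level=0.9, seed=0,
                         orientation_anchor=np.array([1.0]))

    def test_excess_failures_error(self):
        def fit_once(idx):
            raise ValueError("degenerate")

        with pytest.raises(RuntimeError, match="replicates failed"):
            bootstrap_ci(fit_once, n=30, n_boot=60, ci_level=0.95, seed=0,
                         orientation_anchor=np.array([1.0]))

    def test_sign_alignment_of_flipped_replicates(self):
        rng = np.random.default_rng(0)

        def fit_once(idx):
            sign = -1.0 if rng.uniform() < 0.5 else 1.0
            return sign * 2.0, np.array([sign])

        res = bootstrap_ci(fit_once, n=10, n_boot=100, ci_level=0.95, seed=1,
                           orientation_anchor=np.array([1.0]))
        assert np.all(res.replicates == 2.0)


class TestEstimateLCETables:
    def test_end_to_end_on_fixture(self, fixture_dir):
        from latentpls.data_prep import read_clinical_table, read_feature_table

        paths = fixture_dir["tiny"]
        features = read_feature_table(paths["features"])
        clinical = read_clinical_table(paths["clinical"])
        spec = OutcomeSpec(kind="continuous", value_column="y")
        est = estimate_lce(features, clinical, paths["schema"], spec,
                           EstimatorConfig(seed=42, n_boot=100))
        assert est.n_used == 40
        assert est.dropped_subjects == 0
        assert len(est.boot_replicates) + est.n_boot_failed == 100
        assert est.z_hat.shape == (40,)
        assert est.outcome_kind == "continuous"

    def test_survival_pipeline_runs_and_recomputes_residuals(self, fixture_dir):
        from latentpls.data_prep import read_clinical_table, read_feature_table

        paths = fixture_dir["survival"]
        features = read_feature_table(paths["features"])
        clinical = read_clinical_table(paths["clinical"])
        spec = OutcomeSpec(kind="survival", time_column="time",
                           event_column="event")
        est = estimate_lce(features, clinical, paths["schema"], spec,
                           EstimatorConfig(seed=7, n_boot=100))
        assert est.outcome_kind == "survival"
        assert np.isfinite(est.lce)
        assert est.ci_lower <= est.lce <= est.ci_upper

    def test_missing_confounder_drops_subject(self, fixture_dir):
        from latentpls.data_prep import read_clinical_table, read_feature_table

        paths = fixture_dir["tiny"]
        features = read_feature_table(paths["features"])
        clinical = read_clinical_table(paths["clinical"])
        clinical.loc[clinical.index[0], "sex"] = np.nan
        spec = OutcomeSpec(kind="continuous", value_column="y")
        est = estimate_lce(features, clinical, paths["schema"], spec,
                           EstimatorConfig(seed=1, n_boot=50))
        assert est.n_used == 39
        assert est.dropped_subjects == 1


class TestPCABaseline:
    def test_rank_one_features_recover_single_direction(self, rng):
        z = rng.standard_normal(30)
        direction = rng.standard_normal(4)
        U = np.outer(z, direction)
        U_std = standardize(U).values
        y = z + 0.1 * rng.standard_normal(30)
        conf = rng.standard_normal((30, 1))
        fit = pca_baseline(U_std, conf, y)
        zs = (z - z.mean()) / z.std(ddof=1)
        scale = np.linalg.norm(fit.pc1_scores) / np.linalg.norm(zs)
        assert min(np.abs(fit.pc1_scores - scale * zs).max(),
                   np.abs(fit.pc1_scores + scale * zs).max()) < 1e-8

    def test_pc1_matches_svd(self, rng):
        U_std = standardize(rng.standard_normal((20, 5))).values
        fit = pca_baseline(U_std, rng.standard_normal((20, 2)),
                           rng.standard_normal(20))
        _, _, vt = np.linalg.svd(U_std, full_matrices=False)
        ref = U_std @ vt[0]
        assert min(np.abs(fit.pc1_scores - ref).max(),
                   np.abs(fit.pc1_scores + ref).max()) < 1e-10

    def test_coefficients_match_direct_solve(self, rng):
        U_std = standardize(rng.standard_normal((40, 6))).values
        C = rng.standard_normal((40, 2))
        y = rng.standard_normal(40)
        fit = pca_baseline(U_std, C, y)
        design = np.column_stack([np.ones(40), fit.pc1_scores, C])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        got = np.concatenate([[fit.intercept, fit.pc1_coefficient],
                              fit.confounder_coefficients])
        assert np.abs(got - beta).max() < 1e-10
        # conventional OLS standard errors
        resid = y - design @ beta
        sigma2 = resid @ resid / (40 - design.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))
        assert np.abs(fit.standard_errors - se).max() < 1e-8

    def test_rank_deficient_design_errors(self, rng):
        U_std = standardize(rng.standard_normal((20, 3))).values
        C = np.ones((20, 2))  # duplicate constant columns collide with intercept
        with pytest.raises(ValueError, match="rank"):
            pca_baseline(U_std, C, rng.standard_normal(20))
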