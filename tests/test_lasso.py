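import numpy as np
import pandas as pd
import pytest

from phosresp import (
    cv_select_lambda,
    default_lambda_grid,
    lambda_max,
    lasso_fit,
    loclo_run,
    pool_descriptive_model,
    train_average_model,
)
from phosresp.lasso import AveragedModel
from phosresp.preprocess import NormalizedMatrix


def lasso_objective(x, y, beta0, coef, lam):
    resid = y - beta0 - x @ np.atleast_1d(coef)
    return (resid**2).sum() / (2 * len(y)) + lam * np.abs(coef).sum()


def brute_force_lasso(x, y, lam, span=5.0, rounds=4, points=41):
    """Grid-refinement minimizer of the lasso objective for p <= 2.

    The unpenalized intercept is profiled out exactly: for any coefficient
    vector B, the optimal beta0 is mean(y - XB). Independent of any
    coordinate-descent solver.
    """
    p = x.shape[1]
    center = np.zeros(p)
    width = span
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)
        b0 = (y[:, None] - x @ cand.T).mean(axis=0)
        resid = y[:, None] - b0[None, :] - x @ cand.T
        obj = (resid**2).sum(axis=0) / (2 * len(y)) + lam * np.abs(cand).sum(axis=1)
        center = cand[np.argmin(obj)]
        width = 2 * width / (points - 1)
    return float((y - x @ center).mean()), center


class TestLassoFit:
    def test_lambda_max_gives_null_model_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 4))
        x = (x - x.mean(0)) / x.std(0)
        y = rng.normal(size=10)
        lam = lambda_max(x, y)
        model = lasso_fit(x, y, lam * 1.0001)
        np.testing.assert_array_equal(model.coef, 0.0)
        assert model.beta0 == pytest.approx(y.mean(), abs=1e-12)

    def test_ols_limit_single_predictor(self):
        # x standardized, n=2: lam=0 -> beta = 1, beta0 = 2 (plain OLS)
        x = np.array([[1.0], [-1.0]])
        y = np.array([3.0, 1.0])
        model = lasso_fit(x, y, 0.0)
        assert model.coef[0] == pytest.approx(1.0, abs=1e-10)
        assert model.beta0 == pytest.approx(2.0, abs=1e-10)

    def test_soft_threshold_example(self):
        # same x, y with lam = 0.4: beta = S(1, 0.4) = 0.6
        x = np.array([[1.0], [-1.0]])
        y = np.array([3.0, 1.0])
        model = lasso_fit(x, y, 0.4)
        assert model.coef[0] == pytest.approx(0.6, abs=1e-6)
        assert model.beta0 == pytest.approx(2.0, abs=1e-9)
        b0_ref, coef_ref = brute_force_lasso(x, y, 0.4)
        assert model.coef[0] == pytest.approx(coef_ref[0], abs=1e-3)

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_brute_force_grid(self, p):
        rng = np.random.default_rng(42 + p)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            x = rng.normal(size=(n, p))
            x = (x - x.mean(0)) / x.std(0)
            y = rng.normal(size=n) * 2
            lam = float(rng.uniform(0.01, 1.0)) * lambda_max(x, y)
            model = lasso_fit(x, y, lam)
            _, coef_ref = brute_force_lasso(x, y, lam)
            np.testing.assert_allclose(model.coef, coef_ref, atol=1e-3)

    def test_objective_never_worse_than_null_model(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 6))
        x = (x - x.mean(0)) / x.std(0)
        y = rng.normal(size=15)
        for lam in [0.0, 0.01, 0.1, 1.0]:
            m = lasso_fit(x, y, lam)
            assert lasso_objective(x, y, m.beta0, m.coef, lam) <= (
                lasso_objective(x, y, y.mean(), np.zeros(6), lam) + 1e-12
            )

    def test_l1_norm_monotone_in_lambda(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 10))
        x = (x - x.mean(0)) / x.std(0)
        y = x[:, 0] * 2 + rng.normal(size=20)
        norms = [np.abs(lasso_fit(x, y, lam).coef).sum()
                 for lam in default_lambda_grid(x, y, n_points=25)]
        # grid is descending in lambda, so L1 norms must be non-decreasing
        assert all(b >= a - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_sparsity_monotone_on_orthogonal_design(self):
        n = 16
        x = np.kron(np.eye(4), np.ones((4, 1)))  # orthogonal blocks
        x = (x - x.mean(0)) / x.std(0)
        rng = np.random.default_rng(9)
        y = x @ np.array([3.0, -2.0, 1.0, 0.5]) + rng.normal(scale=0.1, size=n)
        nnz = [int((lasso_fit(x, y, lam).coef != 0).sum())
               for lam in default_lambda_grid(x, y, n_points=30)]
        assert all(b >= a for a, b in zip(nnz, nnz[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lasso_fit(np.array([[np.inf]]), np.array([1.0]), 0.1)


class TestCvAndAveraging:
    def test_single_value_grid_returned(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        assert cv_select_lambda(x, y, grid=np.array([0.37]), seed=0) == 0.37

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            cv_select_lambda(np.ones((2, 1)), np.ones(2), k_folds=3)

    def test_single_iteration_equals_single_fit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 8))
        x = (x - x.mean(0)) / x.std(0)
        y = x[:, 0] + rng.normal(scale=0.1, size=12)
        avg = train_average_model(x, y, n_iterations=1, seed=3)
        assert set(np.unique(avg.nonnull_frequency)) <= {0.0, 1.0}
        lam_grid = default_lambda_grid(x, y)
        rng2 = np.random.default_rng(3)
        lam = cv_select_lambda(x, y, grid=lam_grid, seed=int(rng2.integers(2**31)))
        single = lasso_fit(x, y, lam)
        np.testing.assert_allclose(avg.coef, single.coef, atol=1e-3)

    def test_dominant_predictor_kept(self):
        rng = np.random.default_rng(4)
        kept = 0
        for seed in range(10):
            x = rng.normal(size=(18, 30))
            x = (x - x.mean(0)) / x.std(0)
            y = 3 * x[:, 5] + rng.normal(scale=0.5, size=18)
            avg = train_average_model(x, y, n_iterations=5, seed=seed)
            kept += avg.nonnull_frequency[5] > 0.5
        assert kept >= 9

    def test_pure_noise_stays_sparse(self):
        rng = np.random.default_rng(5)
        counts = []
        for seed in range(10):
            x = rng.normal(size=(18, 100))
            x = (x - x.mean(0)) / x.std(0)
            y = rng.normal(size=18)
            lam = cv_select_lambda(x, y, seed=seed)
            counts.append(int((lasso_fit(x, y, lam).coef != 0).sum()))
        assert np.median(counts) < 10  # < p/10


class TestPooling:
    def _model(self, coef, freq, left_out="c"):
        return AveragedModel(beta0=0.0, coef=np.asarray(coef, float),
                             nonnull_frequency=np.asarray(freq, float),
                             n_iterations=20, drug="d", left_out=left_out)

    def test_identical_models_pool_to_themselves(self):
        m = self._model([1.0, 0.0], [1.0, 0.0])
        pooled = pool_descriptive_model([m] * 7, ["a", "b"])
        assert list(pooled.table.index) == ["a"]
        assert pooled.table["mean_coefficient"].iloc[0] == 1.0
        assert pooled.table["mean_frequency"].iloc[0] == 1.0

    def test_single_fold_frequency_dilutes(self):
        models = [self._model([0.0], [0.0]) for _ in range(6)]
        models.append(self._model([0.7], [0.7]))
        pooled = pool_descriptive_model(models, ["a"])
        assert pooled.table["mean_frequency"].iloc[0] == pytest.approx(0.1)
        assert not pooled.table["excerpt"].iloc[0]

    def test_everywhere_null_excluded(self):
        models = [self._model([0.0, 2.0], [0.0, 1.0]) for _ in range(7)]
        pooled = pool_descriptive_model(models, ["a", "b"])
        assert list(pooled.table.index) == ["b"]
        assert pooled.excerpt.index.tolist() == ["b"]

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="regressor"):
            pool_descriptive_model([self._model([1.0], [1.0])], ["a", "b"])


class TestLoclo:
    def test_models_exclude_left_out_line(self, small_drug):
        _, ds, normm = small_drug
        drug = ds.truth.marker_drug
        res = loclo_run(normm, ds.meta, ds.viability, drug, seed=0, n_iterations=2)
        assert len(res.models) == 7
        lines = sorted(res.models)
        # each fold trains on (7 - 1) * 3 = 18 samples
        n_samples = len(normm.sample_ids)
        assert n_samples - len(ds.meta.samples_of_line(lines[0])) == 18
        # altering the left-out line's intensities must not change its model
        victim = lines[0]
        df = normm.data.copy()
        cols = ds.meta.samples_of_line(victim)
        df[cols] = df[cols].values * 3.7
        res2 = loclo_run(
            NormalizedMatrix(df, normm.provenance), ds.meta, ds.viability, drug,
            seed=0, n_iterations=2,
        )
        np.testing.assert_array_equal(res.models[victim].coef, res2.models[victim].coef)

    def test_planted_markers_drive_good_predictions(self, small_drug):
        _, ds, normm = small_drug
        res = loclo_run(normm, ds.meta, ds.viability, ds.truth.marker_drug,
                        seed=1, n_iterations=5)
        assert res.pearson_r > 0.8
        assert res.p_value < 1e-4
        assert len(res.predictions) == 21
        # observed scores are z-normalized drug-wise
        assert res.predictions["observed"].mean() == pytest.approx(0.0, abs=1e-12)
        assert res.predictions["observed"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_paper_mode_standardizes_over_all_samples(self, small_drug):
        _, ds, normm = small_drug
        res = loclo_run(normm, ds.meta, ds.viability, ds.truth.marker_drug,
                        seed=1, n_iterations=2, paper_mode=True)
        assert np.isfinite(res.pearson_r)

    def test_missing_viability_rejected(self, small_drug):
        _, ds, normm = small_drug
        viab = ds.viability.data
        truncated = viab[viab.cell_line != "AML1"]
        from phosresp import ViabilityTable
        with pytest.raises(ValueError, match="AML1"):
            loclo_run(normm, ds.meta, ViabilityTable(truncated),
                      ds.truth.marker_drug, n_iterations=1)

    def test_degenerate_predictions_flagged(self):
        # constant y: every model is null, predictions constant, R undefined
        rng = np.random.default_rng(6)
        from phosresp import SampleMeta, ViabilityTable
        rows, cols = [], []
        for li in range(4):
            for r in range(2):
                rows.append({"sample_id": f"L{li}_r{r}", "cell_line": f"L{li}",
                             "disease": "AML", "replicate": r})
                cols.append(f"L{li}_r{r}")
        meta = SampleMeta(pd.DataFrame(rows).set_index("sample_id"))
        viab = ViabilityTable(pd.DataFrame(
            {"cell_line": [f"L{i}" for i in range(4)], "drug": "d",
             "viability_percent": [50.0] * 4}))
        normm = NormalizedMatrix(
            pd.DataFrame(rng.lognormal(size=(30, 8)),
                         index=[f"p{i}" for i in range(30)], columns=cols))
        res = loclo_run(normm, meta, viab, "d", n_iterations=1, k_folds=2)
        assert res.degenerate and np.isnan(res.pearson_r)
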