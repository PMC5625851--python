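"""NIPALS PLS1: oracle equivalences, CV selection, metrics, study driver."""

import numpy as np
import pandas as pd
import pytest

import grainspec as gs
from grainspec.pls import (PLSCalibration, evaluate, nipals_pls1,
                           predict_scores, r2_from_rmse, run_study,
                           select_ncomp, split_by_grain)
from grainspec.pretreat import PretreatmentSpec


def random_problem(seed, n=30, b=8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, b))
    beta = rng.normal(size=b)
    y = X @ beta + rng.normal(0, 0.1, n)
    return X, y


class TestSplitByGrain:
    def test_orientations_stay_together(self):
        grains = np.repeat(np.arange(10), 2)
        plan = split_by_grain(grains, 0.8, seed=0)
        assert plan.calibration_grains.size == 8
        cal, val = plan.masks(grains)
        # both spectra of a grain land on the same side
        for g in range(10):
            sel = cal[grains == g]
            assert sel.all() or not sel.any()

    def test_deterministic_per_seed(self):
        grains = np.arange(50)
        p1 = split_by_grain(grains, 0.8, seed=7)
        p2 = split_by_grain(grains, 0.8, seed=7)
        np.testing.assert_array_equal(p1.calibration_grains,
                                      p2.calibration_grains)

    def test_fraction_one_warns_empty_validation(self):
        with pytest.warns(UserWarning, match="empty"):
            split_by_grain(np.arange(10), 1.0, seed=0)

    def test_too_few_grains_rejected(self):
        with pytest.raises(ValueError, match="5"):
            split_by_grain(np.arange(4), 0.8, seed=0)


class TestNipals:
    def test_single_band_equals_simple_regression(self):
        """Closed-form oracle: with one predictor, PLS is the least-squares
        line slope cov(x,y)/var(x)."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 2.5 * x + 1 + rng.normal(0, 0.2, 40)
        model = nipals_pls1(x[:, None], y, 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model["beta"][0] == pytest.approx(slope, abs=1e-10)
        assert model["beta0"] == pytest.approx(y.mean() - slope * x.mean(),
                                               abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_ols(self, seed):
        """Normal-equations oracle: at full component count on tall full-rank
        data, PLS predictions equal ordinary least squares."""
        X, y = random_problem(seed)
        model = nipals_pls1(X, y, X.shape[1])
        pred = X @ model["beta"] + model["beta0"]
        Xd = np.column_stack([np.ones(len(X)), X])
        coef = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(pred, Xd @ coef, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_beta_form_equals_score_form(self, seed):
        X, y = random_problem(seed)
        for a in (1, 3, X.shape[1]):
            model = nipals_pls1(X, y, a)
            beta_pred = X @ model["beta"] + model["beta0"]
            np.testing.assert_allclose(predict_scores(model, X), beta_pred,
                                       atol=1e-8)

    def test_constant_response_predicts_mean(self):
        X = np.random.default_rng(1).normal(size=(20, 5))
        y = np.full(20, 7.0)
        model = nipals_pls1(X, y, 3, allow_truncation=True)
        np.testing.assert_allclose(model["beta"], 0, atol=1e-12)
        np.testing.assert_allclose(X @ model["beta"] + model["beta0"], 7.0)

    def test_degenerate_deflation_raises_without_truncation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X[:, 2] = X[:, 0] + X[:, 1]   # rank 2: third component must degenerate
        y = X @ np.array([1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="component"):
            nipals_pls1(X, y, 3)

    def test_cross_check_against_sklearn(self):
        """Independent implementation cross-check at reduced rank."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(11, n=50, b=12)
        for a in (2, 5):
            ours = nipals_pls1(X, y, a)
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                X @ ours["beta"] + ours["beta0"],
                ref.predict(X).ravel(), atol=1e-6)


class TestSelectNcomp:
    def test_recovers_latent_rank(self):
        """Constructed low-rank oracle: noiseless y from rank-2 X selects
        A* = 2 with essentially zero RMSECV."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(60, 2))
        loadings = rng.normal(size=(2, 12))
        X = scores @ loadings
        y = scores @ np.array([1.5, -2.0])
        a_star, curve = select_ncomp(X, y, max_components=6, folds=5, seed=0)
        assert a_star == 2
        assert curve[1] < 1e-6

    def test_pure_noise_selects_small_a(self):
        rng = np.random.default_rng(100)
        X = rng.normal(size=(60, 15))
        y = rng.normal(size=60)
        a_star, curve = select_ncomp(X, y, max_components=10, folds=5, seed=0)
        assert a_star <= 2

    def test_amax_one(self):
        X, y = random_problem(5)
        a_star, curve = select_ncomp(X, y, max_components=1, folds=5, seed=0)
        assert a_star == 1 and curve.shape == (1,)


class TestEvaluate:
    def test_perfect_prediction(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(ref, ref)
        assert m.slope == pytest.approx(1.0)
        assert m.bias == 0.0 and m.rmse == 0.0 and m.r2 == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        m = evaluate(np.array([1.0, 2.0]), np.array([1.0, 4.0]))
        assert m.bias == pytest.approx(-1.0)
        assert m.rmse == pytest.approx(np.sqrt(2.0))

    def test_published_consistency_of_best_model_row(self):
        """The printed validation R2 of the best protein model (0.790)
        follows from its printed RMSEP (0.944) and the validation SD (2.06)
        through R2 = 1 - (RMSE/SD)^2."""
        assert round(r2_from_rmse(0.944, 2.06), 3) == 0.790

    def test_zero_reference_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            evaluate(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    def test_metric_identities_hold(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(10, 2, 200)
        pred = ref + rng.normal(0, 0.5, 200)
        m = evaluate(pred, ref)
        sd_n = ref.std()  # population sd matches the SS_tot/n convention
        assert m.r2 == pytest.approx(1 - (m.rmse / sd_n) ** 2, abs=1e-12)
        assert m.rpd == pytest.approx(ref.std(ddof=1) / m.rmse, abs=1e-12)


class TestCalibrationModel:
    def test_fit_results_consistency(self, calibration_table):
        _, table, _ = calibration_table
        spec = PretreatmentSpec([{"step": "snv"}])
        res = PLSCalibration(table, "protein", spec).fit(seed=0)
        assert res.n_components >= 1
        # score-form and beta-form agree on the validation set
        val = table.subset(res.val_mask)
        np.testing.assert_allclose(res.predict(val),
                                   res.predict_via_scores(val), atol=1e-8)
        # no grain appears on both sides
        assert not set(res.plan.calibration_grains) & \
            set(res.plan.validation_grains)

    def test_summary_mentions_metrics(self, calibration_table):
        _, table, _ = calibration_table
        res = PLSCalibration(table, "protein").fit(seed=0)
        text = res.summary()
        assert "validation" in text and "RPD" in text

    def test_model_json_round_trip(self, calibration_table):
        _, table, _ = calibration_table
        spec = PretreatmentSpec([{"step": "msc"}])
        res = PLSCalibration(table, "protein", spec).fit(seed=0)
        frozen = gs.PLSCalibrationResults.from_json(res.to_json())
        np.testing.assert_allclose(
            frozen.predict(table.spectra, table.grid),
            res.predict(table), atol=1e-10)

    def test_parameter_recovery_noiseless(self):
        """On noiseless Beer-Lambert mixture spectra the validation error
        collapses with no more components than generating constituents."""
        rng = np.random.default_rng(21)
        grid = gs.WavelengthGrid(np.linspace(980, 2500, 96))
        lib = gs.default_component_library(grid)
        n = 120
        protein = rng.uniform(6.15, 19.77, n)
        moisture = rng.uniform(0.10, 0.14, n)
        p = protein / 100.0
        X = (p[:, None] * lib.curves["protein"]
             + moisture[:, None] * lib.curves["water"]
             + (1 - p - moisture)[:, None] * lib.curves["starch"])
        records = [gs.KernelRecord(kernel_id=i, protein_ref=protein[i])
                   for i in range(n)]
        table = gs.SpectraTable(X, grid, records)
        res = PLSCalibration(table, "protein").fit(n_components=2, seed=0)
        assert res.metrics_val.rmse < 1e-4

    def test_planted_outlier_flagged(self, calibration_table):
        _, table, _ = calibration_table
        corrupted = gs.SpectraTable(table.spectra.copy(), table.grid,
                                    [r for r in table.records])
        import copy
        corrupted.records = [copy.copy(r) for r in table.records]
        res0 = PLSCalibration(corrupted, "protein").fit(seed=0)
        victim = int(np.flatnonzero(res0.cal_mask)[0])
        corrupted.records[victim].protein_ref += 10.0
        res = PLSCalibration(corrupted, "protein").fit(seed=0)
        flags = res.detect_outliers()
        victim_grain = corrupted.records[victim].kernel_id
        assert flags.loc[flags.grain == victim_grain, "flagged"].any()

    def test_clean_set_flag_rate_low(self, calibration_table):
        """On clean synthetic data the default leverage/residual screen
        flags under 2% of calibration samples (raw-spectra model)."""
        _, table, _ = calibration_table
        res = PLSCalibration(table, "protein").fit(seed=1)
        flags = res.detect_outliers()
        assert flags["flagged"].mean() < 0.02

    def test_infinite_thresholds_flag_nothing(self, calibration_table):
        _, table, _ = calibration_table
        res = PLSCalibration(table, "protein").fit(seed=0)
        flags = res.detect_outliers(leverage_k=np.inf, resid_k=np.inf)
        assert not flags["flagged"].any()


class TestRunStudy:
    def test_results_grid_columns_and_blocking(self, calibration_table):
        _, table, _ = calibration_table
        grid_df, fits = run_study(table, "protein", seed=0)
        assert list(grid_df.columns[:10]) == [
            "pretreatment", "slope_cal", "bias_cal", "rmsec", "r2_cal",
            "slope_val", "bias_val", "rmsep", "r2_val", "pc"]
        for res in fits.values():
            assert not set(res.plan.calibration_grains) & \
                set(res.plan.validation_grains)

    def test_empty_subset_rejected(self, calibration_table):
        _, table, _ = calibration_table
        with pytest.raises(ValueError, match="subset"):
            run_study(table, "protein", subset={"orientation": "sideways"},
                      seed=0)

    def test_orientation_subsets_equivalent(self, calibration_table):
        """Kernel orientation does not change model quality: crease-up and
        crease-down validation R2 differ by < 0.05."""
        _, table, _ = calibration_table
        specs = [PretreatmentSpec([{"step": "snv"}], name="snv")]
        r2 = {}
        for o in ("crease_up", "crease_down"):
            df, _ = run_study(table, "protein", specs=specs,
                              subset={"orientation": o}, seed=0)
            r2[o] = df["r2_val"].iloc[0]
        assert abs(r2["crease_up"] - r2["crease_down"]) < 0.05
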