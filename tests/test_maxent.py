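"""Feature expansion, penalized fitting, prediction, and serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import spearmanr

from hsm.features import FeatureSet
from hsm.maxent import Maxent, MaxentResults, default_lambdas
from hsm.swd import SWDTable

from helpers import make_swd


class TestFeatureExpansion:
    def test_linear_single_variable_is_scaled_values(self, simple_swd):
        fs = FeatureSet.from_swd(simple_swd)
        X, meta = fs.expand(simple_swd.df, ["v0"], ["linear"])
        assert X.shape[1] == 1 and meta[0].cls == "linear"
        bg = simple_swd.background_rows().df["v0"]
        lo, hi = bg.min(), bg.max()
        expected = np.clip((simple_swd.df["v0"] - lo) / (hi - lo), 0, 1)
        np.testing.assert_allclose(X[:, 0], expected)

    def test_linear_quadratic_two_vars_four_columns(self, simple_swd):
        fs = FeatureSet.from_swd(simple_swd)
        X, meta = fs.expand(simple_swd.df, ["v0", "v1"], ["linear", "quadratic"])
        assert X.shape[1] == 4
        assert sorted({m.cls for m in meta}) == ["linear", "quadratic"]

    def test_hinge_ten_knots_twenty_unit_range_columns(self, simple_swd):
        fs = FeatureSet.from_swd(simple_swd, n_hinge_knots=10)
        X, meta = fs.expand(simple_swd.df, ["v0"], ["hinge"])
        assert X.shape[1] == 20  # 10 forward + 10 reverse
        assert X.min() >= 0.0 and X.max() <= 1.0
        assert sum(m.name.startswith("hinge+") for m in meta) == 10

    def test_product_columns_are_pairwise(self, simple_swd):
        fs = FeatureSet.from_swd(simple_swd)
        X, meta = fs.expand(simple_swd.df, ["v0", "v1", "v2"], ["product"])
        assert X.shape[1] == 3  # C(3,2)

    def test_categorical_expands_to_indicators_only(self):
        swd = make_swd(50, 200, n_vars=2, seed=1)
        swd.df["cat"] = np.random.default_rng(0).integers(0, 4, len(swd.df)).astype(float)
        swd = SWDTable(swd.df, categorical={"cat"})
        fs = FeatureSet.from_swd(swd)
        X, meta = fs.expand(swd.df, ["cat"], ["linear", "hinge", "product"])
        assert all(m.cls == "categorical" for m in meta)
        assert X.shape[1] == 4
        np.testing.assert_allclose(X.sum(axis=1), 1.0)

    def test_constant_variable_warns_and_contributes_nothing(self):
        swd = make_swd(20, 80, n_vars=2, seed=2)
        swd.df["v1"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            fs = FeatureSet.from_swd(SWDTable(swd.df))
        X, meta = fs.expand(swd.df, ["v1"], ["linear", "quadratic", "hinge"])
        assert np.all(X == 0.0) if X.size else True

    def test_knots_strictly_inside_range(self, simple_swd):
        fs = FeatureSet.from_swd(simple_swd, n_hinge_knots=30)
        for v in ("v0", "v1", "v2"):
            assert (fs.hinge_knots[v] > fs.vmin[v]).all()
            assert (fs.hinge_knots[v] < fs.vmax[v]).all()


class TestFit:
    def test_null_data_gives_near_zero_effect(self):
        """Presences drawn from the background distribution: the fitted
        linear predictor is flat (effect below 0.1 in raw-variable units)."""
        swd = make_swd(700, 1300, n_vars=1, seed=3, shift=0.0)
        model = Maxent(swd, ("linear",))
        res = model.fit(1.0)
        raw_range = model.featureset.vmax["v0"] - model.featureset.vmin["v0"]
        beta_raw = res.params.iloc[0] / raw_range  # per raw unit (sd = 1)
        assert abs(beta_raw) < 0.1
        pred = res.predict(swd)
        assert pred.std() < 0.05  # near-constant suitability

    def test_monotone_recovery_positive_beta(self):
        swd = make_swd(400, 1600, n_vars=2, seed=4, shift=1.2)
        res = Maxent(swd, ("linear",)).fit(1.0)
        assert res.params["lin:v0"] > 0

    def test_l1_path_nonzeros_never_increase_when_rm_doubles(self):
        swd = make_swd(400, 2000, n_vars=3, seed=42, shift=0.8)
        model = Maxent(swd, ("linear", "quadratic", "hinge"), n_hinge_knots=10)
        counts = [len(model.fit(rm, tol=1e-8, max_iter=2000).nonzero) for rm in (0.5, 1, 2, 4)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_raw_prediction_sums_to_one_over_training_background(self):
        swd = make_swd(150, 800, seed=5)
        res = Maxent(swd, ("linear", "quadratic")).fit(1.0)
        assert abs(res.raw_background.sum() - 1.0) < 1e-6
        # recomputing through predict() agrees
        raw = res.predict(swd.background_rows(), output="raw")
        assert abs(raw.sum() - 1.0) < 1e-6

    def test_oracle_equivalence_unpenalized_linear(self):
        """With linear features and vanishing penalty the fit matches an
        independent BFGS solution of the same presence/background likelihood."""
        swd = make_swd(300, 1500, n_vars=2, seed=6, shift=1.0)
        model = Maxent(swd, ("linear",))
        res = model.fit(1e-6, tol=1e-10, max_iter=5000)
        X, pres = model.exog, model.is_presence
        Xp, Xb = X[pres], X[~pres]

        def nll(b):
            return -Xp.mean(0) @ b + logsumexp(Xb @ b) - np.log(len(Xb))

        oracle = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                          options={"gtol": 1e-10}).x
        np.testing.assert_allclose(res.params.to_numpy(), oracle, atol=1e-3)

    def test_rm_must_be_positive(self, simple_swd):
        with pytest.raises(ValueError):
            Maxent(simple_swd, ("linear",)).fit(0.0)

    def test_hinge_penalty_scales_with_rm(self, simple_swd):
        m = Maxent(simple_swd, ("linear", "hinge"), n_hinge_knots=5)
        lam1 = default_lambdas(m.exog, m.meta, m.is_presence, 1.0)
        lam2 = default_lambdas(m.exog, m.meta, m.is_presence, 2.0)
        np.testing.assert_allclose(lam2, 2.0 * lam1)


class TestPredict:
    def test_cloglog_in_unit_interval_and_rank_equals_raw(self):
        swd = make_swd(200, 900, seed=7)
        res = Maxent(swd, ("linear", "quadratic", "hinge"), n_hinge_knots=8).fit(1.0)
        raw = res.predict(swd, output="raw")
        cll = res.predict(swd, output="cloglog")
        assert (cll >= 0).all() and (cll <= 1).all()
        assert spearmanr(raw, cll).statistic == pytest.approx(1.0)

    def test_missing_variable_named_in_error(self):
        swd = make_swd(50, 200, seed=8)
        res = Maxent(swd, ("linear",)).fit(1.0)
        with pytest.raises(ValueError, match="v2"):
            res.predict(swd.df[["v0", "v1"]])

    def test_out_of_range_values_clamped(self):
        swd = make_swd(200, 800, seed=9)
        res = Maxent(swd, ("linear", "hinge"), n_hinge_knots=8).fit(1.0)
        lo = res.predict(pd.DataFrame({"v0": [-100.0], "v1": [0.0], "v2": [0.0]}))
        at_min = res.predict(pd.DataFrame(
            {"v0": [res.model.featureset.vmin["v0"]], "v1": [0.0], "v2": [0.0]}
        ))
        np.testing.assert_allclose(lo, at_min)

    def test_stack_prediction_respects_mask(self, small_stack):
        from hsm.swd import OccurrenceSet, build_swd

        centers = small_stack.cell_centers()
        swd = build_swd(
            small_stack,
            OccurrenceSet("sp", centers[:20]),
            OccurrenceSet("background", centers[20:]),
        )
        res = Maxent(swd, ("linear",)).fit(1.0)
        out = res.predict(small_stack)
        assert np.isnan(out.grid[0][~out.mask]).all()
        assert np.isfinite(out.grid[0][out.mask]).all()

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        swd = make_swd(150, 600, seed=10)
        res = Maxent(swd, ("linear", "quadratic", "hinge"), n_hinge_knots=6).fit(1.0)
        res.to_json(tmp_path / "model.json")
        frozen = MaxentResults.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(frozen.predict(swd), res.predict(swd), atol=1e-12)

    def test_summary_mentions_key_quantities(self):
        swd = make_swd(100, 400, seed=11)
        res = Maxent(swd, ("linear",)).fit(1.0)
        text = res.summary()
        assert "regularization multiplier" in text
        assert "entropy" in text
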