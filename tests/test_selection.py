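"""Spatial-CV scoring and the three-stage forward selection pipeline."""

import numpy as np
import pandas as pd
import pytest

from hsm.selection import (
    RM_GRID,
    ModelSettings,
    SpatialCVScorer,
    cv_score,
    forward_feature_selection,
    forward_variable_selection,
    random_cv_score,
    tune,
    tune_rm,
)
from hsm.swd import SWDTable

from helpers import make_swd, make_study

FAST = ModelSettings(n_hinge_knots=4, n_threshold_knots=4, max_iter=150, tol=1e-5)


def swd_with_folds(seed=0, n_presence=120, n_background=600, n_vars=3, shift=1.0, k=4):
    return make_swd(n_presence, n_background, n_vars, seed=seed, shift=shift, k_folds=k)


class TestCvScore:
    def test_one_model_per_fold(self):
        swd = swd_with_folds(k=4)
        mean, per_fold = cv_score(swd, FAST)
        assert len(per_fold) == 4
        assert mean == pytest.approx(np.mean(list(per_fold.values())))

    def test_perfectly_separating_variable_scores_one(self):
        swd = swd_with_folds(seed=1, k=3)
        swd.df["v0"] = np.where(swd.df["is_presence"] == 1, 5.0, 0.0) \
            + np.random.default_rng(0).uniform(0, 0.5, len(swd.df))
        mean, per_fold = cv_score(swd, FAST, var_names=["v0", "v1"])
        assert mean == pytest.approx(1.0)

    def test_deterministic_repeat(self):
        swd = swd_with_folds(seed=2)
        a, pa = cv_score(swd, FAST)
        b, pb = cv_score(swd, FAST)
        assert a == b and pa == pb

    def test_unlabeled_rows_rejected(self, simple_swd):
        with pytest.raises(ValueError, match="fold"):
            cv_score(simple_swd, FAST)

    def test_single_fold_rejected(self):
        swd = swd_with_folds(k=4)
        swd.df["fold"] = 1
        with pytest.raises(ValueError):
            cv_score(SWDTable(swd.df), FAST)


class TestForwardVariableSelection:
    def test_two_candidates_single_pair_model(self):
        swd = swd_with_folds(seed=3, n_vars=2)
        scorer = SpatialCVScorer(swd, FAST)
        selected, log = forward_variable_selection(scorer)
        pair_evals = [r for r in log if r["stage"] == "variables" and "+" in str(r["candidate"])]
        assert len(pair_evals) == 1  # C(2,2)
        assert sorted(selected) == ["v0", "v1"]

    def test_duplicate_of_selected_variable_never_added(self):
        """A copy of an already-selected variable cannot improve the CV
        score, so the greedy addition step never takes it."""
        swd = swd_with_folds(seed=4, n_vars=2, shift=1.5)
        swd.df["v1"] += np.where(swd.df["is_presence"] == 1, 1.0, 0.0)  # both informative
        swd.df["v0_copy"] = swd.df["v0"]
        scorer = SpatialCVScorer(SWDTable(swd.df), FAST)
        selected, log = forward_variable_selection(scorer)
        assert selected[:2] == ["v0", "v1"]
        assert "v0_copy" not in selected

    def test_informative_variables_found_in_study(self):
        data = make_study(seed=1, shape=(96, 96), n_presences=300,
                          clustering=6, n_background=2000)
        scorer = SpatialCVScorer(data["swd_fine"], FAST)
        selected, log = forward_variable_selection(scorer)
        true_vars = set(data["truth"].coefficients)
        assert len(true_vars & set(selected)) >= 2
        accepted = [r["score"] for r in log if r["accepted"]]
        assert accepted == sorted(accepted)  # non-decreasing over accepted steps

    def test_fewer_than_two_candidates_rejected(self):
        swd = swd_with_folds(n_vars=1)
        with pytest.raises(ValueError):
            forward_variable_selection(SpatialCVScorer(swd, FAST), ["v0"])


class TestForwardFeatureSelection:
    def test_always_contains_linear(self):
        swd = swd_with_folds(seed=5)
        classes, _ = forward_feature_selection(SpatialCVScorer(swd, FAST), ["v0", "v1"])
        assert "linear" in classes

    def test_linear_truth_rarely_accepts_extra_classes(self):
        """A monotone linear presence signal should keep the linear basis."""
        kept_linear = 0
        for seed in range(6):
            swd = swd_with_folds(seed=100 + seed, n_presence=200, n_background=1000, shift=1.2)
            classes, _ = forward_feature_selection(SpatialCVScorer(swd, FAST), ["v0", "v1"])
            kept_linear += classes == ("linear",)
        assert kept_linear >= 4

    def test_step_truth_accepts_flexible_class(self):
        """A step-function response needs threshold or hinge features."""
        accepted_flexible = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            n_p, n_b = 250, 1200
            xb = rng.uniform(0, 1, n_b)
            xp = np.where(rng.uniform(0, 1, n_p) < 0.9,
                          rng.uniform(0.6, 0.65, n_p), rng.uniform(0, 1, n_p))
            swd = make_swd(n_p, n_b, n_vars=2, seed=seed, shift=0.0, k_folds=4)
            swd.df["v0"] = np.concatenate([xp, xb])
            scorer = SpatialCVScorer(SWDTable(swd.df), FAST)
            classes, _ = forward_feature_selection(scorer, ["v0", "v1"])
            accepted_flexible += bool({"threshold", "hinge", "quadratic"} & set(classes))
        assert accepted_flexible >= 4


class TestTuneRm:
    def test_grid_has_fourteen_values_and_winner_is_member(self):
        assert len(RM_GRID) == 14
        assert RM_GRID[0] == 0.5 and RM_GRID[-1] == 7.0
        swd = swd_with_folds(seed=6)
        rm, log = tune_rm(SpatialCVScorer(swd, FAST), ["v0", "v1"], ("linear",))
        assert rm in RM_GRID
        assert sum(r["stage"] == "rm" for r in log) == 14

    def test_tie_resolves_to_larger_rm(self):
        swd = swd_with_folds(seed=7, n_presence=30, n_background=150)
        scorer = SpatialCVScorer(swd, FAST)
        rm, log = tune_rm(scorer, ["v0"], ("linear",))
        best = max(r["score"] for r in log)
        tied = [r["candidate"] for r in log if r["score"] == best]
        assert rm == max(tied)

    def test_noisier_features_demand_more_regularization(self):
        """Adding pure-noise variables should not lower the winning RM."""
        wins = []
        for seed in range(6):
            clean = make_swd(150, 700, n_vars=2, seed=300 + seed, shift=1.0, k_folds=4)
            noisy_df = clean.df.copy()
            rng = np.random.default_rng(seed)
            for j in range(4):
                noisy_df[f"noise{j}"] = rng.normal(size=len(noisy_df))
            noisy = SWDTable(noisy_df)
            rm_clean, _ = tune_rm(SpatialCVScorer(clean, FAST), ["v0", "v1"], ("linear", "quadratic"))
            rm_noisy, _ = tune_rm(
                SpatialCVScorer(noisy, FAST),
                ["v0", "v1", "noise0", "noise1", "noise2", "noise3"],
                ("linear", "quadratic"),
            )
            wins.append(rm_noisy >= rm_clean)
        assert sum(wins) >= 4


class TestTunePipeline:
    def test_full_tune_beats_or_matches_untuned_baseline(self, study):
        swd = study["swd_fine"]
        result = tune(swd, FAST)
        untuned, _ = cv_score(swd, FAST)  # all variables, default basis, RM 1
        assert result.score >= untuned - 1e-9
        assert result.rm in RM_GRID
        assert set(result.variables) <= set(swd.var_names)
        assert isinstance(result.trajectory, pd.DataFrame)

    def test_stage_toggles_respected(self, study):
        settings = ModelSettings(
            n_hinge_knots=4, max_iter=150, tol=1e-5,
            select_variables=False, select_features=False, select_rm=False,
        )
        result = tune(study["swd_coarse"], settings)
        assert result.variables == study["swd_coarse"].var_names
        assert result.rm == settings.rm


class TestSpatialVsRandomCv:
    def test_random_cv_optimistic_on_clustered_data(self):
        data = make_study(seed=3)
        swd = data["swd_fine"]
        spatial, _ = cv_score(swd, FAST)
        rand, _ = random_cv_score(swd, 5, seed=11, settings=FAST)
        assert rand > spatial
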