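"""Model selection by spatial cross-validation, in a fixed stage order.

The tuning pipeline follows the fixed stage order used by spatial-
cross-validation Maxent workflows: (1) forward
variable selection — score every pair of candidate variables by spatial
CV, keep the best pair, then greedily add single variables while the
mean held-out score improves; (2) forward feature-class selection —
starting from linear features, greedily add quadratic / product / hinge /
threshold classes; (3) regularization-multiplier tuning over the grid
0.5, 1.0, ..., 7.0. Stages run sequentially without backtracking.

The selection score is the mean held-out AUC (ROC) across spatial folds:
each fold in turn is held out, the model is fitted on the remaining
folds, and held-out presences are scored against held-out background.
During variable selection the basis is fixed at {linear, quadratic,
hinge} with RM = 1 so that variable choice is not confounded with the
later stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .features import DesignCache, FeatureSet
from .maxent import default_lambdas, fit_design
from .metrics import auc_roc
from .swd import SWDTable

__all__ = [
    "ModelSettings",
    "TuneResult",
    "SpatialCVScorer",
    "cv_score",
    "forward_variable_selection",
    "forward_feature_selection",
    "tune_rm",
    "tune",
    "RM_GRID",
]

#: the 14-value regularization-multiplier grid: 0.5 to 7.0 in steps of 0.5
RM_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 15) * 0.5, 2))

SELECTION_CLASSES = ("linear", "quadratic", "hinge")


@dataclass(frozen=True)
class ModelSettings:
    """Tunables shared by fitting and selection."""

    feature_classes: tuple[str, ...] = SELECTION_CLASSES
    rm: float = 1.0
    n_hinge_knots: int = 50
    n_threshold_knots: int = 50
    max_iter: int = 600
    tol: float = 1e-6
    #: a greedy step is accepted only if it beats the incumbent score by
    #: this margin, so solver-tolerance noise cannot drive selection
    min_improvement: float = 5e-4
    rm_grid: tuple[float, ...] = RM_GRID
    select_variables: bool = True
    select_features: bool = True
    select_rm: bool = True


@dataclass
class TuneResult:
    """Winning settings plus the score trajectory of every accepted step."""

    variables: list[str]
    feature_classes: tuple[str, ...]
    rm: float
    score: float
    trajectory: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "feature_classes": list(self.feature_classes),
            "rm": self.rm,
            "score": self.score,
        }


class SpatialCVScorer:
    """Mean held-out AUC across spatial folds, with design caching.

    Fold labels are taken from the SWD table's ``fold`` column (both
    presence and background rows must be labeled). Each ``score`` call
    fits one model per fold; identical calls return identical scores.
    """

    def __init__(self, swd: SWDTable, settings: ModelSettings = ModelSettings()):
        fold = swd.fold
        if np.isnan(fold).any():
            raise ValueError("all SWD rows need fold labels for spatial CV")
        self.swd = swd
        self.settings = settings
        self.folds = np.unique(fold.astype(int))
        if len(self.folds) < 2:
            raise ValueError("spatial CV needs at least 2 folds")
        self.fold_labels = fold.astype(int)
        self.is_presence = swd.is_presence.astype(bool)
        for f in self.folds:
            held = self.fold_labels == f
            if not (self.is_presence & held).any():
                raise ValueError(f"fold {f} has no presence rows")
            if not (~self.is_presence & held).any():
                raise ValueError(f"fold {f} has no background rows")
        fs = FeatureSet.from_swd(
            swd,
            n_hinge_knots=settings.n_hinge_knots,
            n_threshold_knots=settings.n_threshold_knots,
        )
        self.cache = DesignCache(swd, fs)
        self._warm: dict[tuple, np.ndarray] = {}

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def score(
        self,
        var_names,
        feature_classes=None,
        rm: float | None = None,
        *,
        warm_key=None,
    ) -> tuple[float, dict[int, float]]:
        """Fit per held-out fold and return (mean AUC, per-fold AUCs)."""
        classes = tuple(feature_classes or self.settings.feature_classes)
        rm = self.settings.rm if rm is None else rm
        X, meta = self.cache.matrix(list(var_names), classes)
        per_fold: dict[int, float] = {}
        for f in self.folds:
            held = self.fold_labels == f
            train = ~held
            lam = default_lambdas(X[train], meta, self.is_presence[train], rm)
            key = (warm_key, int(f)) if warm_key is not None else None
            beta0 = self._warm.get(key) if key is not None else None
            beta, _ = fit_design(
                X[train],
                self.is_presence[train],
                lam,
                max_iter=self.settings.max_iter,
                tol=self.settings.tol,
                beta0=beta0,
                on_fail="warn",
            )
            if key is not None:
                self._warm[key] = beta
            lp = X[held] @ beta
            pres = self.is_presence[held]
            per_fold[int(f)] = auc_roc(lp[pres], lp[~pres])
        return float(np.mean(list(per_fold.values()))), per_fold


def cv_score(swd: SWDTable, settings: ModelSettings = ModelSettings(), var_names=None):
    """One-shot spatial-CV score of a fixed configuration."""
    scorer = SpatialCVScorer(swd, settings)
    return scorer.score(var_names or swd.var_names, settings.feature_classes, settings.rm)


def forward_variable_selection(
    scorer: SpatialCVScorer, candidates=None
) -> tuple[list[str], list[dict]]:
    """Forward selection of variables by spatial-CV AUC.

    All C(V, 2) pairs are scored first (basis fixed at linear + quadratic
    + hinge, RM = 1); the best pair seeds the model, then single variables
    are added greedily while the mean score strictly improves. Ties break
    to the first candidate in name order.
    """
    cand = sorted(candidates if candidates is not None else scorer.swd.var_names)
    if len(cand) < 2:
        raise ValueError("forward variable selection needs >= 2 candidates")
    log: list[dict] = []
    best_pair, best_score = None, -np.inf
    for pair in combinations(cand, 2):
        s, _ = scorer.score(list(pair), SELECTION_CLASSES, 1.0)
        log.append({"stage": "variables", "candidate": "+".join(pair), "score": s, "accepted": False})
        if s > best_score:
            best_pair, best_score = list(pair), s
    selected = best_pair
    for rec in log:
        if rec["candidate"] == "+".join(selected):
            rec["accepted"] = True
            break

    eps = scorer.settings.min_improvement
    improved = True
    while improved:
        improved = False
        remaining = [v for v in cand if v not in selected]
        step_best, step_var = best_score, None
        for v in remaining:
            s, _ = scorer.score(selected + [v], SELECTION_CLASSES, 1.0)
            log.append({"stage": "variables", "candidate": v, "score": s, "accepted": False})
            if s > step_best + eps:
                step_best, step_var = s, v
        if step_var is not None:
            selected.append(step_var)
            best_score = step_best
            for rec in reversed(log):
                if rec["stage"] == "variables" and rec["candidate"] == step_var:
                    rec["accepted"] = True
                    break
            improved = True
    return selected, log


def forward_feature_selection(
    scorer: SpatialCVScorer, selected_vars, rm: float = 1.0
) -> tuple[tuple[str, ...], list[dict]]:
    """Greedy feature-class selection starting from {linear}."""
    classes = ["linear"]
    base, _ = scorer.score(selected_vars, tuple(classes), rm)
    log = [{"stage": "features", "candidate": "linear", "score": base, "accepted": True}]
    pool = ["quadratic", "hinge", "product", "threshold"]
    eps = scorer.settings.min_improvement
    improved = True
    while improved and pool:
        improved = False
        step_best, step_cls = base, None
        for c in pool:
            s, _ = scorer.score(selected_vars, tuple(classes + [c]), rm)
            log.append({"stage": "features", "candidate": c, "score": s, "accepted": False})
            if s > step_best + eps:
                step_best, step_cls = s, c
        if step_cls is not None:
            classes.append(step_cls)
            pool.remove(step_cls)
            base = step_best
            for rec in reversed(log):
                if rec["stage"] == "features" and rec["candidate"] == step_cls:
                    rec["accepted"] = True
                    break
            improved = True
    ordered = tuple(c for c in ("linear", "quadratic", "product", "hinge", "threshold") if c in classes)
    return ordered, log


def tune_rm(
    scorer: SpatialCVScorer, selected_vars, classes, grid=RM_GRID
) -> tuple[float, list[dict]]:
    """Score every RM on the grid; ties resolve to the larger multiplier."""
    log = []
    best_rm, best_score = None, -np.inf
    for rm in grid:
        s, _ = scorer.score(selected_vars, classes, rm, warm_key=("rm", tuple(selected_vars), classes))
        log.append({"stage": "rm", "candidate": rm, "score": s, "accepted": False})
        if s >= best_score:  # >= so ties move to the larger (more parsimonious) RM
            best_rm, best_score = rm, s
    for rec in log:
        if rec["stage"] == "rm" and rec["candidate"] == best_rm:
            rec["accepted"] = True
    return float(best_rm), log


def tune(swd: SWDTable, settings: ModelSettings = ModelSettings()) -> TuneResult:
    """Run the full pipeline: variables, then feature classes, then RM."""
    scorer = SpatialCVScorer(swd, settings)
    log: list[dict] = []
    if settings.select_variables and len(swd.var_names) >= 2:
        variables, l1 = forward_variable_selection(scorer)
        log += l1
    else:
        variables = list(swd.var_names)
    if settings.select_features:
        classes, l2 = forward_feature_selection(scorer, variables, rm=1.0)
        log += l2
    else:
        classes = settings.feature_classes
    if settings.select_rm:
        rm, l3 = tune_rm(scorer, variables, classes, settings.rm_grid)
        log += l3
    else:
        rm = settings.rm
    score, _ = scorer.score(variables, classes, rm)
    return TuneResult(
        variables=variables,
        feature_classes=classes,
        rm=rm,
        score=score,
        trajectory=pd.DataFrame(log, columns=["stage", "candidate", "score", "accepted"]),
    )


def random_cv_score(
    swd: SWDTable, k: int, seed, settings: ModelSettings = ModelSettings(), var_names=None
):
    """Spatial-CV scoring with fold labels replaced by random ones.

    Used to demonstrate the optimism of non-spatial cross-validation on
    spatially clustered data: with autocorrelated predictors, random
    folds put near-duplicate neighbors of every training point into the
    test set, inflating the held-out AUC relative to spatial folds.
    """
    rng = np.random.default_rng(seed)
    shuffled = swd.df.copy()
    shuffled["fold"] = rng.integers(1, k + 1, size=len(shuffled))
    return cv_score(SWDTable(shuffled, set(swd.categorical)), settings, var_names)
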