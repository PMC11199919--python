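"""Forward fold metric estimation: nested evaluation over test-fold pairs.

With k spatial folds, every unordered choice of ``n_test`` folds (by
default 2 of 7, giving C(7,2) = 21 splits) is held out in turn. Within
each split the full tuning pipeline (variable, feature-class, and RM
selection) runs on the training folds only — true nesting, so no
test-fold datum influences any selection decision — a final model is
fitted on all training-fold rows, and the ten evaluation metrics are
computed on the held-out presences against an equal-size random sample
of held-out background. The unweighted mean of each metric across splits
summarizes the workflow's transferable performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .maxent import Maxent
from .metrics import METRIC_NAMES, compute_report
from .selection import ModelSettings, tune
from .swd import SWDTable

__all__ = ["FfmeReport", "enumerate_splits", "run_ffme", "compare_approaches"]


@dataclass
class FfmeReport:
    """Per-split metric rows plus their unweighted mean."""

    rows: pd.DataFrame
    skipped: list[tuple] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.rows[list(METRIC_NAMES)].mean()

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def enumerate_splits(k: int, n_test: int = 2) -> list[tuple[tuple, tuple]]:
    """All C(k, n_test) unordered test-fold sets with their training folds.

    Fold labels are 1..k; output order is lexicographic in the test set.
    """
    if not 0 < n_test < k:
        raise ValueError("need 0 < n_test < k")
    labels = range(1, k + 1)
    out = []
    for test in combinations(labels, n_test):
        train = tuple(f for f in labels if f not in test)
        out.append((test, train))
    return out


def run_ffme(
    swd: SWDTable,
    n_test: int = 2,
    settings: ModelSettings = ModelSettings(),
    seed: int = 0,
) -> FfmeReport:
    """Nested forward-fold evaluation of the full tuning workflow.

    Per split: tune on the training folds, fit the final model on all
    training-fold rows, predict held-out presences plus an equal-size
    seeded background sample from the held-out folds, and compute the
    ten-metric report. Splits whose test folds hold no presences are
    skipped with a warning. Aggregation is the unweighted mean.
    """
    folds = swd.folds_present()
    k = len(folds)
    if k < 3:
        raise ValueError("ffme needs at least 3 folds")
    fold_col = swd.fold
    records = []
    skipped = []
    # map positional labels 1..k onto the actual fold labels present
    for i, (test_pos, train_pos) in enumerate(enumerate_splits(k, n_test)):
        test = tuple(folds[np.array(test_pos) - 1])
        train = tuple(folds[np.array(train_pos) - 1])
        in_test = np.isin(fold_col, test)
        train_swd = swd.subset_rows(~in_test)
        test_swd = swd.subset_rows(in_test)
        test_pres = test_swd.presence_rows()
        test_bg = test_swd.background_rows()
        if len(test_pres) == 0 or len(test_bg) == 0:
            warnings.warn(f"split {test}: no test presences/background; skipped", stacklevel=2)
            skipped.append(test)
            continue

        result = tune(train_swd, settings)
        model = Maxent(
            train_swd.subset_vars(result.variables),
            result.feature_classes,
            n_hinge_knots=settings.n_hinge_knots,
            n_threshold_knots=settings.n_threshold_knots,
        )
        fitted = model.fit(result.rm, max_iter=settings.max_iter, tol=settings.tol, on_fail="warn")

        rng = np.random.default_rng((seed + i) % (2**31 - 1))
        n_abs = min(len(test_pres), len(test_bg))
        sel = rng.choice(len(test_bg), size=n_abs, replace=False)
        pred_pres = fitted.predict(test_pres)
        pred_bg_all = fitted.predict(test_bg)
        report = compute_report(pred_pres, pred_bg_all[sel], pred_landscape=pred_bg_all)

        rec = {
            "split": "+".join(map(str, test)),
            "test_folds": test,
            "n_test_presence": len(test_pres),
            "variables": ",".join(result.variables),
            "feature_classes": ",".join(result.feature_classes),
            "rm": result.rm,
            "cv_score": result.score,
        }
        rec.update(report.as_series().to_dict())
        records.append(rec)

    if not records:
        raise ValueError("every split was skipped; no evaluable test folds")
    return FfmeReport(rows=pd.DataFrame(records), skipped=skipped)


def compare_approaches(
    report_a: FfmeReport,
    report_b: FfmeReport,
    names: tuple[str, str] = ("targeted", "generalized"),
) -> pd.DataFrame:
    """Per-metric mean difference and win table between two approaches.

    MAE is won by the smaller value; every other metric by the larger.
    Ties score no win. The returned frame has one row per metric plus a
    ``wins`` attribute-style summary row is left to the caller (use
    ``(df['winner'] == name).sum()``).
    """
    mean_a, mean_b = report_a.mean, report_b.mean
    rows = []
    for m in METRIC_NAMES:
        a, b = mean_a[m], mean_b[m]
        delta = a - b
        if m == "mae":
            winner = names[0] if a < b else names[1] if b < a else "tie"
        else:
            winner = names[0] if a > b else names[1] if b > a else "tie"
        rows.append({"metric": m, names[0]: a, names[1]: b, "delta": delta, "winner": winner})
    return pd.DataFrame(rows)
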