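"""Collinearity prefilter: drop highly correlated variables before modeling.

Pairwise Pearson correlation is computed on background rows only (the
rows that span the whole environmental space), and variables are removed
greedily until no pair exceeds the threshold (default |r| > 0.7). Which
member of an offending pair is dropped follows the caret
``findCorrelation`` convention: the one with the larger mean absolute
correlation against all remaining variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .swd import SWDTable

__all__ = ["FilterReport", "correlation_prefilter"]


@dataclass
class FilterReport:
    """Outcome of the correlation prefilter."""

    kept: list[str]
    dropped: list[str] = field(default_factory=list)
    pairs: pd.DataFrame | None = None  # dropped, kept_partner, r, reason
    threshold: float = 0.7

    def to_csv(self, path) -> None:
        if self.pairs is not None:
            self.pairs.to_csv(path, index=False)


def correlation_prefilter(bg_swd: SWDTable, threshold: float = 0.7) -> FilterReport:
    """Greedily remove variables until all pairwise |r| <= threshold.

    Correlations are computed on the background rows of ``bg_swd``.
    Zero-variance variables are dropped first with a warning (their
    correlation is undefined). While any pair exceeds the threshold, the
    member of the currently worst pair with the larger mean |r| against
    all remaining variables is removed. The surviving set is admissible:
    no remaining pair exceeds the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    bg = bg_swd.background_rows()
    if len(bg) < 2:
        raise ValueError("need at least two background rows")

    names = list(bg_swd.var_names)
    X = bg.df[names].to_numpy(float)

    records = []
    sd = X.std(axis=0)
    degenerate = [n for n, s in zip(names, sd) if s == 0]
    if degenerate:
        warnings.warn(
            f"dropping zero-variance variable(s): {degenerate}", stacklevel=2
        )
        for n in degenerate:
            records.append({"dropped": n, "kept_partner": "", "r": np.nan, "reason": "zero variance"})
        keep_idx = [i for i, n in enumerate(names) if n not in degenerate]
        names = [names[i] for i in keep_idx]
        X = X[:, keep_idx]

    if len(names) < 2:
        return FilterReport(kept=names, dropped=degenerate,
                            pairs=pd.DataFrame(records), threshold=threshold)

    r = np.corrcoef(X, rowvar=False)
    absr = np.abs(r)
    np.fill_diagonal(absr, 0.0)
    alive = np.ones(len(names), dtype=bool)

    while True:
        sub = np.where(np.outer(alive, alive), absr, 0.0)
        worst = sub.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        # mean |r| against all other remaining variables
        mean_i = sub[i, alive].sum() / max(1, alive.sum() - 1)
        mean_j = sub[j, alive].sum() / max(1, alive.sum() - 1)
        drop, keep = (i, j) if mean_i >= mean_j else (j, i)
        alive[drop] = False
        records.append(
            {
                "dropped": names[drop],
                "kept_partner": names[keep],
                "r": float(r[i, j]),
                "reason": f"|r|={absr[i, j]:.3f} > {threshold}",
            }
        )

    kept = [n for n, a in zip(names, alive) if a]
    dropped = degenerate + [n for n, a in zip(names, alive) if not a]
    return FilterReport(
        kept=kept,
        dropped=dropped,
        pairs=pd.DataFrame(records, columns=["dropped", "kept_partner", "r", "reason"]),
        threshold=threshold,
    )
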