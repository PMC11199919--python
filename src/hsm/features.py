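"""Feature expansion for the presence-background model.

Raw environmental variables are turned into the model basis: linear,
quadratic, product, hinge, and threshold transforms of min-max scaled
values, plus one indicator per observed class for categorical variables.
Scaling constants and knot positions are frozen from the training
background sample, so that prediction on new data (including whole
rasters) reuses the training geometry; values outside the training range
are clamped to the range edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .swd import SWDTable

__all__ = ["FeatureSet", "FeatureColumn", "ALL_CLASSES", "DesignCache"]

ALL_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")


@dataclass(frozen=True)
class FeatureColumn:
    """Metadata for one design-matrix column."""

    name: str
    cls: str  # linear | quadratic | product | hinge | threshold | categorical
    vars: tuple[str, ...]


@dataclass
class FeatureSet:
    """Per-variable scaling constants, knots, and categorical levels.

    ``vmin``/``vmax`` span all training rows (presences contribute to the
    modeled density's support, so clamping must not truncate them); hinge
    and threshold knots sit at uniform quantiles of the training
    background, strictly inside (vmin, vmax). Background values always
    map into [0, 1].
    """

    vmin: dict[str, float]
    vmax: dict[str, float]
    hinge_knots: dict[str, np.ndarray]
    threshold_knots: dict[str, np.ndarray]
    levels: dict[str, np.ndarray]  # categorical variable -> observed classes
    n_hinge_knots: int = 50
    n_threshold_knots: int = 50

    @classmethod
    def from_swd(
        cls,
        swd: SWDTable,
        n_hinge_knots: int = 50,
        n_threshold_knots: int = 50,
    ) -> "FeatureSet":
        bg = swd.background_rows()
        ref = bg if len(bg) else swd
        vmin, vmax, hk, tk, levels = {}, {}, {}, {}, {}
        for v in swd.var_names:
            col = ref.df[v].to_numpy(float)
            if v in swd.categorical:
                levels[v] = np.unique(swd.df[v].to_numpy(float))
                continue
            full = swd.df[v].to_numpy(float)
            lo, hi = float(full.min()), float(full.max())
            vmin[v], vmax[v] = lo, hi
            if hi <= lo:
                warnings.warn(f"variable {v!r} is constant on training data; "
                              "it contributes no usable feature", stacklevel=2)
                hk[v] = np.empty(0)
                tk[v] = np.empty(0)
                continue
            qs_h = np.quantile(col, np.arange(1, n_hinge_knots + 1) / (n_hinge_knots + 1))
            qs_t = np.quantile(col, np.arange(1, n_threshold_knots + 1) / (n_threshold_knots + 1))
            hk[v] = np.unique(qs_h[(qs_h > lo) & (qs_h < hi)])
            tk[v] = np.unique(qs_t[(qs_t > lo) & (qs_t < hi)])
        return cls(vmin, vmax, hk, tk, levels, n_hinge_knots, n_threshold_knots)

    # -- scaling ---------------------------------------------------------

    def scaled(self, v: str, x: np.ndarray) -> np.ndarray:
        """Min-max scale with clamping to the training range."""
        lo, hi = self.vmin[v], self.vmax[v]
        if hi <= lo:
            return np.zeros_like(x, dtype=float)
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def continuous(self, var_names: Iterable[str]) -> list[str]:
        return [v for v in var_names if v not in self.levels]

    # -- expansion -------------------------------------------------------

    def expand(
        self,
        data: Mapping[str, np.ndarray] | pd.DataFrame,
        var_names: Sequence[str],
        classes: Iterable[str],
    ) -> tuple[np.ndarray, list[FeatureColumn]]:
        """Build the design matrix for the given variables and classes.

        Categorical variables always expand to class indicators (never to
        hinge/product/threshold); continuous variables expand per the
        enabled classes. Returns (matrix, column metadata).
        """
        classes = set(classes)
        unknown = classes - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        cols: list[np.ndarray] = []
        meta: list[FeatureColumn] = []

        def raw(v: str) -> np.ndarray:
            x = np.asarray(data[v], dtype=float)
            lo, hi = self.vmin.get(v), self.vmax.get(v)
            if lo is not None:
                x = np.clip(x, lo, hi)
            return x

        cont = self.continuous(var_names)
        z = {v: self.scaled(v, raw(v)) for v in cont}

        if "linear" in classes:
            for v in cont:
                cols.append(z[v])
                meta.append(FeatureColumn(f"lin:{v}", "linear", (v,)))
        if "quadratic" in classes:
            for v in cont:
                cols.append(z[v] ** 2)
                meta.append(FeatureColumn(f"quad:{v}", "quadratic", (v,)))
        if "product" in classes:
            for a, b in combinations(cont, 2):
                cols.append(z[a] * z[b])
                meta.append(FeatureColumn(f"prod:{a}*{b}", "product", (a, b)))
        if "hinge" in classes:
            for v in cont:
                xv = raw(v)
                lo, hi = self.vmin[v], self.vmax[v]
                for t in self.hinge_knots.get(v, ()):
                    cols.append(np.clip((xv - t) / (hi - t), 0.0, 1.0))
                    meta.append(FeatureColumn(f"hinge+:{v}@{t:.6g}", "hinge", (v,)))
                for t in self.hinge_knots.get(v, ()):
                    cols.append(np.clip((t - xv) / (t - lo), 0.0, 1.0))
                    meta.append(FeatureColumn(f"hinge-:{v}@{t:.6g}", "hinge", (v,)))
        if "threshold" in classes:
            for v in cont:
                xv = np.asarray(data[v], dtype=float)
                for t in self.threshold_knots.get(v, ()):
                    cols.append((xv > t).astype(float))
                    meta.append(FeatureColumn(f"thr:{v}@{t:.6g}", "threshold", (v,)))
        # categorical indicators are part of every class configuration
        for v in var_names:
            if v in self.levels:
                xv = np.asarray(data[v], dtype=float)
                for c in self.levels[v]:
                    cols.append((xv == c).astype(float))
                    meta.append(FeatureColumn(f"cat:{v}=={c:g}", "categorical", (v,)))

        if not cols:
            n = len(next(iter(data[v] for v in var_names)))
            return np.empty((n, 0)), []
        return np.column_stack(cols), meta

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "vmin": self.vmin,
            "vmax": self.vmax,
            "hinge_knots": {k: v.tolist() for k, v in self.hinge_knots.items()},
            "threshold_knots": {k: v.tolist() for k, v in self.threshold_knots.items()},
            "levels": {k: v.tolist() for k, v in self.levels.items()},
            "n_hinge_knots": self.n_hinge_knots,
            "n_threshold_knots": self.n_threshold_knots,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            vmin={k: float(v) for k, v in d["vmin"].items()},
            vmax={k: float(v) for k, v in d["vmax"].items()},
            hinge_knots={k: np.asarray(v, float) for k, v in d["hinge_knots"].items()},
            threshold_knots={k: np.asarray(v, float) for k, v in d["threshold_knots"].items()},
            levels={k: np.asarray(v, float) for k, v in d["levels"].items()},
            n_hinge_knots=d.get("n_hinge_knots", 50),
            n_threshold_knots=d.get("n_threshold_knots", 50),
        )


class DesignCache:
    """Cached per-(variable, class) column blocks for one SWD table.

    Forward selection and tuning refit the model hundreds of times on
    column subsets of one table; this cache expands each block once.
    """

    def __init__(self, swd: SWDTable, featureset: FeatureSet):
        self.swd = swd
        self.fs = featureset
        self._blocks: dict[tuple, tuple[np.ndarray, list[FeatureColumn]]] = {}

    def _block(self, key: tuple, vars_: Sequence[str], classes: Iterable[str]):
        if key not in self._blocks:
            self._blocks[key] = self.fs.expand(self.swd.df, vars_, classes)
        return self._blocks[key]

    def matrix(
        self, var_names: Sequence[str], classes: Iterable[str]
    ) -> tuple[np.ndarray, list[FeatureColumn]]:
        """Assemble the design for a variable/class subset from cached blocks."""
        classes = [c for c in ALL_CLASSES if c in set(classes)]
        parts, meta = [], []
        for v in var_names:
            if v in self.fs.levels:
                blocks = [self._block(("cat", v), [v], [])]
            else:
                blocks = [
                    self._block(("cont", v, c), [v], [c])
                    for c in classes
                    if c != "product"
                ]
            for X, m in blocks:
                if X.shape[1]:
                    parts.append(X)
                    meta.extend(m)
        if "product" in classes:
            cont = self.fs.continuous(var_names)
            for a, b in combinations(cont, 2):
                X, m = self._block(("prod", a, b), [a, b], ["product"])
                if X.shape[1]:
                    parts.append(X)
                    meta.extend(m)
        if not parts:
            return np.empty((len(self.swd), 0)), []
        return np.column_stack(parts), meta
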