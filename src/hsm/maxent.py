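"""Presence-background maximum-entropy model (penalized Gibbs density).

The model represents habitat use as a Gibbs density over the landscape,
approximated by the background sample: q(x) = exp(f(x)'beta) / Z, with f
the expanded feature vector. Fitting maximizes the per-presence average
log-likelihood of the presence sample under q, minus L1 penalties

    sum_j lambda_j |beta_j|,   lambda_j = RM * c_class(m) * sd_j / sqrt(m)

where m is the presence count, sd_j the feature's standard deviation over
the presence sample, and c_class the reference per-class regularization
tables indexed by presence count. RM is the user-facing regularization
multiplier. This penalized-GLM formulation is the convex equivalent of
the classical sequential-update algorithm and is solved here by FISTA
(accelerated proximal gradient with backtracking and adaptive restart).

Outputs: ``raw`` is the normalized density (sums to one over the training
background); ``cloglog`` is the standard monotone rescaling
1 - exp(-exp(H) * raw) with H the entropy of the fitted density over the
background, giving a [0, 1] suitability index.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .features import ALL_CLASSES, FeatureColumn, FeatureSet
from .raster import RasterStack
from .swd import SWDTable

__all__ = [
    "Maxent",
    "MaxentResults",
    "ConvergenceError",
    "default_lambdas",
    "fit_design",
]


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the objective trace."""

    def __init__(self, message: str, trace: np.ndarray):
        super().__init__(message)
        self.trace = trace


# Reference per-class default regularization tables, interpolated in the
# presence count (linear/quadratic/product share one table; hinge is
# constant; threshold and categorical have their own).
_REG_TABLES: dict[str, tuple[list[float], list[float]]] = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "product": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "threshold": ([0, 100], [2.0, 1.0]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
}
_HINGE_REG = 0.5


def default_lambdas(
    X: np.ndarray,
    meta: Sequence[FeatureColumn],
    is_presence: np.ndarray,
    rm: float,
) -> np.ndarray:
    """Per-feature L1 penalties: RM x class default x sd / sqrt(m)."""
    if rm <= 0:
        raise ValueError("regularization multiplier must be > 0")
    pres = np.asarray(is_presence, bool)
    m = int(pres.sum())
    sd = X[pres].std(axis=0)
    fallback = X.std(axis=0)
    sd = np.where(sd > 0, sd, np.maximum(fallback, 1e-4))
    lam = np.empty(X.shape[1])
    for j, col in enumerate(meta):
        if col.cls == "hinge":
            c = _HINGE_REG
        else:
            xs, ys = _REG_TABLES[col.cls]
            c = float(np.interp(m, xs, ys))
        lam[j] = rm * c * sd[j] / np.sqrt(max(m, 1))
    if any(c.cls == "hinge" for c in meta):
        floor = rm * _HINGE_REG / np.sqrt(max(m, 1))
        hid = np.array([c.cls == "hinge" for c in meta])
        lam[hid] = np.maximum(lam[hid], floor)
    return lam


def _objective(b, Xp_mean, Xb, lam):
    lp_b = Xb @ b
    lz = logsumexp(lp_b)
    smooth = -float(Xp_mean @ b) + lz - np.log(Xb.shape[0])
    return smooth + float(np.abs(b) @ lam), lp_b, lz


def fit_design(
    X: np.ndarray,
    is_presence: np.ndarray,
    lam: np.ndarray,
    *,
    max_iter: int = 1000,
    tol: float = 1e-7,
    beta0: np.ndarray | None = None,
    on_fail: str = "raise",
):
    """Minimize the penalized Gibbs negative log-likelihood by FISTA.

    Returns (beta, info) where info carries convergence diagnostics and
    the objective trace. ``on_fail`` controls behavior at the iteration
    cap: 'raise' (default) raises :class:`ConvergenceError`, 'warn'
    returns the best iterate with a warning.
    """
    pres = np.asarray(is_presence, bool)
    Xp, Xb = X[pres], X[~pres]
    if Xp.shape[0] < 1 or Xb.shape[0] < 2:
        raise ValueError("need >= 1 presence and >= 2 background rows")
    p = X.shape[1]
    if p == 0:
        return np.empty(0), {"converged": True, "n_iter": 0, "trace": np.empty(0)}
    Xp_mean = Xp.mean(axis=0)

    b = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    y = b.copy()
    t = 1.0
    L = 1.0
    F_b, _, _ = _objective(b, Xp_mean, Xb, lam)
    trace = [F_b]
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        lp_y = Xb @ y
        lz = logsumexp(lp_y)
        q = np.exp(lp_y - lz)
        g = Xb.T @ q - Xp_mean
        f_y = -float(Xp_mean @ y) + lz - np.log(Xb.shape[0])
        # backtracking on the smooth part
        while True:
            b_new = np.sign(y - g / L) * np.maximum(np.abs(y - g / L) - lam / L, 0.0)
            d = b_new - y
            f_new = -float(Xp_mean @ b_new) + logsumexp(Xb @ b_new) - np.log(Xb.shape[0])
            if f_new <= f_y + g @ d + 0.5 * L * (d @ d) + 1e-12:
                break
            L *= 2.0
        F_new = f_new + float(np.abs(b_new) @ lam)
        # adaptive restart if the objective went up
        if F_new > F_b:
            y = b.copy()
            t = 1.0
            L *= 2.0
            trace.append(F_b)
            continue
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = b_new + ((t - 1.0) / t_new) * (b_new - b)
        rel = abs(F_b - F_new) / max(1.0, abs(F_new))
        b, F_b, t = b_new, F_new, t_new
        trace.append(F_b)
        L = max(L / 1.5, 1e-3)  # allow the step size to grow back
        if rel < tol:
            converged = True
            break
    info = {"converged": converged, "n_iter": it, "trace": np.asarray(trace)}
    if not converged:
        msg = f"no convergence after {it} iterations (last rel change above {tol:g})"
        if on_fail == "raise":
            raise ConvergenceError(msg, np.asarray(trace))
        warnings.warn(msg, stacklevel=2)
    return b, info


class Maxent:
    """Presence-background Maxent-style model over an SWD table.

    Parameters
    ----------
    swd : SWDTable
        Presence and background rows with extracted variable values.
    feature_classes : iterable of str
        Subset of {'linear', 'quadratic', 'product', 'hinge', 'threshold'}.
        Categorical variables always expand to class indicators.
    n_hinge_knots, n_threshold_knots : int
        Knots per variable at uniform background quantiles.

    ``fit(rm)`` returns a :class:`MaxentResults`.
    """

    def __init__(
        self,
        swd: SWDTable,
        feature_classes: Iterable[str] = ("linear", "quadratic", "hinge"),
        *,
        n_hinge_knots: int = 50,
        n_threshold_knots: int = 50,
        featureset: FeatureSet | None = None,
    ):
        swd.check_fit_ready()
        self.swd = swd
        self.feature_classes = tuple(c for c in ALL_CLASSES if c in set(feature_classes))
        if set(feature_classes) - set(ALL_CLASSES):
            raise ValueError(f"unknown feature classes: {set(feature_classes) - set(ALL_CLASSES)}")
        self.var_names = list(swd.var_names)
        self.featureset = featureset or FeatureSet.from_swd(
            swd, n_hinge_knots=n_hinge_knots, n_threshold_knots=n_threshold_knots
        )
        self.exog, self.meta = self.featureset.expand(swd.df, self.var_names, self.feature_classes)
        self.is_presence = swd.is_presence.astype(bool)

    @property
    def n_presence(self) -> int:
        return int(self.is_presence.sum())

    def fit(
        self,
        rm: float = 1.0,
        *,
        max_iter: int = 1000,
        tol: float = 1e-7,
        on_fail: str = "raise",
    ) -> "MaxentResults":
        lam = default_lambdas(self.exog, self.meta, self.is_presence, rm)
        beta, info = fit_design(
            self.exog, self.is_presence, lam, max_iter=max_iter, tol=tol, on_fail=on_fail
        )
        return MaxentResults(self, beta, lam, rm, info)


class MaxentResults:
    """Fitted coefficients, normalizers, and prediction for a Maxent model."""

    def __init__(self, model: Maxent, params: np.ndarray, lambdas: np.ndarray, rm: float, info: dict):
        self.model = model
        self.params = pd.Series(params, index=[c.name for c in model.meta])
        self.lambdas = lambdas
        self.rm = rm
        self.converged = info["converged"]
        self.n_iter = info["n_iter"]
        self.objective_trace = info["trace"]
        # normalizers over the TRAINING background
        lp_bg = model.exog[~model.is_presence] @ params
        self.log_z = float(logsumexp(lp_bg))
        raw_bg = np.exp(lp_bg - self.log_z)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy = float(-(raw_bg * np.where(raw_bg > 0, np.log(raw_bg), 0.0)).sum())
        self._raw_bg = raw_bg

    # -- introspection ---------------------------------------------------

    @property
    def nonzero(self) -> pd.Series:
        return self.params[self.params != 0.0]

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def summary(self) -> str:
        lines = [
            "Presence-background Maxent model",
            "=" * 48,
            f"presences: {self.model.n_presence:>8d}   background: {(~self.model.is_presence).sum():>8d}",
            f"feature classes: {', '.join(self.model.feature_classes)}",
            f"features: {len(self.params)}   nonzero: {len(self.nonzero)}",
            f"regularization multiplier: {self.rm}",
            f"converged: {self.converged} ({self.n_iter} iterations)",
            f"penalized objective: {self.objective:.6f}",
            f"background entropy H: {self.entropy:.4f}",
            "-" * 48,
            f"{'feature':<32}{'coef':>12}",
        ]
        for name, val in self.nonzero.items():
            lines.append(f"{name:<32}{val:>12.5f}")
        return "\n".join(lines)

    # -- prediction ------------------------------------------------------

    def _tabular_lp(self, data: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.model.var_names if v not in data]
        if missing:
            raise ValueError(f"missing variable(s) for prediction: {missing}")
        X, _ = self.model.featureset.expand(data, self.model.var_names, self.model.feature_classes)
        return X @ self.params.to_numpy()

    def _transform(self, lp: np.ndarray, output: str) -> np.ndarray:
        raw = np.exp(lp - self.log_z)
        if output == "raw":
            return raw
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        raise ValueError("output must be 'raw' or 'cloglog'")

    def predict(self, data, output: str = "cloglog"):
        """Predict suitability.

        ``data`` may be an SWDTable, a DataFrame/mapping of variable
        columns, or a RasterStack (returning a one-layer 'suitability'
        stack with masked cells as NaN). ``output`` is 'raw' (normalized
        density over the training background) or 'cloglog'.
        """
        if isinstance(data, RasterStack):
            missing = [v for v in self.model.var_names if v not in data.names]
            if missing:
                raise ValueError(f"missing variable(s) for prediction: {missing}")
            cols = {v: data.valid_values(v) for v in self.model.var_names}
            vals = self._transform(self._tabular_lp(cols), output)
            grid = np.full(data.shape, np.nan)
            grid[data.mask] = vals
            return RasterStack(
                names=["suitability"],
                grid=grid[None],
                mask=data.mask,
                cell_size=data.cell_size,
                origin=data.origin,
                crs=data.crs,
            )
        if isinstance(data, SWDTable):
            data = data.df
        return self._transform(self._tabular_lp(data), output)

    @property
    def raw_background(self) -> np.ndarray:
        """Raw (density) prediction at the training background; sums to 1."""
        return self._raw_bg

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "var_names": self.model.var_names,
            "feature_classes": list(self.model.feature_classes),
            "categorical": sorted(self.model.swd.categorical),
            "featureset": self.model.featureset.to_dict(),
            "params": {k: float(v) for k, v in self.params.items()},
            "rm": self.rm,
            "log_z": self.log_z,
            "entropy": self.entropy,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "FrozenMaxent":
        if isinstance(source, Path) or (isinstance(source, str) and source.lstrip()[:1] != "{"):
            source = Path(source).read_text()
        d = json.loads(source)
        return FrozenMaxent(d)


class FrozenMaxent:
    """Deserialized model: prediction only, no refitting."""

    def __init__(self, payload: dict):
        self.var_names = payload["var_names"]
        self.feature_classes = tuple(payload["feature_classes"])
        self.featureset = FeatureSet.from_dict(payload["featureset"])
        self.params = payload["params"]
        self.rm = payload["rm"]
        self.log_z = payload["log_z"]
        self.entropy = payload["entropy"]

    def predict(self, data, output: str = "cloglog"):
        if isinstance(data, RasterStack):
            cols = {v: data.valid_values(v) for v in self.var_names}
            X, meta = self.featureset.expand(cols, self.var_names, self.feature_classes)
            beta = np.array([self.params.get(c.name, 0.0) for c in meta])
            raw = np.exp(X @ beta - self.log_z)
            vals = raw if output == "raw" else 1.0 - np.exp(-np.exp(self.entropy) * raw)
            grid = np.full(data.shape, np.nan)
            grid[data.mask] = vals
            return RasterStack(["suitability"], grid[None], data.mask, data.cell_size, data.origin, data.crs)
        if isinstance(data, SWDTable):
            data = data.df
        X, meta = self.featureset.expand(data, self.var_names, self.feature_classes)
        beta = np.array([self.params.get(c.name, 0.0) for c in meta])
        raw = np.exp(X @ beta - self.log_z)
        return raw if output == "raw" else 1.0 - np.exp(-np.exp(self.entropy) * raw)
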