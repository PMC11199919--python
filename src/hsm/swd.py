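"""Occurrence tables and the samples-with-data (SWD) modeling currency.

An :class:`OccurrenceSet` is a set of presence points for one species,
optionally carrying spatial-fold labels. An :class:`SWDTable` is the flat
table consumed by the model: one row per point (presence or background)
with a 0/1 presence flag, an optional fold label, and the environmental
variable values extracted at that point. Points that fall on masked cells
are rejected at extraction time, so an SWD table never holds missing
variable values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import RasterStack, extract_values

__all__ = ["OccurrenceSet", "SWDTable", "build_swd"]

BACKGROUND_LABEL = "background"
_META_COLS = ["species", "x", "y", "is_presence", "fold"]


@dataclass
class OccurrenceSet:
    """Presence points of one species in a projected, meter-based CRS."""

    species: str
    points: np.ndarray  # (n, 2) of x, y
    fold: np.ndarray | None = None  # (n,) integer labels 1..k, or None
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if self.fold is not None:
            self.fold = np.asarray(self.fold, dtype=int)
            if self.fold.shape != (len(self.points),):
                raise ValueError("fold must hold one label per point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_folds(self) -> int:
        if self.fold is None:
            return 0
        return len(np.unique(self.fold))

    def with_fold(self, fold: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.species, self.points.copy(), np.asarray(fold, int), self.crs)

    def take(self, idx) -> "OccurrenceSet":
        idx = np.asarray(idx)
        return OccurrenceSet(
            self.species,
            self.points[idx],
            None if self.fold is None else self.fold[idx],
            self.crs,
        )

    # -- CSV round trip: header species,x,y[,fold] ----------------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"species": self.species, "x": self.points[:, 0], "y": self.points[:, 1]}
        )
        if self.fold is not None:
            df["fold"] = self.fold
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, species: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        for col in ("species", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"occurrence CSV must have a {col!r} column")
        if species is not None:
            df = df[df["species"] == species]
        elif df["species"].nunique() > 1:
            raise ValueError("multiple species in CSV; pass species=")
        fold = df["fold"].to_numpy(int) if "fold" in df.columns else None
        return cls(
            species=str(df["species"].iloc[0]),
            points=df[["x", "y"]].to_numpy(float),
            fold=fold,
        )


@dataclass
class SWDTable:
    """Samples-with-data: points plus extracted variable values.

    ``df`` has the meta columns ``species, x, y, is_presence, fold``
    (fold is NaN when unassigned) followed by one column per variable.
    """

    df: pd.DataFrame
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SWD table missing meta columns: {missing}")
        if self.df[self.var_names].isna().any().any():
            raise ValueError("SWD table has missing variable values")

    @property
    def var_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in _META_COLS]

    @property
    def is_presence(self) -> np.ndarray:
        return self.df["is_presence"].to_numpy(int)

    @property
    def fold(self) -> np.ndarray:
        return self.df["fold"].to_numpy(float)

    @property
    def values(self) -> np.ndarray:
        return self.df[self.var_names].to_numpy(float)

    @property
    def n_presence(self) -> int:
        return int(self.is_presence.sum())

    @property
    def n_background(self) -> int:
        return len(self.df) - self.n_presence

    def __len__(self) -> int:
        return len(self.df)

    def subset_vars(self, names: Sequence[str]) -> "SWDTable":
        keep = _META_COLS + list(names)
        return SWDTable(self.df[keep].copy(), {n for n in names if n in self.categorical})

    def subset_rows(self, mask) -> "SWDTable":
        return SWDTable(self.df.loc[np.asarray(mask)].reset_index(drop=True), set(self.categorical))

    def presence_rows(self) -> "SWDTable":
        return self.subset_rows(self.is_presence == 1)

    def background_rows(self) -> "SWDTable":
        return self.subset_rows(self.is_presence == 0)

    def folds_present(self) -> np.ndarray:
        f = self.df["fold"].dropna().unique()
        return np.sort(f.astype(int))

    def check_fit_ready(self) -> None:
        if self.n_presence < 1 or self.n_background < 1:
            raise ValueError(
                "fitting requires at least one presence and one background row"
            )

    # -- Maxent SWD dialect: species,x,y,var1,var2,... -------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.loc[out["is_presence"] == 0, "species"] = BACKGROUND_LABEL
        cols = ["species", "x", "y"] + (["fold"] if out["fold"].notna().any() else []) + self.var_names
        out[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, categorical: Sequence[str] = ()) -> "SWDTable":
        df = pd.read_csv(path)
        df["is_presence"] = (df["species"] != BACKGROUND_LABEL).astype(int)
        if "fold" not in df.columns:
            df["fold"] = np.nan
        var_cols = [c for c in df.columns if c not in _META_COLS]
        return cls(df[_META_COLS + var_cols], set(categorical))


def build_swd(
    stack: RasterStack,
    presences: OccurrenceSet,
    background: OccurrenceSet,
) -> SWDTable:
    """Extract stack values at presence and background points.

    Points on masked cells are dropped (with a warning from the extractor);
    fold labels are carried through for the surviving rows.
    """
    frames = []
    for occ, flag in ((presences, 1), (background, 0)):
        vals, kept, _ = extract_values(stack, occ.points)
        df = pd.DataFrame(vals, columns=stack.names)
        df.insert(0, "species", occ.species if flag else BACKGROUND_LABEL)
        df.insert(1, "x", occ.points[kept, 0])
        df.insert(2, "y", occ.points[kept, 1])
        df.insert(3, "is_presence", flag)
        df.insert(4, "fold", occ.fold[kept] if occ.fold is not None else np.nan)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return SWDTable(table, set(stack.categorical))
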