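"""Suitability map products: thresholding, agreement, and suitable area.

Continuous suitability maps are thresholded (typically at the
TSS-maximizing threshold of the corresponding model evaluation) into
presence-absence maps; pairs of maps are compared by Pearson correlation
and RMSE over valid cells; suitable area is the count of presence cells
times the cell area, reported in square kilometers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .raster import RasterStack, RasterAlignmentError

__all__ = [
    "ComparisonReport",
    "threshold_map",
    "compare_suitability",
    "suitable_area",
    "compare_maps",
    "plot_map",
]


@dataclass
class ComparisonReport:
    """Agreement between two approaches' maps."""

    pearson_r: float
    rmse: float
    area_a_km2: float
    area_b_km2: float
    area_diff_km2: float  # unsigned, as differences are conventionally reported
    area_diff_signed_km2: float
    threshold_a: float
    threshold_b: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_layer(m) -> tuple[np.ndarray, np.ndarray, float]:
    """(values, mask, cell_size) from a RasterStack or plain array."""
    if isinstance(m, RasterStack):
        if m.n_layers != 1:
            raise ValueError("expected a single-layer map")
        return m.grid[0], m.mask, m.cell_size
    arr = np.asarray(m, float)
    return arr, np.isfinite(arr), np.nan


def threshold_map(suitability, threshold: float):
    """Binary presence-absence map: cell >= threshold becomes 1.

    Accepts and returns a RasterStack (mask preserved) or a plain array
    (NaN cells stay NaN).
    """
    if isinstance(suitability, RasterStack):
        vals, mask, _ = _as_layer(suitability)
        out = np.where(vals >= threshold, 1.0, 0.0)
        out[~mask] = np.nan
        return RasterStack(
            names=["presence_absence"],
            grid=out[None],
            mask=mask,
            cell_size=suitability.cell_size,
            origin=suitability.origin,
            crs=suitability.crs,
        )
    vals = np.asarray(suitability, float)
    out = np.where(vals >= threshold, 1.0, 0.0)
    out[~np.isfinite(vals)] = np.nan
    return out


def compare_suitability(map_a, map_b) -> tuple[float, float]:
    """(Pearson r, RMSE) between two maps over shared valid cells."""
    va, ma, _ = _as_layer(map_a)
    vb, mb, _ = _as_layer(map_b)
    if va.shape != vb.shape:
        raise RasterAlignmentError("maps have different grids")
    if isinstance(map_a, RasterStack) and isinstance(map_b, RasterStack):
        if not map_a.same_geometry(map_b):
            raise RasterAlignmentError("maps have different geometry or masks")
    mask = ma & mb
    a, b = va[mask], vb[mask]
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    r = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else np.nan
    return r, rmse


def suitable_area(pa_map, cell_size: float | None = None) -> float:
    """Suitable area in km2: (count of 1-cells) x cell_size^2 / 1e6."""
    vals, mask, cs = _as_layer(pa_map)
    if cell_size is not None:
        cs = cell_size
    if not np.isfinite(cs):
        raise ValueError("cell_size required for plain-array maps")
    v = vals[mask]
    if not np.isin(v, (0.0, 1.0)).all():
        raise ValueError("presence-absence map must be binary on valid cells")
    return float(v.sum() * cs * cs / 1e6)


def plot_map(map_, ax=None, *, cmap="RdYlBu_r", title=None):
    """Render a suitability or presence-absence map (masked cells blank).

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    vals, mask, _ = _as_layer(map_)
    shown = np.where(mask, vals, np.nan)
    if ax is None:
        _, ax = plt.subplots()
    extent = None
    if isinstance(map_, RasterStack):
        xmin, ymin, xmax, ymax = map_.extent
        extent = (xmin, xmax, ymin, ymax)
    im = ax.imshow(shown, cmap=cmap, vmin=0.0, vmax=1.0, extent=extent)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    return ax


def compare_maps(
    suit_a, suit_b, threshold_a: float, threshold_b: float
) -> ComparisonReport:
    """Full two-approach map comparison.

    Pearson r and RMSE are computed on the continuous suitability maps;
    each map is then thresholded with its own model's threshold and the
    suitable areas and their (unsigned) difference reported.
    """
    r, rmse = compare_suitability(suit_a, suit_b)
    pa_a = threshold_map(suit_a, threshold_a)
    pa_b = threshold_map(suit_b, threshold_b)
    area_a = suitable_area(pa_a)
    area_b = suitable_area(pa_b)
    return ComparisonReport(
        pearson_r=r,
        rmse=rmse,
        area_a_km2=area_a,
        area_b_km2=area_b,
        area_diff_km2=abs(area_a - area_b),
        area_diff_signed_km2=area_a - area_b,
        threshold_a=threshold_a,
        threshold_b=threshold_b,
    )
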