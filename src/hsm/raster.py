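"""Co-registered raster stacks: GeoTIFF I/O, masking, and point extraction.

A :class:`RasterStack` holds named, grid-aligned single-band layers sharing
one validity mask (typically a forest mask), a square cell size in meters,
an upper-left origin, and a CRS tag. The package never reprojects: stacks
and occurrence tables must already share a projected, meter-based CRS.

GeoTIFFs are read and written through :mod:`tifffile`, handling the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL nodata)
directly. Cells follow the half-open convention: a cell owns its left and
top edges' interior points, i.e. a point on a shared vertical edge belongs
to the cell on the right and a point on a shared horizontal edge to the
cell below.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "RasterStack",
    "RasterAlignmentError",
    "load_stack",
    "write_stack",
    "read_geotiff",
    "write_geotiff",
    "extract_values",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_IMAGE_DESCRIPTION = 270

#: sentinel written to masked cells on export
NODATA = -9999.0


class RasterAlignmentError(ValueError):
    """Raised when layers do not share grid geometry (shape, origin, cell size)."""


@dataclass
class RasterStack:
    """Named, co-registered raster variables with a shared validity mask.

    Parameters
    ----------
    names : list of str
        One identifier per layer.
    grid : ndarray, shape (n_layers, ny, nx)
        Layer values; entries under invalid mask cells are undefined.
    mask : ndarray of bool, shape (ny, nx)
        True where cells are valid (inside the study area).
    cell_size : float
        Square cell edge length in meters.
    origin : (float, float)
        (x, y) map coordinates of the grid's upper-left corner.
    crs : str
        Opaque CRS tag; stacks and occurrences must agree on it.
    categorical : set of str
        Names of layers holding class codes rather than continuous values.
    """

    names: list[str]
    grid: np.ndarray
    mask: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local-meters"
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D (n_layers, ny, nx)")
        if len(self.names) != self.grid.shape[0]:
            raise ValueError("one name per layer required")
        if self.grid.shape[1:] != self.mask.shape:
            raise RasterAlignmentError("mask shape differs from layer shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not self.mask.any():
            raise ValueError("empty study area: mask has no valid cells")

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_layers(self) -> int:
        return len(self.names)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        ny, nx = self.shape
        x0, y0 = self.origin
        return (x0, y0 - ny * self.cell_size, x0 + nx * self.cell_size, y0)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def layer(self, name: str) -> np.ndarray:
        return self.grid[self.names.index(name)]

    def valid_values(self, name: str) -> np.ndarray:
        """Values of one layer at valid cells, row-major order."""
        return self.layer(name)[self.mask]

    def cell_centers(self) -> np.ndarray:
        """(n_valid, 2) array of (x, y) centers of valid cells, row-major."""
        rows, cols = np.nonzero(self.mask)
        x0, y0 = self.origin
        cs = self.cell_size
        return np.column_stack([x0 + (cols + 0.5) * cs, y0 - (rows + 0.5) * cs])

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under the half-open cell convention.

        A point on a shared vertical edge belongs to the cell on its right;
        a point on a shared horizontal edge to the cell below it. Indices
        may fall outside the grid; callers must bounds-check.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - y) / self.cell_size).astype(int)
        return row, col

    def subset(self, names: Sequence[str]) -> "RasterStack":
        idx = [self.names.index(n) for n in names]
        return RasterStack(
            names=list(names),
            grid=self.grid[idx],
            mask=self.mask,
            cell_size=self.cell_size,
            origin=self.origin,
            crs=self.crs,
            categorical={n for n in names if n in self.categorical},
        )

    def same_geometry(self, other: "RasterStack") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and np.array_equal(self.mask, other.mask)
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------


def write_geotiff(
    path: str | Path,
    array: np.ndarray,
    *,
    cell_size: float,
    origin: tuple[float, float],
    crs: str = "local-meters",
    nodata: float = NODATA,
) -> None:
    """Write a single-band float64 GeoTIFF with georeferencing tags."""
    array = np.asarray(array, dtype=np.float64)
    desc = json.dumps({"crs": crs})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(cell_size), float(cell_size), 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(
        path, array, description=desc, extratags=extratags, photometric="minisblack"
    )


def read_geotiff(path: str | Path):
    """Read a single-band GeoTIFF.

    Returns
    -------
    array, cell_size, origin, crs, nodata
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray().astype(np.float64)
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else None
        crs = "local-meters"
        if _TAG_IMAGE_DESCRIPTION in tags:
            try:
                crs = json.loads(tags[_TAG_IMAGE_DESCRIPTION].value).get("crs", crs)
            except (json.JSONDecodeError, AttributeError):
                pass
    if array.ndim != 2:
        raise IOError(f"{path}: expected a single-band raster")
    if not np.isclose(scale[0], scale[1]):
        raise RasterAlignmentError(f"{path}: non-square cells not supported")
    origin = (float(tiepoint[3]), float(tiepoint[4]))
    return array, float(scale[0]), origin, crs, nodata


def load_stack(
    paths: Iterable[str | Path],
    mask_path: str | Path,
    *,
    categorical: Iterable[str] = (),
) -> RasterStack:
    """Read aligned single-band GeoTIFFs and apply a shared mask.

    Layer names derive from file stems. All rasters must share shape,
    origin and cell size exactly; any mismatch raises
    :class:`RasterAlignmentError` rather than resampling. The mask raster's
    zero/NoData cells, plus every layer's own NoData cells, are unified
    into one validity mask.
    """
    mask_arr, cs, origin, crs, mask_nd = read_geotiff(mask_path)
    mask = np.isfinite(mask_arr) & (mask_arr != 0)
    if mask_nd is not None:
        mask &= mask_arr != mask_nd

    names: list[str] = []
    layers: list[np.ndarray] = []
    for p in paths:
        p = Path(p)
        arr, cs_i, origin_i, crs_i, nd = read_geotiff(p)
        if arr.shape != mask_arr.shape:
            raise RasterAlignmentError(
                f"{p.name}: shape {arr.shape} != mask shape {mask_arr.shape}"
            )
        if not np.isclose(cs_i, cs) or not np.allclose(origin_i, origin):
            raise RasterAlignmentError(
                f"{p.name}: origin/cell size mismatch "
                f"({origin_i}, {cs_i}) vs ({origin}, {cs})"
            )
        if crs_i != crs:
            raise RasterAlignmentError(f"{p.name}: CRS {crs_i!r} != mask CRS {crs!r}")
        if nd is not None:
            mask &= arr != nd
        mask &= np.isfinite(arr)
        names.append(p.stem)
        layers.append(arr)

    if not mask.any():
        raise ValueError("empty study area: mask has no valid cells")
    return RasterStack(
        names=names,
        grid=np.stack(layers),
        mask=mask,
        cell_size=cs,
        origin=origin,
        crs=crs,
        categorical=set(categorical),
    )


def write_stack(stack: RasterStack, out_dir: str | Path, *, write_mask: bool = True) -> list[Path]:
    """Write each layer (and optionally the mask) as single-band GeoTIFF.

    Masked cells are written as the NoData sentinel; valid cells round-trip
    bit-exactly (float64 storage).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, name in enumerate(stack.names):
        arr = stack.grid[i].copy()
        arr[~stack.mask] = NODATA
        path = out_dir / f"{name}.tif"
        write_geotiff(
            path, arr, cell_size=stack.cell_size, origin=stack.origin, crs=stack.crs
        )
        written.append(path)
    if write_mask:
        path = out_dir / "mask.tif"
        write_geotiff(
            path,
            stack.mask.astype(float),
            cell_size=stack.cell_size,
            origin=stack.origin,
            crs=stack.crs,
        )
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------


def extract_values(stack: RasterStack, points: np.ndarray, *, warn: bool = True):
    """Extract layer values at points.

    Points on masked cells or outside the extent are dropped, never imputed.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        (x, y) map coordinates in the stack's CRS (meters).

    Returns
    -------
    values : ndarray, shape (n_kept, n_layers)
    kept : ndarray of int
        Indices into ``points`` of the rows that were kept.
    n_dropped : int
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    row, col = stack.cell_index(points[:, 0], points[:, 1])
    ny, nx = stack.shape
    inside = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    ok = inside.copy()
    ok[inside] &= stack.mask[row[inside], col[inside]]
    n_dropped = int((~ok).sum())
    if n_dropped and warn:
        warnings.warn(
            f"dropped {n_dropped} point(s) outside the extent or on masked cells",
            stacklevel=2,
        )
    values = stack.grid[:, row[ok], col[ok]].T
    return values, np.nonzero(ok)[0], n_dropped
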