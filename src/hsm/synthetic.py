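"""Synthetic forest landscapes with a known habitat-suitability truth.

Real occurrence data for forest bats are typically confidential, so the
pipeline is exercised on simulated landscapes that mimic their key
statistical features: spatially autocorrelated environmental fields, two
variable stacks describing the same landscape at different levels of
detail (a fine "targeted" stack of structure/composition indices plus a
tree-species-like class layer, and a coarse "generalized" stack of merged
classes and block-averaged structure), a known suitability surface driven
by a sparse subset of the fine variables only, and spatially clustered
presence points.

Random fields use an exponential spatial covariance, simulated exactly by
circulant embedding; every generator is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from numpy.fft import fft2, ifft2

from .raster import RasterStack, extract_values

__all__ = [
    "SyntheticTruth",
    "gaussian_field",
    "make_paired_stacks",
    "sample_presences",
]

# 6 tree-species-like classes merged into 3 coarse classes
# (broadleaf-like, conifer-like, mixed/other), mimicking how a detailed
# tree-species map degrades to a generic land-cover product.
CLASS_MERGE_TABLE: dict[int, int] = {0: 0, 1: 0, 2: 1, 3: 1, 4: 2, 5: 2}


@dataclass
class SyntheticTruth:
    """Known suitability surface and the recipe that generated it."""

    suitability: np.ndarray  # (ny, nx), in [0, 1] on valid cells
    mask: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    coefficients: dict[str, float]  # nonzero generating coefficients
    intercept: float
    detail_map: dict[str, str] = field(default_factory=dict)  # fine -> coarse
    crs: str = "local-meters"

    def as_stack(self) -> RasterStack:
        return RasterStack(
            names=["truth_suitability"],
            grid=self.suitability[None, :, :],
            mask=self.mask,
            cell_size=self.cell_size,
            origin=self.origin,
            crs=self.crs,
        )

    def suitability_at(self, points: np.ndarray) -> np.ndarray:
        vals, kept, _ = extract_values(self.as_stack(), points, warn=False)
        if len(kept) != len(np.atleast_2d(points)):
            raise ValueError("some points fall outside the valid study area")
        return vals[:, 0]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gaussian_field(
    shape: tuple[int, int],
    corr_range: float,
    seed,
    *,
    cell_size: float = 50.0,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with exponential covariance.

    cov(h) = exp(-h / corr_range) with distance h in meters; the empirical
    correlation at lag = corr_range is therefore about exp(-1). Simulated
    by circulant embedding on a doubled grid (exact up to clipping of the
    occasional tiny negative embedding eigenvalue). ``corr_range = 0``
    gives i.i.d. standard normal noise.
    """
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise ValueError("grid dimensions must be positive")
    if corr_range < 0:
        raise ValueError("corr_range must be >= 0")
    rng = _rng(seed)
    if corr_range == 0:
        return rng.standard_normal((ny, nx))
    my, mx = 2 * ny, 2 * nx
    iy = np.minimum(np.arange(my), my - np.arange(my)) * cell_size
    ix = np.minimum(np.arange(mx), mx - np.arange(mx)) * cell_size
    h = np.hypot(iy[:, None], ix[None, :])
    cov = np.exp(-h / corr_range)
    lam = fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal((my, mx)) + 1j * rng.standard_normal((my, mx))
    f = ifft2(np.sqrt(lam) * z)
    # ifft2 normalizes by 1/(mx*my); rescale so each component is N(0, 1)
    field = np.sqrt(mx * my) * f.real
    return field[:ny, :nx]


def _block_mean(arr: np.ndarray, block: int) -> np.ndarray:
    """Average over block x block windows, then paste back to full resolution."""
    ny, nx = arr.shape
    py, px = (-ny) % block, (-nx) % block
    padded = np.pad(arr, ((0, py), (0, px)), mode="edge")
    by, bx = padded.shape[0] // block, padded.shape[1] // block
    means = padded.reshape(by, block, bx, block).mean(axis=(1, 3))
    up = np.repeat(np.repeat(means, block, axis=0), block, axis=1)
    return up[:ny, :nx]


def make_paired_stacks(
    n_fine: int = 12,
    n_coarse: int = 5,
    *,
    shape: tuple[int, int] = (128, 128),
    cell_size: float = 50.0,
    corr_range: float = 300.0,
    seed=0,
    n_true: int = 3,
    coef_scale: float = 1.5,
    intercept: float = -1.0,
    block: int = 8,
    degrade_noise: float = 0.5,
    mask_valid_frac: float = 0.85,
) -> tuple[RasterStack, RasterStack, SyntheticTruth]:
    """Build fine ("targeted") and coarse ("generalized") variable stacks.

    The fine stack holds ``n_fine - 1`` continuous structure/composition
    fields (with realistic inter-variable correlation through shared latent
    fields) plus one tree-species-like class layer with 6 classes. The
    coarse stack holds a 3-class merger of that class layer plus block-mean
    degradations of the first fine continuous fields — the same landscape
    at lower detail. Aggregation over ``block`` x ``block`` windows (400 m
    at the defaults) on fields with a shorter correlation range, plus
    multiplicative-free Gaussian measurement noise of relative magnitude
    ``degrade_noise`` on the aggregated products, emulates how generalized
    products (global canopy height, generic land cover) both smooth away
    and corrupt the stand-scale structure that targeted indices resolve.
    The truth suitability is a logistic function of ``n_true`` FINE
    continuous variables only, so the fine stack carries strictly more
    information about habitat than the coarse one.
    """
    if not n_fine > n_coarse:
        raise ValueError("n_fine must exceed n_coarse")
    if n_coarse < 1:
        raise ValueError("n_coarse must be >= 1")
    n_cont = n_fine - 1
    if n_true > n_cont:
        raise ValueError("n_true cannot exceed the number of continuous fine variables")
    rng = _rng(seed)
    ny, nx = shape

    # landscape mask: smooth field thresholded at a quantile
    mfield = gaussian_field(shape, corr_range, rng, cell_size=cell_size)
    mask = mfield > np.quantile(mfield, 1.0 - mask_valid_frac)

    # Continuous fine variables. The first n_true are independent
    # structural axes (the habitat drivers); the remaining indices are
    # correlated derivatives of shared latent fields, mimicking families
    # of related structure/composition indices.
    n_latent = max(2, (n_cont - n_true) // 3) if n_cont > n_true else 1
    latents = [gaussian_field(shape, corr_range, rng, cell_size=cell_size) for _ in range(n_latent)]
    fine_names, fine_layers = [], []
    for i in range(n_cont):
        own = gaussian_field(shape, corr_range, rng, cell_size=cell_size)
        if i < n_true:
            layer = own
        else:
            a = 0.6 if i % 2 else 0.4
            layer = a * latents[(i - n_true) % n_latent] + np.sqrt(1 - a * a) * own
        fine_names.append(f"struct_{i:02d}")
        fine_layers.append(layer)

    # tree-species-like categorical layer: argmax over 6 latent class fields
    class_fields = np.stack(
        [gaussian_field(shape, corr_range, rng, cell_size=cell_size) for _ in range(6)]
    )
    tree_classes = np.argmax(class_fields, axis=0).astype(float)
    fine_names.append("tree_species")
    fine_layers.append(tree_classes)

    fine = RasterStack(
        names=fine_names,
        grid=np.stack(fine_layers),
        mask=mask,
        cell_size=cell_size,
        origin=(0.0, ny * cell_size),
        categorical={"tree_species"},
    )

    # truth: logistic in a sparse subset of the fine continuous variables
    true_vars = fine_names[:n_true]
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_true)])
    coefs = dict(zip(true_vars, signs * coef_scale))
    lp = intercept + sum(coefs[v] * fine.layer(v) for v in true_vars)
    suitability = 1.0 / (1.0 + np.exp(-lp))

    # coarse stack: merged classes + block-averaged structure layers
    coarse_names, coarse_layers = [], []
    detail_map: dict[str, str] = {}
    merged = np.vectorize(CLASS_MERGE_TABLE.get)(tree_classes.astype(int)).astype(float)
    coarse_names.append("forest_class3")
    coarse_layers.append(merged)
    detail_map["tree_species"] = "forest_class3"
    for i in range(n_coarse - 1):
        src = fine_names[i]
        degraded = _block_mean(fine_layers[i], block)
        if degrade_noise > 0:
            degraded = degraded + degrade_noise * degraded.std() * rng.standard_normal(shape)
        coarse_names.append(f"coarse_{i:02d}")
        coarse_layers.append(degraded)
        detail_map[src] = f"coarse_{i:02d}"

    coarse = RasterStack(
        names=coarse_names,
        grid=np.stack(coarse_layers),
        mask=mask,
        cell_size=cell_size,
        origin=(0.0, ny * cell_size),
        categorical={"forest_class3"},
    )

    truth = SyntheticTruth(
        suitability=suitability,
        mask=mask,
        cell_size=cell_size,
        origin=(0.0, ny * cell_size),
        coefficients=coefs,
        intercept=intercept,
        detail_map=detail_map,
    )
    return fine, coarse, truth


def sample_presences(
    truth: SyntheticTruth,
    n: int,
    clustering: int = 1,
    seed=0,
    *,
    species: str = "synthetic_species",
    cluster_sd_cells: float | None = None,
):
    """Draw presence points with probability proportional to suitability.

    With ``clustering > 1`` the sampling weight is additionally multiplied
    by a sum of Gaussian bumps around ``clustering`` suitability-weighted
    centers, producing the spatially aggregated point pattern needed for
    meaningful spatial folds. ``clustering <= 1`` applies no spatial
    restriction. Points are jittered uniformly within their cell.
    """
    from .swd import OccurrenceSet

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    rows, cols = np.nonzero(truth.mask)
    w = truth.suitability[rows, cols].astype(float)
    if not np.any(w > 0):
        raise ValueError("suitability is identically zero on valid cells")

    ny, nx = truth.mask.shape
    if clustering > 1:
        centers = rng.choice(len(w), size=clustering, replace=False, p=w / w.sum())
        sd = cluster_sd_cells if cluster_sd_cells is not None else 0.08 * min(ny, nx)
        kern = np.zeros_like(w)
        for c in centers:
            d2 = (rows - rows[c]) ** 2 + (cols - cols[c]) ** 2
            kern += np.exp(-0.5 * d2 / sd**2)
        w = w * kern
        if not np.any(w > 0):
            raise ValueError("clustering kernel left no positive sampling weight")

    idx = rng.choice(len(w), size=n, replace=True, p=w / w.sum())
    x0, y0 = truth.origin
    cs = truth.cell_size
    x = x0 + (cols[idx] + rng.uniform(0, 1, n)) * cs
    y = y0 - (rows[idx] + rng.uniform(0, 1, n)) * cs
    return OccurrenceSet(species=species, points=np.column_stack([x, y]), crs=truth.crs)
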