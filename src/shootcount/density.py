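"""Ground-truth density maps from point annotations.

A dot annotation is turned into a non-negative grid whose integral equals
the shoot count by dropping one unit-mass Gaussian on each point.  The
bandwidth of each kernel follows the geometry-adaptive rule: sigma_j is
``beta`` times the mean distance from point j to its k nearest annotated
neighbours, so smoothing tightens where shoots crowd together and widens
where they are sparse.  Kernels are truncated at 4 sigma and renormalized
after boundary clipping, which makes the sum-equals-count invariant exact
rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .annotations_io import PointAnnotation

__all__ = [
    "DensityMap",
    "adaptive_sigmas",
    "render_density",
    "downsample_density",
    "density_from_points",
    "DEFAULT_K",
    "DEFAULT_BETA",
    "FALLBACK_SIGMA",
    "MIN_SIGMA",
]

DEFAULT_K = 3
DEFAULT_BETA = 0.3
#: bandwidth used when a point has fewer than k annotated neighbours (px)
FALLBACK_SIGMA = 4.0
#: floor protecting against coincident duplicate points (px)
MIN_SIGMA = 1.0
#: kernel support radius in units of sigma; <1e-4 mass lies beyond it
TRUNCATE = 4.0


@dataclass
class DensityMap:
    """Non-negative 2-D grid whose sum is the (possibly fractional) count.

    ``stride`` is the downsampling factor relative to the source image:
    grid cell (r, c) covers source pixels ``[r*stride, (r+1)*stride)`` etc.
    """

    grid: np.ndarray
    stride: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.ndim != 2:
            raise ValueError("density grid must be 2-D")
        if (g < 0).any():
            raise ValueError("density grid has negative entries")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        self.grid = g

    @property
    def count(self) -> float:
        return float(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


def adaptive_sigmas(
    points: PointAnnotation | np.ndarray,
    k: int = DEFAULT_K,
    beta: float = DEFAULT_BETA,
    fallback_sigma: float = FALLBACK_SIGMA,
    min_sigma: float = MIN_SIGMA,
) -> np.ndarray:
    """Geometry-adaptive kernel bandwidths, one per point.

    sigma_j = beta * mean distance to the k nearest other points.  Points
    with fewer than k neighbours get ``fallback_sigma``; bandwidths below
    ``min_sigma`` (e.g. from coincident duplicates) are floored.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    pts = points.points if isinstance(points, PointAnnotation) else np.asarray(points, float)
    pts = pts.reshape(-1, 2)
    n = pts.shape[0]
    if n == 0:
        return np.empty(0)
    if n <= k:
        return np.full(n, float(fallback_sigma))
    tree = cKDTree(pts)
    # first neighbour is the point itself
    dists, _ = tree.query(pts, k=k + 1)
    sigmas = beta * dists[:, 1:].mean(axis=1)
    return np.maximum(sigmas, min_sigma)


def render_density(
    points: PointAnnotation | np.ndarray,
    sigmas: np.ndarray,
    shape: tuple[int, int],
    source_id: str = "",
) -> DensityMap:
    """Render unit-mass truncated Gaussians onto a grid of ``shape`` (H, W).

    Each kernel is evaluated on integer pixel centres within 4 sigma of its
    point, clipped at the image boundary, and renormalized so its in-image
    mass is exactly 1; the grid therefore sums to the point count to within
    floating-point accumulation error.
    """
    H, W = int(shape[0]), int(shape[1])
    if H < 1 or W < 1:
        raise ValueError(f"density shape must be at least 1x1, got {shape}")
    pts = points.points if isinstance(points, PointAnnotation) else np.asarray(points, float)
    pts = pts.reshape(-1, 2)
    sigmas = np.asarray(sigmas, dtype=float).ravel()
    if sigmas.shape[0] != pts.shape[0]:
        raise ValueError("need exactly one sigma per point")
    sid = points.image_id if isinstance(points, PointAnnotation) else source_id
    grid = np.zeros((H, W), dtype=np.float64)
    for (x, y), sigma in zip(pts, sigmas):
        r = max(1.0, TRUNCATE * sigma)
        x0, x1 = max(0, int(np.floor(x - r))), min(W - 1, int(np.ceil(x + r)))
        y0, y1 = max(0, int(np.floor(y - r))), min(H - 1, int(np.ceil(y + r)))
        xs = np.arange(x0, x1 + 1, dtype=np.float64)
        ys = np.arange(y0, y1 + 1, dtype=np.float64)
        gx = np.exp(-((xs - x) ** 2) / (2.0 * sigma * sigma))
        gy = np.exp(-((ys - y) ** 2) / (2.0 * sigma * sigma))
        patch = np.outer(gy, gx)
        mass = patch.sum()
        if mass <= 0:  # pathological sigma; fall back to nearest-pixel delta
            grid[min(H - 1, max(0, round(y))), min(W - 1, max(0, round(x)))] += 1.0
            continue
        grid[y0 : y1 + 1, x0 : x1 + 1] += patch / mass
    return DensityMap(grid=grid, stride=1, source_id=sid or source_id)


def downsample_density(d: DensityMap, factor: int) -> DensityMap:
    """Sum-pool a density map by ``factor``, preserving total mass exactly.

    Dimensions not divisible by ``factor`` are zero-padded on the
    bottom/right first; the stride is multiplied accordingly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return DensityMap(d.grid.copy(), d.stride, d.source_id)
    H, W = d.grid.shape
    Hp = -(-H // factor) * factor
    Wp = -(-W // factor) * factor
    g = d.grid
    if (Hp, Wp) != (H, W):
        g = np.zeros((Hp, Wp), dtype=g.dtype)
        g[:H, :W] = d.grid
    pooled = g.reshape(Hp // factor, factor, Wp // factor, factor).sum(axis=(1, 3))
    return DensityMap(pooled, d.stride * factor, d.source_id)


def density_from_points(
    points: PointAnnotation,
    k: int = DEFAULT_K,
    beta: float = DEFAULT_BETA,
    stride: int = 1,
) -> DensityMap:
    """Convenience pipeline: adaptive bandwidths -> render -> optional pooling."""
    sig = adaptive_sigmas(points, k=k, beta=beta)
    dm = render_density(points, sig, (points.height, points.width))
    return downsample_density(dm, stride) if stride > 1 else dm
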