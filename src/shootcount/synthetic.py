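"""Synthetic crown/shoot scene generator.

Produces labeled imagery with the statistical structure the counting
method assumes: one or more non-overlapping elliptical "crowns" on a
textured green background, each crown holding a clustered point process of
"shoots" rendered as small bright blobs.  The local shoot density rises
linearly with normalized image height — expected density at height
h = y/H is proportional to ``1 + perspective_gain * h`` — emulating the
perspective effect in nadir UAV shots where far-from-camera canopy appears
denser.

Clustering is parent–child (Neyman–Scott): cluster centres are uniform in
the crown ellipse and shoots scatter around them with Gaussian spread,
then height-based thinning shapes the vertical density profile.  The
number of shoots per crown is drawn exactly from the configured range, so
the configured mean is the true mean.

Everything is deterministic given ``(config.seed, scene index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations_io import (
    Box,
    BoxAnnotation,
    PointAnnotation,
    save_image,
    write_points,
    write_voc_boxes,
)

__all__ = ["SceneConfig", "SceneGenerationError", "generate_scene", "generate_dataset"]


class SceneGenerationError(RuntimeError):
    pass


@dataclass
class SceneConfig:
    """Parameters of the synthetic stand.

    Ranges are inclusive ``(lo, hi)`` pairs; integer ranges are sampled
    uniformly over integers, real ranges uniformly over the interval.
    """

    image_size: int = 256
    n_crowns: tuple[int, int] = (1, 3)
    crown_radius: tuple[float, float] = (30.0, 60.0)
    shoots_per_crown: tuple[int, int] = (10, 40)
    cluster_spread: float = 4.0
    perspective_gain: float = 2.0
    blob_sigma: float = 1.5
    background_texture_scale: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_crowns", "crown_radius", "shoots_per_crown"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range ({lo}, {hi}) is inverted")
        if self.perspective_gain < 0:
            raise ValueError("perspective_gain must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        if self.cluster_spread <= 0 or self.blob_sigma <= 0:
            raise ValueError("cluster_spread and blob_sigma must be positive")


@dataclass
class _Crown:
    cx: float
    cy: float
    rx: float
    ry: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ((x - self.cx) / self.rx) ** 2 + ((y - self.cy) / self.ry) ** 2 <= 1.0

    @property
    def box(self) -> Box:
        return Box(self.cx - self.rx, self.cy - self.ry, self.cx + self.rx, self.cy + self.ry)


def _place_crowns(cfg: SceneConfig, rng: np.random.Generator) -> list[_Crown]:
    n = int(rng.integers(cfg.n_crowns[0], cfg.n_crowns[1] + 1))
    crowns: list[_Crown] = []
    attempts = 0
    while len(crowns) < n:
        if attempts >= 1000:
            raise SceneGenerationError(
                f"could not place {n} non-overlapping crowns in a "
                f"{cfg.image_size}px image after 1000 attempts; "
                "reduce n_crowns or crown_radius"
            )
        attempts += 1
        rx = rng.uniform(*cfg.crown_radius)
        ry = rx * rng.uniform(0.8, 1.2)
        ry = min(ry, cfg.image_size / 2.0 - 1.0)
        rx = min(rx, cfg.image_size / 2.0 - 1.0)
        cx = rng.uniform(rx, cfg.image_size - rx)
        cy = rng.uniform(ry, cfg.image_size - ry)
        cand = _Crown(cx, cy, rx, ry)
        # conservative overlap check on bounding circles
        ok = all(
            np.hypot(c.cx - cand.cx, c.cy - cand.cy) > max(c.rx, c.ry) + max(rx, ry)
            for c in crowns
        )
        if ok:
            crowns.append(cand)
    return crowns


def _sample_shoots(
    crown: _Crown, n: int, cfg: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Clustered (parent–child) points inside the crown following the height law.

    Cluster centres carry the perspective profile: their vertical positions
    are drawn by stratified inversion of the in-ellipse density
    width(y) * (1 + g*y/H), so the 2-D centre density inside the crown is
    proportional to (1 + g*y/H) with far less sampling noise than
    independent draws would give.  Shoots are then allocated evenly across
    centres and scattered with Gaussian spread, rejected back into the
    ellipse, which leaves the marginal height law intact.
    """
    if n == 0:
        return np.empty((0, 2))
    H = float(cfg.image_size)
    g = cfg.perspective_gain
    k_parents = max(1, int(round(n / 5)))

    # stratified inverse-CDF sampling of parent heights within the ellipse
    ys = np.linspace(crown.cy - crown.ry, crown.cy + crown.ry, 256)
    half_width = crown.rx * np.sqrt(
        np.maximum(0.0, 1.0 - ((ys - crown.cy) / crown.ry) ** 2)
    )
    weight = half_width * (1.0 + g * np.clip(ys, 0.0, H - 1) / H)
    cdf = np.cumsum(weight)
    cdf = cdf / cdf[-1]
    u = (np.arange(k_parents) + rng.uniform(0.0, 1.0, k_parents)) / k_parents
    py = np.interp(u, cdf, ys)
    pw = np.interp(py, ys, half_width)
    px = crown.cx + rng.uniform(-1.0, 1.0, k_parents) * pw
    parents = np.column_stack([px, py])

    # even allocation of shoots to clusters, in shuffled parent order
    order = rng.permutation(k_parents)
    pts: list[tuple[float, float]] = []
    for i in range(n):
        p = parents[order[i % k_parents]]
        x, y = p
        for _ in range(100):
            cx, cy = p + rng.normal(0.0, cfg.cluster_spread, size=2)
            if crown.contains(np.array(cx), np.array(cy)):
                x, y = cx, cy
                break
        pts.append(
            (float(np.clip(x, 0.0, H - 1e-3)), float(np.clip(y, 0.0, H - 1e-3)))
        )
    return np.asarray(pts)


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency green noise so the counter cannot trivially threshold."""
    from scipy import ndimage

    size = cfg.image_size
    coarse = max(2, int(round(size / cfg.background_texture_scale)))
    noise = rng.uniform(0.0, 1.0, size=(coarse, coarse))
    smooth = ndimage.zoom(noise, size / coarse, order=3)[:size, :size]
    smooth = (smooth - smooth.min()) / max(float(np.ptp(smooth)), 1e-9)
    img = np.zeros((size, size, 3))
    img[..., 0] = 25 + 30 * smooth
    img[..., 1] = 70 + 60 * smooth
    img[..., 2] = 25 + 25 * smooth
    return img


def generate_scene(
    cfg: SceneConfig, index: int = 0
) -> tuple[np.ndarray, PointAnnotation, BoxAnnotation]:
    """Render scene ``index``: image, shoot points, and crown boxes.

    Deterministic: the RNG stream is derived from ``(cfg.seed, index)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    size = cfg.image_size
    crowns = _place_crowns(cfg, rng)
    img = _background(cfg, rng)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    all_pts: list[np.ndarray] = []
    for crown in crowns:
        mask = crown.contains(xx, yy)
        # crown canopy: darker, denser green
        img[mask, 0] *= 0.7
        img[mask, 1] = img[mask, 1] * 0.55 + 35
        img[mask, 2] *= 0.7
        n = int(rng.integers(cfg.shoots_per_crown[0], cfg.shoots_per_crown[1] + 1))
        all_pts.append(_sample_shoots(crown, n, cfg, rng))

    pts = np.vstack(all_pts) if all_pts else np.empty((0, 2))
    # shoots: small bright yellow-green blobs
    s = cfg.blob_sigma
    r = max(1, int(np.ceil(3 * s)))
    for x, y in pts:
        x0, x1 = max(0, int(x) - r), min(size - 1, int(x) + r)
        y0, y1 = max(0, int(y) - r), min(size - 1, int(y) + r)
        gx = np.exp(-((np.arange(x0, x1 + 1) - x) ** 2) / (2 * s * s))
        gy = np.exp(-((np.arange(y0, y1 + 1) - y) ** 2) / (2 * s * s))
        blob = np.outer(gy, gx)
        img[y0 : y1 + 1, x0 : x1 + 1, 0] += 140 * blob
        img[y0 : y1 + 1, x0 : x1 + 1, 1] += 160 * blob
        img[y0 : y1 + 1, x0 : x1 + 1, 2] += 60 * blob

    image_id = f"scene_{cfg.seed}_{index:05d}"
    image = np.clip(img, 0, 255).astype(np.uint8)
    points = PointAnnotation(image_id, size, size, pts)
    boxes = BoxAnnotation(image_id, [c.box for c in crowns])
    return image, points, boxes


def generate_dataset(cfg: SceneConfig, n_images: int, out_dir: str | Path) -> pd.DataFrame:
    """Write ``n_images`` scenes (PNG + point CSV + VOC XML) and a manifest.

    The manifest CSV lists one row per scene with its file names, crown
    count and shoot count; the total of the count column equals the sum of
    the per-file point counts by construction (asserted before writing).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        image, points, boxes = generate_scene(cfg, i)
        stem = points.image_id
        save_image(image, out / f"{stem}.png")
        write_points(points, out / f"{stem}.csv")
        write_voc_boxes(boxes, out / f"{stem}.xml", width=cfg.image_size, height=cfg.image_size)
        rows.append(
            {
                "image_id": stem,
                "image": f"{stem}.png",
                "points_file": f"{stem}.csv",
                "boxes_file": f"{stem}.xml",
                "n_crowns": len(boxes),
                "count": points.count,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
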