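"""Voxel carving of a visual hull from calibrated binary silhouettes.

The visual hull is the largest volume consistent with every silhouette: a
voxel survives iff its centre projects to a foreground pixel in every view.
Reconstruction quality is scored by reprojecting the carved hull back into
each view and computing the Dice overlap with the input silhouette; hulls
whose aggregate score falls below an acceptance threshold (default 0.70), or
whose skeleton is not a tree, are rejected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .camera import CalibratedView
from .synthetic_plant import SilhouetteSet

Array = np.ndarray

__all__ = [
    "VoxelGrid", "ReconstructionScore", "carve", "reproject", "dice",
    "score_reconstruction", "accept_reconstruction", "add_noise_blobs",
]

DICE_THRESHOLD = 0.70


@dataclass
class VoxelGrid:
    """Cubic occupancy grid with physical scale.

    ``occupancy[i, j, k]`` covers the world cube
    ``origin + ([i, j, k] + [0, 1]) * voxel_size``.
    """

    occupancy: Array
    voxel_size: float
    origin: Array

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D array")
        if min(self.occupancy.shape) < 8:
            raise ValueError("grid resolution must be at least 8 voxels per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def resolution(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def occupied_centers(self) -> Array:
        idx = np.argwhere(self.occupancy)
        return self.origin + (idx + 0.5) * self.voxel_size

    def world_to_index(self, points: Array) -> Array:
        return np.floor((np.atleast_2d(points) - self.origin) / self.voxel_size).astype(int)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), occupancy=self.occupancy)
        sidecar = {"voxel_size": self.voxel_size, "origin": self.origin.tolist(),
                   "resolution": list(self.occupancy.shape)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelGrid":
        path = Path(path)
        occ = np.load(path.with_suffix(".npz"))["occupancy"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(occupancy=occ, voxel_size=meta["voxel_size"],
                   origin=np.asarray(meta["origin"]))


@dataclass(frozen=True)
class ReconstructionScore:
    """Per-view and aggregate silhouette-reprojection Dice scores."""

    per_view: dict[str, float]
    aggregate: float
    threshold: float = DICE_THRESHOLD

    @property
    def accepted(self) -> bool:
        return self.aggregate >= self.threshold


def default_grid_spec(world_extent: float, resolution: int) -> tuple[float, Array]:
    """Voxel size and origin for a cube of side ``world_extent`` sitting on z=0."""
    vs = world_extent / resolution
    origin = np.array([-world_extent / 2.0, -world_extent / 2.0, 0.0])
    return vs, origin


def carve(silhouettes: SilhouetteSet, views: list[CalibratedView] | None = None, *,
          resolution: int = 128, world_extent: float | None = None,
          voxel_size: float | None = None, origin: Array | None = None,
          chunk_voxels: int = 4_000_000) -> VoxelGrid:
    """Intersect the silhouette cones of all views on a voxel grid.

    A voxel is kept iff its centre projects inside the foreground mask of
    every view (membership sampled at the nearest pixel).  An empty
    intersection is legal and produces an empty grid with a warning.
    """
    views = list(views) if views is not None else list(silhouettes.views)
    if len(views) < 2:
        raise ValueError("carving requires at least two views")
    if len(views) != len(silhouettes.masks):
        raise ValueError("number of masks must match number of views")
    for mask, view in zip(silhouettes.masks, views):
        if tuple(mask.shape) != tuple(view.image_shape):
            raise ValueError(f"mask shape {mask.shape} does not match view "
                             f"{view.label!r} image {view.image_shape}")
    if voxel_size is None or origin is None:
        if world_extent is None:
            if silhouettes.rig is None:
                raise ValueError("world_extent required when silhouettes carry no rig")
            world_extent = silhouettes.rig.world_extent
        voxel_size, origin = default_grid_spec(world_extent, resolution)
    origin = np.asarray(origin, dtype=float)

    n = resolution
    axes = [origin[d] + (np.arange(n) + 0.5) * voxel_size for d in range(3)]
    occ = np.empty((n, n, n), dtype=bool)
    slab = max(1, chunk_voxels // (n * n))
    for k0 in range(0, n, slab):
        k1 = min(k0 + slab, n)
        gx, gy, gz = np.meshgrid(axes[0], axes[1], axes[2][k0:k1], indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        keep = np.ones(len(pts), dtype=bool)
        for mask, view in zip(silhouettes.masks, views):
            rows, cols = view.project(pts[keep])
            ri = np.rint(rows).astype(np.int64)
            ci = np.rint(cols).astype(np.int64)
            h, w = view.image_shape
            inside = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
            hit = np.zeros(inside.shape, dtype=bool)
            hit[inside] = mask[ri[inside], ci[inside]]
            keep[keep.copy()] = hit
            if not keep.any():
                break
        occ[:, :, k0:k1] = keep.reshape(n, n, k1 - k0)
    grid = VoxelGrid(occupancy=occ, voxel_size=voxel_size, origin=origin)
    if grid.n_occupied == 0:
        warnings.warn("visual hull is empty: silhouettes have no common intersection",
                      stacklevel=2)
    return grid


def reproject(grid: VoxelGrid, view: CalibratedView,
              image_shape: tuple[int, int] | None = None,
              mode: str = "footprint") -> Array:
    """Project the occupied voxels of a grid into a view's image plane.

    ``mode="center"`` marks, for each occupied voxel, the pixel nearest its
    projected centre; this is the exact adjoint of the carving membership
    test, so the result is a subset of each input mask.  ``mode="footprint"``
    additionally dilates by the projected voxel footprint, approximating the
    set of pixels whose viewing ray intersects the hull.
    """
    if mode not in ("center", "footprint"):
        raise ValueError(f"unknown reprojection mode {mode!r}")
    shape = tuple(image_shape) if image_shape is not None else tuple(view.image_shape)
    mask = np.zeros(shape, dtype=bool)
    centers = grid.occupied_centers()
    if len(centers) == 0:
        return mask
    rows, cols = view.project(centers)
    ri = np.rint(rows).astype(np.int64)
    ci = np.rint(cols).astype(np.int64)
    inside = (ri >= 0) & (ri < shape[0]) & (ci >= 0) & (ci < shape[1])
    mask[ri[inside], ci[inside]] = True
    if mode == "footprint":
        hr, hc = view.footprint_halfwidth_px(grid.voxel_size)
        size = (2 * int(np.floor(hr + 0.5)) + 1, 2 * int(np.floor(hc + 0.5)) + 1)
        if size != (1, 1):
            mask = ndimage.binary_dilation(mask, structure=np.ones(size, dtype=bool))
    return mask


def dice(mask_a: Array, mask_b: Array) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def score_reconstruction(grid: VoxelGrid, silhouettes: SilhouetteSet,
                         views: list[CalibratedView] | None = None,
                         mode: str = "center", pooling: str = "mean",
                         threshold: float = DICE_THRESHOLD) -> ReconstructionScore:
    """Dice between the reprojected hull and each input silhouette.

    ``pooling="mean"`` averages per-view Dice values (a single accuracy score
    per reconstruction); ``pooling="pixels"`` pools pixels across views before
    computing one Dice value.
    """
    views = list(views) if views is not None else list(silhouettes.views)
    per_view: dict[str, float] = {}
    inter = total = 0
    for mask, view in zip(silhouettes.masks, views):
        re = reproject(grid, view, image_shape=mask.shape, mode=mode)
        per_view[view.label] = dice(re, mask)
        inter += int((re & mask).sum())
        total += int(re.sum()) + int(mask.sum())
    if pooling == "mean":
        aggregate = float(np.mean(list(per_view.values()))) if per_view else 0.0
    elif pooling == "pixels":
        aggregate = 1.0 if total == 0 else 2.0 * inter / total
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return ReconstructionScore(per_view=per_view, aggregate=aggregate,
                               threshold=threshold)


def accept_reconstruction(score: ReconstructionScore, topology_ok: bool) -> bool:
    """Keep a reconstruction iff its score clears the threshold (inclusive)
    and its skeleton has tree topology."""
    return bool(score.accepted and topology_ok)


def add_noise_blobs(grid: VoxelGrid, n_blobs: int = 3, size_vox: int = 4,
                    seed: int = 0) -> VoxelGrid:
    """Attach small random voxel blobs to the hull surface (noise model).

    Each blob is a short random walk seeded at a random occupied surface
    voxel, emulating segmentation noise that produces spurious skeleton
    branches.
    """
    rng = np.random.default_rng(seed)
    occ = grid.occupancy.copy()
    surface = occ & ~ndimage.binary_erosion(occ)
    candidates = np.argwhere(surface)
    if len(candidates) == 0:
        return VoxelGrid(occ, grid.voxel_size, grid.origin.copy())
    shape = np.array(occ.shape)
    for _ in range(n_blobs):
        pos = candidates[rng.integers(len(candidates))].copy()
        for _ in range(size_vox):
            step = rng.integers(-1, 2, size=3)
            pos = np.clip(pos + step, 0, shape - 1)
            occ[tuple(pos)] = True
    return VoxelGrid(occ, grid.voxel_size, grid.origin.copy())
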