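"""Drill-canal estimation from the pre/post difference image.

The carved canal shows up as a tube of large positive values in
``pre - post_registered``.  Segmentation keeps the largest connected
component above a difference threshold; the axis is the first principal
component of the surviving voxel coordinates weighted by difference
magnitude (weighting suppresses rim artifacts); endpoints are then refined
to sub-voxel precision with a half-maximum edge rule, standing in for the
interactive fine-tuning a human operator would perform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume, DensityProfile, DrillPath, SpecimenMeta

__all__ = [
    "VoxelCloud",
    "difference_volume",
    "segment_canal",
    "estimate_axis_pca",
    "refine_endpoints",
    "cylinder_mask",
    "extract_profile",
    "disk_stencil",
]

MIN_CANAL_VOXELS = 20
EIGENRATIO_MIN = 4.0


@dataclass
class VoxelCloud:
    """Weighted voxel set in world coordinates, with the source grid bounds."""

    points: np.ndarray    # (N, 3) world mm
    weights: np.ndarray   # (N,) positive
    bounds_lo: np.ndarray
    bounds_hi: np.ndarray

    def __len__(self) -> int:
        return len(self.weights)


def difference_volume(pre: CTVolume, post_registered: CTVolume) -> CTVolume:
    """Voxelwise ``pre - post`` (positive where bone was removed)."""
    if not pre.same_grid(post_registered):
        raise ValueError("difference requires volumes on the same grid")
    return CTVolume(
        pre.data - post_registered.data, pre.spacing.copy(), pre.origin.copy()
    )


def segment_canal(diff: CTVolume, threshold_hu: float = 400.0) -> VoxelCloud:
    """Threshold the difference image and keep the largest 26-connected blob.

    The default 400 HU clears trabecular/partial-volume noise while keeping
    the canal core (bone-minus-air differences exceed 1000 HU); isolated
    segmentation artifacts fall into smaller components and are dropped.
    """
    if threshold_hu <= 0:
        raise ValueError("threshold_hu must be positive")
    mask = diff.data >= threshold_hu
    if mask.sum() < MIN_CANAL_VOXELS:
        raise ValueError(
            f"canal not detected: only {int(mask.sum())} voxels >= {threshold_hu} HU"
        )
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    if mask.sum() < MIN_CANAL_VOXELS:
        raise ValueError(
            f"canal not detected: largest component has {int(mask.sum())} voxels"
        )
    idx = np.argwhere(mask)
    return VoxelCloud(
        points=diff.index_to_world(idx),
        weights=diff.data[mask].astype(np.float64),
        bounds_lo=diff.origin.copy(),
        bounds_hi=diff.world_max.copy(),
    )


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Inverse empirical CDF: smallest value whose cumulative weight >= q.

    The step convention matters at the extremes: trimming less than one
    voxel's worth of weight must keep the extreme voxels."""
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    idx = int(np.searchsorted(cw, q * cw[-1], side="left"))
    return float(v[min(idx, len(v) - 1)])


def estimate_axis_pca(voxels: VoxelCloud, radius: float = 1.525) -> DrillPath:
    """Fit the canal axis by weighted principal component analysis.

    The axis is the dominant eigenvector of the weighted coordinate
    covariance; provisional endpoints are the 0.5% / 99.5% weighted
    quantiles of the axial projections (robust to stray voxels).  The path
    is oriented so that ``start`` is the endpoint nearer the volume
    boundary — the drill's entry side.
    """
    if len(voxels) < MIN_CANAL_VOXELS:
        raise ValueError(f"need >= {MIN_CANAL_VOXELS} voxels, got {len(voxels)}")
    w = voxels.weights / voxels.weights.sum()
    centroid = w @ voxels.points
    centered = voxels.points - centroid
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] < EIGENRATIO_MIN * max(evals[-2], 1e-300):
        raise ValueError(
            "no dominant axis: first-to-second eigenvalue ratio "
            f"{evals[-1] / max(evals[-2], 1e-300):.2f} < {EIGENRATIO_MIN}"
        )
    axis = evecs[:, -1]
    proj = centered @ axis
    q = 0.005
    lo = _weighted_quantile(proj, voxels.weights, q)
    hi = _weighted_quantile(proj, voxels.weights, 1.0 - q)
    p_lo = centroid + lo * axis
    p_hi = centroid + hi * axis

    def boundary_distance(p: np.ndarray) -> float:
        return float(
            np.min(np.minimum(p - voxels.bounds_lo, voxels.bounds_hi - p))
        )

    if boundary_distance(p_hi) < boundary_distance(p_lo):
        p_lo, p_hi = p_hi, p_lo
    return DrillPath(p_lo, p_hi, radius)


def disk_stencil(radius: float, n_ring: int = 6) -> np.ndarray:
    """In-plane offsets (K, 2): centre + rings of ``n_ring`` points at r/2 and r."""
    angles = np.arange(n_ring) * (2 * np.pi / n_ring)
    ring = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    return np.vstack([[0.0, 0.0], 0.5 * radius * ring, radius * ring])


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane perpendicular to the axis."""
    e = np.zeros(3)
    e[int(np.argmin(np.abs(direction)))] = 1.0
    u = np.cross(direction, e)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def _disk_points(path: DrillPath, s: np.ndarray, stencil: np.ndarray) -> np.ndarray:
    """World sample points (len(s), K, 3) for a stencil swept along the path."""
    u, v = _plane_basis(path.direction)
    centers = path.point_at(s)  # (n, 3)
    offsets = stencil[:, 0:1] * u + stencil[:, 1:2] * v  # (K, 3)
    return centers[:, None, :] + offsets[None, :, :]


def refine_endpoints(
    diff: CTVolume, path: DrillPath, step: float = 0.05, cap_mm: float = 2.0
) -> DrillPath:
    """Refine both endpoints with a half-maximum edge rule.

    Each endpoint is walked along the axis (``step`` mm increments, at most
    ``cap_mm`` either way) and placed where the disk-mean of the difference
    image first falls below 50% of the canal's median disk-mean.  If no
    crossing is found within the cap the provisional endpoint is kept and a
    warning emitted.
    """
    stencil = disk_stencil(path.radius)
    L = path.length

    def disk_means(s_grid: np.ndarray) -> np.ndarray:
        pts = _disk_points(path, s_grid, stencil)
        return diff.sample(pts.reshape(-1, 3)).reshape(len(s_grid), -1).mean(axis=1)

    interior = np.linspace(0.1 * L, 0.9 * L, 33)
    ref = float(np.median(disk_means(interior)))
    half = 0.5 * ref

    def edge(s_grid: np.ndarray, provisional_s: float) -> float:
        means = disk_means(s_grid)
        below = means < half
        if not below.any():
            warnings.warn(
                "no half-maximum crossing within cap; keeping provisional endpoint",
                stacklevel=3,
            )
            return provisional_s
        j = int(np.argmax(below))
        if j == 0:
            return float(s_grid[0])
        # linear interpolation to the crossing
        m0, m1 = means[j - 1], means[j]
        frac = (m0 - half) / (m0 - m1) if m1 != m0 else 1.0
        return float(s_grid[j - 1] + frac * (s_grid[j] - s_grid[j - 1]))

    # Walk each endpoint outward from inside the canal: start from s = +cap
    # down through s = -cap, end from s = L - cap up through s = L + cap.
    n_steps = int(round(cap_mm / step))
    grid_start = np.arange(n_steps, -n_steps - 1, -1) * step
    s_start = edge(grid_start, 0.0)
    grid_end = L + np.arange(-n_steps, n_steps + 1) * step
    s_end = edge(grid_end, L)

    if s_end <= s_start:
        warnings.warn("endpoint refinement degenerate; keeping provisional path",
                      stacklevel=2)
        return path
    return DrillPath(path.point_at(s_start), path.point_at(s_end), path.radius)


def cylinder_mask(grid_of: CTVolume, path: DrillPath) -> np.ndarray:
    """Binary mask: voxel centres within ``radius`` of the axis segment."""
    ix, iy, iz = np.indices(grid_of.shape, dtype=np.float64)
    rel = np.stack(
        [
            grid_of.origin[0] + ix * grid_of.spacing[0] - path.start[0],
            grid_of.origin[1] + iy * grid_of.spacing[1] - path.start[1],
            grid_of.origin[2] + iz * grid_of.spacing[2] - path.start[2],
        ],
        axis=-1,
    )
    t_ax = rel @ path.direction
    d2 = np.einsum("...i,...i", rel, rel) - t_ax**2
    mask = (d2 <= path.radius**2) & (t_ax >= 0.0) & (t_ax <= path.length)
    if not mask.any():
        raise ValueError("empty mask: cylinder does not cover any voxel centre")
    return mask


def max_back_extension(volume: CTVolume, path: DrillPath, margin_mm: float | None = None) -> float:
    """How far (mm) the path start can be extended backwards along the axis
    while keeping a stencil of ``radius`` inside the volume."""
    if margin_mm is None:
        margin_mm = path.radius + float(np.max(volume.spacing))
    lo = volume.origin + margin_mm
    hi = volume.world_max - margin_mm
    d = path.direction
    u_max = np.inf
    for i in range(3):
        if d[i] > 1e-12:
            u_max = min(u_max, (path.start[i] - lo[i]) / d[i])
        elif d[i] < -1e-12:
            u_max = min(u_max, (path.start[i] - hi[i]) / d[i])
    return float(max(0.0, u_max))


def extract_profile(
    pre: CTVolume,
    path: DrillPath,
    ds: float = 0.1,
    disk_points: int = 13,
    meta: SpecimenMeta | None = None,
) -> DensityProfile:
    """Sample the density profile along the path from the pre volume.

    At each arc position ``s in {0, ds, ..., L}`` a fixed stencil (axis
    point plus two concentric 6-point rings at r/2 and r) is trilinearly
    sampled on the plane perpendicular to the axis; mean, min and max over
    the stencil form the profile channels.  The number of steps is
    ``floor(L / ds) + 1``.
    """
    if disk_points not in (1, 7, 13):
        raise ValueError("disk_points must be 1, 7 or 13 (centre plus 6-point rings)")
    n = int(np.floor(path.length / ds + 1e-9)) + 1
    s = np.arange(n) * ds
    stencil = disk_stencil(path.radius)[:disk_points]
    pts = _disk_points(path, s, stencil)  # (n, K, 3)
    inside = pre.contains(pts.reshape(-1, 3)).reshape(n, -1)
    if not inside.all():
        bad = int(np.argmin(inside.all(axis=1)))
        raise ValueError(
            f"stencil point outside volume at s = {s[bad]:.2f} mm"
        )
    vals = pre.sample(pts.reshape(-1, 3)).reshape(n, -1)
    return DensityProfile(
        s=s,
        mean=vals.mean(axis=1),
        min=vals.min(axis=1),
        max=vals.max(axis=1),
        unit="HU",
        meta=meta,
    )
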