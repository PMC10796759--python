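"""Rigid registration of post- onto pre-interventional volumes.

Both scans come from the same scanner and protocol, so the metric is the
masked mean squared HU difference (no mutual information needed).  The
search is a multi-resolution pyramid (downsample factors 4, 2, 1) with a
derivative-free Powell refinement at each level; the optional ``init``
transform plays the role of a manual coarse pre-alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter
from scipy.optimize import minimize

from .core import AIR_HU, CTVolume, RigidTransform

__all__ = ["RegistrationConfig", "resample", "register_rigid"]


def resample(volume: CTVolume, transform: RigidTransform) -> CTVolume:
    """Resample a volume through a rigid transform (pull semantics).

    The output voxel at world position x takes the trilinearly interpolated
    value of the input at ``transform(x)``; out-of-field voxels are filled
    with air (-1000 HU).  Grid spacing and origin are unchanged.  An exact
    identity transform returns a value-identical copy.
    """
    if transform.is_identity():
        return volume.copy()
    R = transform.matrix
    S = np.diag(volume.spacing)
    Sinv = np.diag(1.0 / volume.spacing)
    matrix = Sinv @ R @ S
    offset = Sinv @ (
        R @ (volume.origin - transform.center)
        + transform.center
        + transform.translation
        - volume.origin
    )
    data = affine_transform(
        volume.data, matrix, offset=offset, order=1, mode="constant", cval=AIR_HU
    )
    return CTVolume(data, volume.spacing.copy(), volume.origin.copy())


@dataclass
class RegistrationConfig:
    pyramid: tuple[int, ...] = (4, 2, 1)
    mask_threshold_hu: float = -500.0  # body mask: everything denser than air
    max_points_per_level: int = 20000
    maxiter: int = 60
    xtol: float = 1e-4
    ftol: float = 1e-7
    min_overlap: float = 0.5
    # Search bounds around the initialisation.  Repeat scans of the same
    # specimen are misaligned by at most a few degrees / millimetres; a
    # bounded search keeps the optimizer away from spurious far-field
    # minima (e.g. near-symmetric 180 degree flips of a smooth body).
    rotation_bound_deg: float = 15.0
    translation_bound_mm: float = 20.0


@dataclass
class RegistrationReport:
    """Per-level metric bookkeeping from one registration run."""

    level_factors: list[int] = field(default_factory=list)
    initial_metrics: list[float] = field(default_factory=list)
    final_metrics: list[float] = field(default_factory=list)
    converged: bool = True


def _downsample(volume: CTVolume, factor: int) -> CTVolume:
    if factor == 1:
        return volume
    smoothed = gaussian_filter(volume.data, sigma=factor / 2.0)
    data = smoothed[::factor, ::factor, ::factor]
    # Strided voxel centres coincide with original voxel centres, so the
    # origin is unchanged and spacing scales by the factor.
    return CTVolume(data, volume.spacing * factor, volume.origin.copy())


def _mask_points(
    volume: CTVolume, threshold: float, max_points: int
) -> tuple[np.ndarray, np.ndarray]:
    mask = volume.data > threshold
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise ValueError(
            f"no voxels in body mask (HU > {threshold}); cannot register"
        )
    if idx.shape[0] > max_points:
        stride = int(np.ceil(idx.shape[0] / max_points))
        idx = idx[::stride]
    pts = volume.index_to_world(idx)
    vals = volume.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return pts, vals


def register_rigid(
    fixed: CTVolume,
    moving: CTVolume,
    init: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
    full_output: bool = False,
):
    """Find the rigid transform aligning ``moving`` onto ``fixed``.

    Returns the transform T minimising the mean squared HU difference
    between ``resample(moving, T)`` and ``fixed`` over the fixed volume's
    body mask.  Rotation centre is the fixed volume's world centre; angles
    in degrees applied x-then-y-then-z.  ``init`` (any centre) provides the
    coarse manual pre-alignment; identity by default.
    """
    if fixed.shape != moving.shape or not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("fixed and moving volumes must share grid shape and spacing")
    cfg = config or RegistrationConfig()
    center = fixed.world_center
    if init is None:
        p0 = np.zeros(6)
    else:
        p0 = init.with_center(center).params.copy()
    init_params = p0.copy()

    report = RegistrationReport()

    def metric(params: np.ndarray, fvol_pts, fvol_vals, mvol) -> float:
        T = RigidTransform(params[:3], params[3:], center)
        mv = mvol.sample(T.apply(fvol_pts))
        return float(np.mean((mv - fvol_vals) ** 2))

    first_level = True
    for factor in cfg.pyramid:
        fvol = _downsample(fixed, factor)
        mvol = _downsample(moving, factor)
        pts, vals = _mask_points(fvol, cfg.mask_threshold_hu, cfg.max_points_per_level)

        if first_level:
            T0 = RigidTransform(p0[:3], p0[3:], center)
            inside = mvol.contains(T0.apply(pts))
            if inside.mean() < cfg.min_overlap:
                raise ValueError(
                    f"initial overlap {inside.mean():.0%} below "
                    f"{cfg.min_overlap:.0%}; provide a better init"
                )
            first_level = False

        if factor == cfg.pyramid[-1] and init is not None:
            # Guard against a coarse level having wandered below the
            # user-provided initialisation.
            if metric(init_params, pts, vals, mvol) < metric(p0, pts, vals, mvol):
                p0 = init_params.copy()

        m0 = metric(p0, pts, vals, mvol)
        bounds = [
            (c - cfg.rotation_bound_deg, c + cfg.rotation_bound_deg)
            for c in init_params[:3]
        ] + [
            (c - cfg.translation_bound_mm, c + cfg.translation_bound_mm)
            for c in init_params[3:]
        ]
        res = minimize(
            metric,
            p0,
            args=(pts, vals, mvol),
            method="Powell",
            bounds=bounds,
            options={"maxiter": cfg.maxiter, "xtol": cfg.xtol, "ftol": cfg.ftol},
        )
        p0 = np.asarray(res.x, dtype=np.float64)
        report.level_factors.append(factor)
        report.initial_metrics.append(m0)
        report.final_metrics.append(float(res.fun))
        if not res.success and res.status != 1:  # status 1 = maxiter reached
            report.converged = False
    if not report.converged:
        warnings.warn(
            "registration did not converge; returning best transform found",
            stacklevel=2,
        )

    result = RigidTransform(p0[:3], p0[3:], center)
    if full_output:
        return result, report
    return result
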