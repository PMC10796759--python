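"""Core geometric types shared by every stage of the pipeline.

Conventions (fixed package-wide):

* World coordinates are in millimetres; voxel indices are 0-based.
* A voxel's value lives at its centre: ``world = origin + index * spacing``.
* Volumes are axis-aligned; the data array is indexed ``[ix, iy, iz]`` with
  axis *i* mapping to world axis *x*, etc.
* Continuous positions are interpolated trilinearly.
* Rigid rotations are Euler angles in degrees applied x-then-y-then-z
  (``R = Rz @ Ry @ Rx``) about a stated centre point, followed by a
  translation in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

AIR_HU = -1000.0

__all__ = [
    "AIR_HU",
    "CTVolume",
    "RigidTransform",
    "DrillPath",
    "DensityProfile",
    "ForceTrace",
    "SpecimenMeta",
    "AlignedPair",
    "CorrelationResult",
]


@dataclass
class CTVolume:
    """A 3-D scalar grid of CT intensities (Hounsfield units).

    Parameters
    ----------
    data:
        3-D array of HU values; may be fractional after resampling.
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"all volume dims must be >= 2, got {self.data.shape}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def world_center(self) -> np.ndarray:
        """World coordinate of the grid centre (mm)."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    @property
    def world_max(self) -> np.ndarray:
        """World coordinate of the last voxel centre (mm)."""
        return self.origin + (np.array(self.shape) - 1) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (points - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return self.origin + indices * self.spacing

    def contains(self, points: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        """True where world points fall inside the voxel-centre bounding box."""
        pts = np.atleast_2d(points)
        lo = self.origin + margin_mm
        hi = self.world_max - margin_mm
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def sample(self, points: np.ndarray, fill: float = AIR_HU) -> np.ndarray:
        """Trilinearly interpolate HU at world points (..., 3) -> (...)."""
        pts = np.asarray(points, dtype=np.float64)
        lead = pts.shape[:-1]
        idx = self.world_to_index(pts.reshape(-1, 3))
        vals = map_coordinates(self.data, idx.T, order=1, mode="constant", cval=fill)
        return vals.reshape(lead) if lead else vals[0]

    def same_grid(self, other: "CTVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "CTVolume":
        return CTVolume(self.data.copy(), self.spacing.copy(), self.origin.copy())


def _rotation_matrix(rotation_deg: np.ndarray) -> np.ndarray:
    """R = Rz @ Ry @ Rx for Euler angles in degrees (x applied first)."""
    rx, ry, rz = np.deg2rad(np.asarray(rotation_deg, dtype=np.float64))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _euler_from_matrix(R: np.ndarray) -> np.ndarray:
    """Recover (rx, ry, rz) in degrees from R = Rz @ Ry @ Rx.

    Assumes |ry| < 90 deg, which covers every transform this pipeline
    produces (misalignments between repeat scans are a few degrees).
    """
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    cy = np.cos(ry)
    if abs(cy) < 1e-12:  # gimbal lock; not reachable for small-angle use
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    else:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    return np.rad2deg(np.array([rx, ry, rz]))


@dataclass
class RigidTransform:
    """Rotation about ``center`` plus translation: ``T(p) = R(p-c) + c + t``."""

    rotation_deg: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=np.float64).reshape(3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if not (
            np.all(np.isfinite(self.rotation_deg))
            and np.all(np.isfinite(self.translation))
        ):
            raise ValueError("transform parameters must be finite")

    @classmethod
    def identity(cls, center: np.ndarray | None = None) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.zeros(3) if center is None else center)

    @property
    def matrix(self) -> np.ndarray:
        return _rotation_matrix(self.rotation_deg)

    @property
    def params(self) -> np.ndarray:
        """(rx, ry, rz, tx, ty, tz) in degrees / mm."""
        return np.concatenate([self.rotation_deg, self.translation])

    def is_identity(self, atol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.params) <= atol))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.matrix.T
        return RigidTransform(
            _euler_from_matrix(Rinv), -(Rinv @ self.translation), self.center
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``.

        Both must share the same centre.
        """
        if not np.allclose(self.center, other.center):
            raise ValueError("can only compose transforms about the same center")
        R = self.matrix @ other.matrix
        t = self.matrix @ other.translation + self.translation
        return RigidTransform(_euler_from_matrix(R), t, self.center)

    def with_center(self, center: np.ndarray) -> "RigidTransform":
        """Same mapping re-expressed about a different rotation centre."""
        center = np.asarray(center, dtype=np.float64).reshape(3)
        # T(p) = R(p - c) + c + t = R(p - c') + c' + t'  with
        # t' = R(c' - c) + c + t - c'
        t_new = self.matrix @ (center - self.center) + self.center + self.translation - center
        return RigidTransform(self.rotation_deg.copy(), t_new, center)


@dataclass
class DrillPath:
    """Oriented canal segment in world mm.

    ``radius`` defaults to 1.525 mm, half the 3.05 mm outer diameter of an
    11-gauge hollow drilling tool.
    """

    start: np.ndarray
    end: np.ndarray
    radius: float = 1.525

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.float64).reshape(3)
        self.end = np.asarray(self.end, dtype=np.float64).reshape(3)
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.length <= 0:
            raise ValueError("path must have positive length")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        return (self.end - self.start) / self.length

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """World point(s) at arc position s (mm from start); s may exceed [0, L]."""
        s = np.asarray(s, dtype=np.float64)
        return self.start + np.multiply.outer(s, self.direction)

    def reversed(self) -> "DrillPath":
        return DrillPath(self.end.copy(), self.start.copy(), self.radius)

    def extended(self, before_mm: float = 0.0, after_mm: float = 0.0) -> "DrillPath":
        d = self.direction
        return DrillPath(self.start - before_mm * d, self.end + after_mm * d, self.radius)


@dataclass
class SpecimenMeta:
    """Specimen labels: donor individual, spine region and vertebral level."""

    individual: str
    region: str
    level: str

    def __post_init__(self) -> None:
        if self.region not in ("T", "L"):
            raise ValueError(f"region must be 'T' or 'L', got {self.region!r}")
        if not self.level.upper().startswith(self.region):
            raise ValueError(
                f"level {self.level!r} inconsistent with region {self.region!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.individual}_{self.level}"


@dataclass
class DensityProfile:
    """Arc-length-indexed intensity series along a drill path.

    Channels are per-step aggregates over the canal cross-section disk:
    mean, min and max.  ``unit`` is "HU" on extraction and "GV" after the
    gray-value conversion.
    """

    s: np.ndarray
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    unit: str = "HU"
    meta: SpecimenMeta | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.min = np.asarray(self.min, dtype=np.float64)
        self.max = np.asarray(self.max, dtype=np.float64)
        n = len(self.s)
        if not (len(self.mean) == len(self.min) == len(self.max) == n):
            raise ValueError("profile channels must have equal length")
        if n and (self.s[0] != 0.0 or np.any(np.diff(self.s) <= 0)):
            raise ValueError("s must start at 0 and be strictly increasing")
        if n:
            # tolerance absorbs float rounding of the mean aggregate
            tol = 1e-9 * max(1.0, float(np.max(np.abs(self.max))))
            if np.any((self.min > self.mean + tol) | (self.mean > self.max + tol)):
                raise ValueError("channel order violated: need min <= mean <= max")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def ds(self) -> float:
        return float(self.s[1] - self.s[0])

    def channel(self, name: str) -> np.ndarray:
        if name not in ("mean", "min", "max"):
            raise ValueError(f"unknown channel {name!r}")
        return getattr(self, name)

    def with_channels(
        self, mean: np.ndarray, min: np.ndarray, max: np.ndarray, unit: str | None = None
    ) -> "DensityProfile":
        return DensityProfile(
            self.s.copy(), mean, min, max, self.unit if unit is None else unit, self.meta
        )


@dataclass
class ForceTrace:
    """Axial drilling force sampled uniformly in time at constant feed.

    The feed velocity converts sample times to displacement:
    ``x = feed_velocity * t`` (mm).
    """

    t: np.ndarray
    F: np.ndarray
    sample_rate: float = 1000.0
    feed_velocity: float = 2.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.F = np.asarray(self.F, dtype=np.float64)
        if len(self.t) != len(self.F):
            raise ValueError("t and F must have equal length")
        if len(self.t) < 2:
            raise ValueError("trace must have at least 2 samples")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("force values must be finite")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6):
            raise ValueError("non-uniform sampling: t must advance by 1/sample_rate")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AlignedPair:
    """Intensity and force series on a common arc grid, both min-max normalized."""

    s: np.ndarray
    intensity_norm: np.ndarray
    force_norm: np.ndarray
    shift_mm: float
    meta: SpecimenMeta | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        self.intensity_norm = np.asarray(self.intensity_norm, dtype=np.float64)
        self.force_norm = np.asarray(self.force_norm, dtype=np.float64)
        if not (len(self.s) == len(self.intensity_norm) == len(self.force_norm)):
            raise ValueError("aligned pair channels must have equal length")
        if len(self.s) < 10:
            raise ValueError(f"aligned pair too short: n={len(self.s)} < 10")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        for name in ("intensity_norm", "force_norm"):
            v = getattr(self, name)
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError(f"{name} not within [0, 1]")

    @property
    def n(self) -> int:
        return len(self.s)

    @property
    def length_mm(self) -> float:
        return float(self.s[-1] - self.s[0])


@dataclass
class CorrelationResult:
    """One row of the correlation table: a specimen or a pooled group."""

    group: str
    n: int
    r_spearman: float
    p: float
    r_pearson: float
    R2: float
    strength: str
    length_mm: float | None = None

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.r_spearman <= 1 + 1e-9:
            raise ValueError("r_spearman outside [-1, 1]")
        if not -1e-9 <= self.R2 <= 1 + 1e-9:
            raise ValueError("R2 outside [0, 1]")

    @property
    def significant(self) -> bool:
        """Significance at the study's fixed 0.01 level."""
        return self.p <= 0.01

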