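"""Synthetic vertebra-like phantoms with known canal geometry and force links.

The generator stands in for cadaver scans that cannot be redistributed: it
builds a pre-interventional volume (cortical shell around trabecular
texture, air background), carves an air-filled canal of known axis and
radius into a post-interventional copy, applies a known rigid misalignment,
and synthesises drilling-force traces from the ground-truth density profile
through a declared monotone link plus autocorrelated noise.  Every stage of
the pipeline can therefore be scored against recorded truth.

The force model is *not* a biomechanical model of drilling.  The study
design only asserts a monotone association between local bone density and
axial force; the simulator's affine-in-gray-value link (plus AR(1) noise)
is the simplest declared link that lets parameter and correlation recovery
be measured.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.signal import lfilter
from scipy.special import ndtri
from scipy.stats import rankdata

from .core import AIR_HU, CTVolume, DensityProfile, DrillPath, ForceTrace, RigidTransform
from .registration import resample

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "make_phantom",
    "carve_canal",
    "simulate_force_trace",
    "simulate_correlated_pair",
    "truth_to_json",
    "truth_from_json",
]


@dataclass
class PhantomConfig:
    """Tunable study conditions for the synthetic phantom.

    HU bands are chosen so that after the gray-value conversion
    (GV = HU + 1026, clamped to [0, 4096]) every tissue lands inside the
    0-4096 GV range and the maximum-GV region is cortical bone.
    """

    air_hu: float = AIR_HU
    trabecular_hu: float = 300.0
    cortical_hu: float = 1200.0
    shell_thickness_mm: float = 1.5
    noise_sd_hu: float = 30.0          # trabecular texture sd
    texture_corr_mm: float = 0.8       # texture correlation length
    psf_sigma_mm: float = 0.4          # scanner point-spread emulation
    canal_length_mm: float = 28.0
    canal_radius_mm: float = 1.525     # 11G tool: 3.05 mm outer diameter
    air_noise_sd_hu: float = 10.0      # noise inside the carved canal
    max_rotation_deg: float = 3.0      # |misalignment| rotation bound
    max_translation_mm: float = 2.0
    link_intercept_n: float = 0.0      # a in F = a + b * GV
    link_slope_n_per_gv: float = 1.2e-3
    force_noise_sd_n: float = 0.1
    force_noise_phi: float = 0.8       # AR(1) coefficient at 1 kHz
    insertion_offset_mm: float = 2.0   # air travel before bone contact
    sample_rate_hz: float = 1000.0
    feed_velocity_mm_s: float = 2.0


@dataclass
class PhantomTruth:
    """Ground truth recorded alongside a generated phantom.

    ``misalignment`` is the rigid correction that realigns the post volume
    with the pre volume, i.e. exactly the transform a registration stage
    should recover; :func:`carve_canal` applies its inverse when producing
    the post volume.
    """

    path: DrillPath
    misalignment: RigidTransform
    link: tuple[float, float]          # (intercept a [N], slope b [N/GV])
    noise: tuple[float, float, float]  # (HU sd, force sd [N], AR(1) phi)
    seed: int
    insertion_offset_mm: float = 2.0
    config: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        if self.path.radius <= 0:
            raise ValueError("canal radius must be positive")
        if not abs(self.noise[2]) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")


def _ray_ellipsoid_exit(
    point: np.ndarray, direction: np.ndarray, center: np.ndarray, semi: np.ndarray
) -> tuple[float, float]:
    """Parameters u of both intersections of ``point + u*direction`` with the
    ellipsoid surface (u_enter < u_exit)."""
    p = (point - center) / semi
    d = direction / semi
    a = d @ d
    b = 2 * p @ d
    c = p @ p - 1.0
    disc = b * b - 4 * a * c
    if disc <= 0:
        raise ValueError("canal axis misses the phantom body")
    root = np.sqrt(disc)
    return (-b - root) / (2 * a), (-b + root) / (2 * a)


def make_phantom(
    shape: tuple[int, int, int] = (128, 128, 128),
    spacing: float | tuple[float, float, float] = 0.5,
    seed: int = 0,
    config: PhantomConfig | None = None,
) -> tuple[CTVolume, PhantomTruth]:
    """Generate a pre-interventional phantom volume plus its ground truth.

    The body is an ellipsoid of trabecular texture (mean ``trabecular_hu``,
    sd ``noise_sd_hu``) inside a cortical shell, with a pedicle-like
    cylindrical boss around the canal entry, on an air background.  The
    recorded canal path crosses the shell obliquely and ends in the
    interior.  All randomness flows from ``seed``.
    """
    cfg = config or PhantomConfig()
    shape = tuple(int(n) for n in shape)
    if any(n < 48 for n in shape):
        raise ValueError(f"shape must be >= (48, 48, 48), got {shape}")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
    if np.any(spacing < 0.2) or np.any(spacing > 1.0):
        raise ValueError(f"spacing must lie in [0.2, 1.0] mm, got {spacing}")
    rng = np.random.default_rng([int(seed), 0x9E3779])

    extent = (np.array(shape) - 1) * spacing
    center = extent / 2.0 + rng.uniform(-1.0, 1.0, 3)
    semi = extent * np.array([0.34, 0.31, 0.29]) * rng.uniform(0.95, 1.05, 3)

    # Oblique canal: tilted off the z axis, random azimuth.
    theta = np.deg2rad(rng.uniform(18.0, 35.0))
    phi = rng.uniform(0.0, 2 * np.pi)
    direction = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    mid = center + rng.uniform(-2.0, 2.0, 3)
    u_in, u_out = _ray_ellipsoid_exit(mid, direction, center, semi)
    surface = mid + u_in * direction  # ellipsoid surface, entry side
    chord = u_out - u_in
    boss_before = 4.0  # pedicle boss protrudes this far beyond the ellipsoid
    # The drill enters at the boss's outer face and runs obliquely into the
    # body interior.
    start = surface - boss_before * direction
    length = min(
        cfg.canal_length_mm * rng.uniform(0.95, 1.05), boss_before + 0.8 * chord
    )
    end = start + length * direction
    path = DrillPath(start, end, cfg.canal_radius_mm)

    # Voxel-centre world coordinates.
    ix, iy, iz = np.indices(shape, dtype=np.float64)
    X = ix * spacing[0]
    Y = iy * spacing[1]
    Z = iz * spacing[2]

    body = (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0

    # Pedicle-like boss: a cylinder around the canal entry, protruding out
    # of the ellipsoid so the canal crosses a shell wall at a realistic
    # oblique angle.
    rel = np.stack([X - start[0], Y - start[1], Z - start[2]], axis=-1)
    t_ax = rel @ direction
    d_perp2 = np.einsum("...i,...i", rel, rel) - t_ax**2
    boss = (d_perp2 <= 5.0**2) & (t_ax >= 0.0) & (t_ax <= boss_before + 10.0)
    body |= boss

    inside_depth = distance_transform_edt(body, sampling=spacing)
    shell = body & (inside_depth <= cfg.shell_thickness_mm)
    interior = body & ~shell

    base = np.full(shape, cfg.air_hu, dtype=np.float64)
    base[interior] = cfg.trabecular_hu
    base[shell] = cfg.cortical_hu
    sigma_vox = cfg.psf_sigma_mm / spacing
    base = gaussian_filter(base, sigma=sigma_vox)

    if cfg.noise_sd_hu > 0:
        white = rng.standard_normal(shape)
        tex = gaussian_filter(white, sigma=cfg.texture_corr_mm / spacing)
        tex *= cfg.noise_sd_hu / tex.std()
        feather = gaussian_filter(interior.astype(np.float64), sigma=sigma_vox)
        base += tex * feather

    volume = CTVolume(base, spacing, np.zeros(3))

    misalignment = RigidTransform(
        rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg, 3),
        rng.uniform(-cfg.max_translation_mm, cfg.max_translation_mm, 3),
        volume.world_center,
    )

    margin = cfg.canal_radius_mm + float(spacing.max())
    if not np.all(volume.contains(np.stack([start, end]), margin_mm=margin)):
        raise ValueError("canal not fully inside volume; enlarge shape or spacing")

    truth = PhantomTruth(
        path=path,
        misalignment=misalignment,
        link=(cfg.link_intercept_n, cfg.link_slope_n_per_gv),
        noise=(cfg.noise_sd_hu, cfg.force_noise_sd_n, cfg.force_noise_phi),
        seed=int(seed),
        insertion_offset_mm=cfg.insertion_offset_mm,
        config=cfg,
    )
    return volume, truth


def carve_canal(pre: CTVolume, truth: PhantomTruth) -> CTVolume:
    """Carve the true canal out of ``pre`` and apply the misalignment.

    Voxels whose centres fall inside the canal cylinder become air (plus
    independent noise); the wall is softened over one voxel to emulate
    partial-volume averaging.  The returned post volume is resampled
    through the inverse of ``truth.misalignment`` (identity transforms
    return the carved volume bit-exactly).
    """
    cfg = truth.config
    path = truth.path
    if not np.all(pre.contains(np.stack([path.start, path.end]))):
        raise ValueError("truth path not inside volume")
    h = float(pre.spacing.max())
    if path.radius < float(pre.spacing[:2].min()):
        warnings.warn(
            "canal radius below one in-plane voxel; canal may vanish under blur",
            stacklevel=2,
        )

    ix, iy, iz = np.indices(pre.shape, dtype=np.float64)
    pts = np.stack(
        [
            pre.origin[0] + ix * pre.spacing[0],
            pre.origin[1] + iy * pre.spacing[1],
            pre.origin[2] + iz * pre.spacing[2],
        ],
        axis=-1,
    )
    rel = pts - path.start
    t_ax = rel @ path.direction
    d_perp = np.sqrt(np.maximum(np.einsum("...i,...i", rel, rel) - t_ax**2, 0.0))
    radial_excess = d_perp - path.radius
    axial_excess = np.maximum(-t_ax, t_ax - path.length)
    outside = np.maximum(radial_excess, axial_excess)
    w = np.clip((h / 2.0 - outside) / h, 0.0, 1.0)  # 1 deep inside, 0 outside

    rng = np.random.default_rng([truth.seed, 0xCA9A1])
    air = np.full(pre.shape, cfg.air_hu)
    if cfg.air_noise_sd_hu > 0:
        air += rng.standard_normal(pre.shape) * cfg.air_noise_sd_hu
    carved = CTVolume(
        (1.0 - w) * pre.data + w * air, pre.spacing.copy(), pre.origin.copy()
    )
    if truth.misalignment.is_identity():
        return carved
    return resample(carved, truth.misalignment.inverse())


def true_profile(pre: CTVolume, truth: PhantomTruth, lead_in_mm: float = 5.0):
    """Convenience: the pre-volume density profile over the true (extended) path."""
    from .pathway import extract_profile

    return extract_profile(pre, truth.path.extended(before_mm=lead_in_mm))


def simulate_force_trace(
    profile: DensityProfile,
    truth: PhantomTruth,
    channel: str = "mean",
    target_rho: float | None = None,
) -> ForceTrace:
    """Synthesize a drilling-force trace from a gray-value profile.

    The drill advances at the configured feed velocity; displacement x maps
    to arc position ``s = x - s0`` where ``s0 > 0`` is the insertion offset
    (air travel before bone contact), so downstream alignment is
    non-trivial.  By default ``F = a + b * GV(s) + eps`` with AR(1) noise;
    the link is applied over the whole covered range so pre-contact force
    sits near 0 N (air gray values are small).

    When ``target_rho`` is given, the trace is instead built so the
    *population* Spearman correlation between force and gray value equals
    ``target_rho`` exactly: the gray values are mapped to normal scores z
    (a strictly monotone transform, hence Spearman-preserving) and
    ``F = 2 + rho_p * z + sqrt(1 - rho_p^2) * eps`` with
    ``rho_p = 2 sin(pi * target_rho / 6)``, the Pearson correlation whose
    bivariate-normal Spearman correlation is ``target_rho``.
    """
    cfg = truth.config
    if target_rho is not None and not (0.0 < target_rho <= 1.0):
        raise ValueError(f"population Spearman rho must be in (0, 1], got {target_rho}")
    if profile.unit != "GV":
        raise ValueError("simulate_force_trace expects a GV-converted profile")
    a, b = truth.link
    if b < 0:
        raise ValueError("link slope b must be >= 0")
    s0 = truth.insertion_offset_mm
    v = cfg.feed_velocity_mm_s
    fs = cfg.sample_rate_hz
    duration = (s0 + profile.s[-1] + 1.0) / v
    n = int(np.floor(duration * fs)) + 1
    t = np.arange(n) / fs
    x = v * t - s0  # arc position along the profile
    gv = np.interp(x, profile.s, profile.channel(channel))

    rng = np.random.default_rng([truth.seed, 0xF0ACE])
    _, sd_f, phi = truth.noise

    def ar1(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n)
        innov = rng.standard_normal(n) * sd * np.sqrt(1 - phi**2)
        innov[0] = rng.standard_normal() * sd  # stationary start
        return lfilter([1.0], [1.0, -phi], innov)

    if target_rho is None:
        F = a + b * gv + ar1(sd_f)
    else:
        rho_p = 2.0 * np.sin(np.pi * target_rho / 6.0)
        z = ndtri(rankdata(gv) / (n + 1))
        F = 2.0 + rho_p * z + np.sqrt(1.0 - rho_p**2) * ar1(1.0)
    return ForceTrace(t, F, sample_rate=fs, feed_velocity=v)


def simulate_correlated_pair(
    rho_s: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (density-like, force-like) pairs with population Spearman rho_s.

    Bivariate normal with Pearson correlation ``2 sin(pi rho_s / 6)``, the
    value whose Gaussian-copula Spearman correlation equals ``rho_s``.
    ``rho_s = 1`` degenerates to an exact monotone (identity) link.
    """
    if not (0.0 <= rho_s <= 1.0):
        raise ValueError(f"rho_s must be in [0, 1], got {rho_s}")
    x = rng.standard_normal(n)
    if rho_s == 1.0:
        return x, x.copy()
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    y = rho_p * x + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    return x, y


def truth_to_json(truth: PhantomTruth, path: str | Path) -> Path:
    """Write the ground-truth sidecar; sufficient to score every stage."""
    cfg = truth.config
    payload = {
        "seed": truth.seed,
        "path": {
            "start_mm": truth.path.start.tolist(),
            "end_mm": truth.path.end.tolist(),
            "radius_mm": truth.path.radius,
        },
        "misalignment": {
            "rotation_deg": truth.misalignment.rotation_deg.tolist(),
            "translation_mm": truth.misalignment.translation.tolist(),
            "center_mm": truth.misalignment.center.tolist(),
        },
        "link": {"intercept_n": truth.link[0], "slope_n_per_gv": truth.link[1]},
        "noise": {
            "hu_sd": truth.noise[0],
            "force_sd_n": truth.noise[1],
            "ar1_phi": truth.noise[2],
        },
        "insertion_offset_mm": truth.insertion_offset_mm,
        "config": {k: getattr(cfg, k) for k in vars(cfg)},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def truth_from_json(path: str | Path) -> PhantomTruth:
    d = json.loads(Path(path).read_text())
    cfg = PhantomConfig(**d["config"])
    return PhantomTruth(
        path=DrillPath(
            d["path"]["start_mm"], d["path"]["end_mm"], d["path"]["radius_mm"]
        ),
        misalignment=RigidTransform(
            d["misalignment"]["rotation_deg"],
            d["misalignment"]["translation_mm"],
            d["misalignment"]["center_mm"],
        ),
        link=(d["link"]["intercept_n"], d["link"]["slope_n_per_gv"]),
        noise=(d["noise"]["hu_sd"], d["noise"]["force_sd_n"], d["noise"]["ar1_phi"]),
        seed=d["seed"],
        insertion_offset_mm=d["insertion_offset_mm"],
        config=cfg,
    )
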