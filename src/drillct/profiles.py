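"""Gray-value conversion and the ±0.2 mm sliding min/max/mean filter.

CT intensities in HU are shifted onto a non-negative gray-value (GV) scale,
GV = HU + offset clamped to [0, 4096], anchored at -1025 HU <-> 1 GV
(offset 1026).  The conversion is a rank-preserving affine map, so every
downstream Spearman correlation is provably insensitive to the offset
choice and Pearson r is insensitive to any affine rescaling; the offset
merely places air near zero and dense cortical bone near the top of the
scale.

The "low-pass filter" of this pipeline is a sliding window of half-width
0.2 mm: at each arc position the min, max and mean over all samples within
±0.2 mm are recorded.  Windows truncate at the profile ends.  The windowed
maximum is the default correlation channel — the densest material in the
cross-section dominates drilling resistance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DensityProfile

__all__ = [
    "GvConversion",
    "WindowFilter",
    "hu_to_gv",
    "profile_to_gv",
    "windowed_stats",
    "normalize_minmax",
]


@dataclass
class GvConversion:
    """HU -> GV shift: ``gv = clamp(hu + offset, *clamp_range)``."""

    offset: float = 1026.0
    clamp_range: tuple[float, float] = (0.0, 4096.0)

    def __post_init__(self) -> None:
        lo, hi = self.clamp_range
        if not lo < hi:
            raise ValueError("clamp_range must be increasing")


@dataclass
class WindowFilter:
    """Sliding window of ``half_width`` mm (total span 2 * half_width)."""

    half_width: float = 0.2

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


def hu_to_gv(hu, conv: GvConversion | None = None):
    """Convert HU to gray values, elementwise."""
    conv = conv or GvConversion()
    hu = np.asarray(hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    out = np.clip(hu + conv.offset, *conv.clamp_range)
    return float(out) if out.ndim == 0 else out


def profile_to_gv(
    profile: DensityProfile, conv: GvConversion | None = None
) -> DensityProfile:
    """Apply the GV conversion to all channels of a profile."""
    if profile.unit == "GV":
        raise ValueError("profile already in GV")
    return profile.with_channels(
        hu_to_gv(profile.mean, conv),
        hu_to_gv(profile.min, conv),
        hu_to_gv(profile.max, conv),
        unit="GV",
    )


def windowed_stats(
    profile: DensityProfile, filt: WindowFilter | None = None
) -> DensityProfile:
    """Sliding min/max/mean over samples within ``half_width`` mm of each step.

    At step i the window holds all samples j with
    ``|s_j - s_i| <= half_width``, truncated at the profile ends.  The
    output max channel is the window maximum of the input max channel, the
    min the window minimum of the input min, and the mean the window mean
    of the input mean — i.e. the extrema range over *all* recorded
    cross-section samples in the window.  Output length equals input
    length.
    """
    filt = filt or WindowFilter()
    n = len(profile)
    if n == 0:
        raise ValueError("empty profile")
    s = profile.s
    # half-width in whole samples; tolerance forgives float grid jitter
    k = int(np.floor(filt.half_width / profile.ds + 1e-9)) if n > 1 else 0
    mins = np.empty(n)
    maxs = np.empty(n)
    means = np.empty(n)
    for i in range(n):
        lo = max(0, i - k)
        hi = min(n, i + k + 1)
        mins[i] = profile.min[lo:hi].min()
        maxs[i] = profile.max[lo:hi].max()
        means[i] = profile.mean[lo:hi].mean()
    return DensityProfile(s.copy(), means, mins, maxs, profile.unit, profile.meta)


def normalize_minmax(series: np.ndarray) -> np.ndarray:
    """Scale a series to [0, 1]: ``(x - min) / (max - min)``; order-preserving."""
    x = np.asarray(series, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("zero range: cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)
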