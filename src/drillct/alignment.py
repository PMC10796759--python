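"""Force/intensity co-registration along the drilling axis.

The force trace lives on a time axis, the density profile on an arc-length
axis.  With a constant feed velocity the trace converts to displacement
(``x = v * t``); both series are then aligned at their insertion points —
the first sustained rise above baseline, i.e. first bone contact — shifted
onto a common arc grid, interpolated, and min-max normalized.  Only the
in-bone overlap (at and beyond the intensity onset) enters the pair count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlignedPair, DensityProfile, ForceTrace, SpecimenMeta
from .profiles import normalize_minmax

__all__ = [
    "InsertionConfig",
    "trace_to_displacement",
    "detect_insertion",
    "align_pair",
]


@dataclass
class InsertionConfig:
    """Onset rule: baseline from the leading samples, rise above a fraction
    of the range sustained for a few samples."""

    baseline_fraction: float = 0.05
    rise_threshold_fraction: float = 0.05
    sustain_samples: int = 3
    # Fraction of the sustain window required above threshold.  Densely
    # sampled noisy series dip briefly below threshold on the rising edge;
    # demanding every sample be above would push the detected onset
    # systematically late.
    sustain_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.baseline_fraction < 0.5:
            raise ValueError("baseline_fraction must be in (0, 0.5)")
        if self.rise_threshold_fraction <= 0 or self.sustain_samples < 1:
            raise ValueError("rise threshold and sustain must be positive")
        if not 0 < self.sustain_fraction <= 1:
            raise ValueError("sustain_fraction must be in (0, 1]")


def trace_to_displacement(trace: ForceTrace) -> tuple[np.ndarray, np.ndarray]:
    """Convert a force trace to (displacement mm, force N) via ``x = v * t``."""
    if trace.feed_velocity <= 0:
        raise ValueError("feed_velocity must be positive")
    return trace.feed_velocity * trace.t, trace.F.copy()


def detect_insertion(
    x: np.ndarray,
    y: np.ndarray,
    cfg: InsertionConfig | None = None,
    sustain_mm: float | None = None,
) -> float:
    """Locate the onset (insertion point) of a rising series.

    Baseline is the mean of the first ``baseline_fraction`` of samples;
    the onset sample is the first one exceeding
    ``baseline + rise_threshold_fraction * (max - baseline)`` for
    ``sustain_samples`` consecutive samples.  ``sustain_mm`` expresses the
    sustain requirement as a physical length instead, so densely sampled
    series (a 1 kHz force trace has a sample every 0.002 mm) demand the
    same sustained rise as coarsely sampled ones and momentary noise
    excursions cannot trigger a false onset.  The returned position refines
    the onset to the linearly interpolated threshold crossing between the
    onset sample and its predecessor, so two series that are affine images
    of one another yield exactly corresponding positions regardless of
    their sample grids.
    """
    cfg = cfg or InsertionConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    sustain = cfg.sustain_samples
    if sustain_mm is not None:
        dx = float(np.median(np.diff(x)))
        sustain = max(sustain, int(round(sustain_mm / dx)))
    if n < 20 * cfg.sustain_samples:
        raise ValueError(f"series too short for onset detection: n={n}")
    n_base = max(1, int(np.floor(cfg.baseline_fraction * n)))
    baseline = float(y[:n_base].mean())
    rng = float(y.max() - baseline)
    if rng <= 0:
        raise ValueError("no insertion detected: series never rises above baseline")
    threshold = baseline + cfg.rise_threshold_fraction * rng

    above = y > threshold
    run = np.convolve(above.astype(int), np.ones(sustain, dtype=int), mode="valid")
    need = int(np.ceil(cfg.sustain_fraction * sustain))
    hits = np.nonzero(above[: len(run)] & (run >= need))[0]
    if hits.size == 0:
        raise ValueError("no insertion detected: rise never sustained")
    j = int(hits[0])
    if j == 0 or y[j - 1] >= threshold:
        return float(x[j])
    frac = (threshold - y[j - 1]) / (y[j] - y[j - 1])
    return float(x[j - 1] + frac * (x[j] - x[j - 1]))


def align_pair(
    profile: DensityProfile,
    force_x: np.ndarray,
    force_y: np.ndarray,
    cfg: InsertionConfig | None = None,
    channel: str = "max",
    meta: SpecimenMeta | None = None,
) -> AlignedPair:
    """Shift the force series onto the profile's arc grid and normalize both.

    The force displacement axis is shifted so its insertion point coincides
    with the profile's; force values are linearly interpolated onto the
    profile steps over the in-bone overlap (arc positions at or beyond the
    intensity onset that the shifted force record covers).  Both channels
    are min-max normalized over the overlap.
    """
    cfg = cfg or InsertionConfig()
    intensity = profile.channel(channel)
    sustain_mm = cfg.sustain_samples * profile.ds
    onset_i = detect_insertion(profile.s, intensity, cfg, sustain_mm=sustain_mm)
    onset_f = detect_insertion(np.asarray(force_x, float), np.asarray(force_y, float),
                               cfg, sustain_mm=sustain_mm)
    shift = onset_i - onset_f
    fx = np.asarray(force_x, dtype=np.float64) + shift
    fy = np.asarray(force_y, dtype=np.float64)

    keep = (profile.s >= onset_i - 1e-9) & (profile.s >= fx[0]) & (profile.s <= fx[-1])
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"aligned overlap too short: n={n} < 10")
    s = profile.s[keep]
    f_on_grid = np.interp(s, fx, fy)
    return AlignedPair(
        s=s,
        intensity_norm=normalize_minmax(intensity[keep]),
        force_norm=normalize_minmax(f_on_grid),
        shift_mm=float(shift),
        meta=meta if meta is not None else profile.meta,
    )
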