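"""Correlation statistics and grouped tabulation.

Spearman rank correlation (average ranks for ties) with a two-sided
t-approximation for the p-value at n > 9 and an exact permutation p-value
at n <= 9; Pearson correlation with its least-squares line and coefficient
of determination R²; strength classification on |r| with left-closed bands
adapted from Chan's scheme (poor < 0.3, fair < 0.6, moderately strong
< 0.8, very strong >= 0.8); and pooled tabulations per specimen, region,
individual, region x individual and overall.  Significance is fixed at
p <= 0.01 throughout.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations
from math import isfinite

import numpy as np
from scipy import stats as sps

from .core import AlignedPair, CorrelationResult

__all__ = [
    "spearman",
    "pearson",
    "classify_r",
    "correlate_pair",
    "grouped_correlations",
    "count_by_class",
    "SIGNIFICANCE_LEVEL",
    "STRENGTH_BANDS",
]

SIGNIFICANCE_LEVEL = 0.01
EXACT_P_MAX_N = 9

# left-closed bands on |r|
STRENGTH_BANDS = (
    (0.3, "poor"),
    (0.6, "fair"),
    (0.8, "moderately_strong"),
    (np.inf, "very_strong"),
)


def _check_xy(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined ranks: constant input series")
    return x, y


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    """All n! permutation index vectors, cached (n <= 9 only)."""
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _rank_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    # exact +-1 for perfectly concordant/discordant rankings, which float
    # normalisation would otherwise round to 1 - O(1e-16)
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx, len(rx) + 1.0 - ry):
        return -1.0
    return float(np.corrcoef(rx, ry)[0, 1])


def exact_permutation_p(x, y, r: float, mid: bool = False) -> float:
    """Two-sided exact permutation p-value for a Spearman coefficient.

    Enumerates all n! rank permutations (n <= 9).  With ``mid=True`` the
    point mass at the observed |r| contributes half weight (the mid-p
    convention), the appropriate form when comparing the discrete
    permutation distribution against a continuous approximation; the
    default conservative convention counts it fully.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    rx_c = sps.rankdata(x) - (n + 1) / 2.0
    ry_c = sps.rankdata(y) - (n + 1) / 2.0
    norm = np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
    perms = _all_permutations(n)  # (n!, n)
    r_all = (ry_c[perms] @ rx_c) / norm
    if mid:
        p = float(
            np.mean(np.abs(r_all) > abs(r) + 1e-12)
            + 0.5 * np.mean(np.abs(np.abs(r_all) - abs(r)) <= 1e-12)
        )
    else:
        p = float(np.mean(np.abs(r_all) >= abs(r) - 1e-12))
    return p


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    r is the Pearson correlation of average-ranked data.  For n > 9 the
    p-value uses the t-approximation ``t = r sqrt((n-2)/(1-r^2))`` with
    n - 2 degrees of freedom; for n <= 9 it is exact, enumerating all n!
    rank permutations.
    """
    x, y = _check_xy(x, y)
    n = len(x)
    r = _rank_r(x, y)
    if n <= EXACT_P_MAX_N:
        p = exact_permutation_p(x, y, r)
    elif abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def pearson(x, y) -> tuple[float, float, float, float]:
    """Pearson correlation: returns (r, R2, slope, intercept)."""
    x, y = _check_xy(x, y)
    res = sps.linregress(x, y)
    r = float(res.rvalue)
    return r, r * r, float(res.slope), float(res.intercept)


def classify_r(r: float) -> str:
    """Strength class of a correlation coefficient, on |r|."""
    if not isfinite(r) or abs(r) > 1 + 1e-9:
        raise ValueError(f"|r| must be <= 1, got {r}")
    a = abs(r)
    for upper, name in STRENGTH_BANDS:
        if a < upper:
            return name
    return STRENGTH_BANDS[-1][1]


def correlate_pair(
    pair: AlignedPair, group: str | None = None, length_mm: float | None = None
) -> CorrelationResult:
    """Full correlation summary of one aligned intensity/force pair."""
    r_s, p = spearman(pair.intensity_norm, pair.force_norm)
    r_p, R2, _, _ = pearson(pair.intensity_norm, pair.force_norm)
    if group is None:
        group = pair.meta.label if pair.meta is not None else "specimen"
    return CorrelationResult(
        group=group,
        n=pair.n,
        r_spearman=r_s,
        p=p,
        r_pearson=r_p,
        R2=R2,
        strength=classify_r(r_s),
        length_mm=pair.length_mm if length_mm is None else length_mm,
    )


def _pooled(pairs: list[AlignedPair], group: str) -> CorrelationResult:
    """Concatenate per-specimen-normalized pairs and correlate jointly.

    Pooling keeps each member's own normalization (the scales were
    normalized per specimen before pooling), so the pooled n is exactly the
    sum of member n.
    """
    x = np.concatenate([p.intensity_norm for p in pairs])
    y = np.concatenate([p.force_norm for p in pairs])
    r_s, p_val = spearman(x, y)
    r_p, R2, _, _ = pearson(x, y)
    return CorrelationResult(
        group=group,
        n=len(x),
        r_spearman=r_s,
        p=p_val,
        r_pearson=r_p,
        R2=R2,
        strength=classify_r(r_s),
        length_mm=None,
    )


def grouped_correlations(pairs: list[AlignedPair]) -> list[CorrelationResult]:
    """Correlations per specimen plus pooled per region, individual,
    region x individual, and overall.

    Requires complete specimen metadata on every pair.  Empty groups are
    skipped.  Pooled rows concatenate the (per-specimen normalized) member
    pairs, so pooled n is additive.
    """
    if not pairs:
        raise ValueError("no aligned pairs given")
    if any(p.meta is None for p in pairs):
        raise ValueError("grouped correlations require specimen metadata")

    results = [correlate_pair(p) for p in pairs]

    def members(pred) -> list[AlignedPair]:
        return [p for p in pairs if pred(p.meta)]

    regions = sorted({p.meta.region for p in pairs})
    individuals = sorted({p.meta.individual for p in pairs})
    for reg in regions:
        results.append(_pooled(members(lambda m: m.region == reg), f"region_{reg}"))
    for ind in individuals:
        results.append(
            _pooled(members(lambda m: m.individual == ind), f"individual_{ind}")
        )
    for ind in individuals:
        for reg in regions:
            sel = members(lambda m: m.individual == ind and m.region == reg)
            if sel:
                results.append(_pooled(sel, f"{ind}_{reg}"))
    results.append(_pooled(pairs, "overall"))
    return results


def count_by_class(
    results: list[CorrelationResult], significance_filter: float = SIGNIFICANCE_LEVEL
) -> dict[str, int]:
    """Tally strength classes over results with ``p <= significance_filter``."""
    counts = {name: 0 for _, name in STRENGTH_BANDS}
    for res in results:
        if res.p <= significance_filter:
            counts[res.strength] += 1
    return counts
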