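"""Published per-specimen summary of the cadaver drilling study.

The original pre/post CT volumes and force recordings (13 thoraco-lumbar
vertebrae, T11-L5, from two female body donors A and B; one T11 specimen
was destroyed during testing and excluded) were never deposited.  What is
reproducible from the published record is the per-specimen summary table:
Spearman r, coefficient of determination R², significance bound, pair
count n along the canal, and canal length.  This module ships those
printed values so the tabulations built on them — pooled pair counts,
region subtotals, strength-class tallies — can be recomputed exactly.

p-values printed as "< 0.001" are stored as the bound 0.001; the only
filter ever applied to them is p <= 0.01, for which any value below the
bound behaves identically.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import SpecimenMeta

__all__ = ["PublishedSpecimen", "SPECIMENS", "POOLED_SPEARMAN", "specimen_table"]


@dataclass(frozen=True)
class PublishedSpecimen:
    """One printed row: specimen labels plus its published statistics."""

    individual: str
    level: str
    r_spearman: float
    R2: float
    p: float          # upper bound where printed as "< 0.001"
    n: int
    length_mm: float

    @property
    def region(self) -> str:
        return self.level[0]

    @property
    def meta(self) -> SpecimenMeta:
        return SpecimenMeta(self.individual, self.region, self.level)


SPECIMENS: tuple[PublishedSpecimen, ...] = (
    PublishedSpecimen("A", "T11", 0.721, 0.521, 0.001, 295, 36.2),
    PublishedSpecimen("A", "T12", 0.687, 0.291, 0.001, 300, 29.3),
    PublishedSpecimen("A", "L1", 0.107, 0.020, 0.051, 330, 32.6),
    PublishedSpecimen("A", "L2", 0.524, 0.227, 0.001, 429, 46.0),
    PublishedSpecimen("A", "L3", 0.512, 0.350, 0.001, 436, 43.0),
    PublishedSpecimen("A", "L4", 0.469, 0.281, 0.001, 414, 40.1),
    PublishedSpecimen("A", "L5", 0.542, 0.343, 0.001, 416, 40.5),
    PublishedSpecimen("B", "T12", 0.686, 0.290, 0.001, 309, 29.9),
    PublishedSpecimen("B", "L1", 0.400, 0.140, 0.001, 418, 41.7),
    PublishedSpecimen("B", "L2", 0.204, 0.029, 0.001, 287, 30.9),
    PublishedSpecimen("B", "L3", 0.202, 0.042, 0.001, 398, 39.1),
    PublishedSpecimen("B", "L4", 0.659, 0.520, 0.001, 385, 38.3),
    PublishedSpecimen("B", "L5", 0.690, 0.137, 0.001, 401, 39.1),
)

# Published pooled Spearman correlations (pair counts are recomputed, not
# stored: they must equal the sums of the per-specimen n above).
POOLED_SPEARMAN: dict[str, float] = {
    "region_T": 0.665,
    "region_L": 0.434,
    "individual_A": 0.472,
    "individual_B": 0.457,
    "A_T": 0.687,
    "A_L": 0.430,
    "B_T": 0.686,
    "B_L": 0.437,
    "overall": 0.466,
}


def specimen_table() -> "pandas.DataFrame":  # noqa: F821
    """The published per-specimen rows as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "individual": s.individual,
                "region": s.region,
                "level": s.level,
                "r_spearman": s.r_spearman,
                "R2": s.R2,
                "p": s.p,
                "n": s.n,
                "length_mm": s.length_mm,
            }
            for s in SPECIMENS
        ]
    )
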