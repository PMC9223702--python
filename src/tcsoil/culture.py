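"""Plate-culture community indices.

Two classical indices summarise the 10-day colony-emergence dynamics of a
plated soil community:

* the colony development index ``CD = 100 * sum_k (N_k / N) / k`` where
  ``N_k`` is the number of colonies first appearing on day ``k`` and ``N`` the
  total over the window — fast-growing (r-strategist) communities approach
  100, slow (K-strategist) ones approach 10;
* the ecophysiological diversity index ``EP = -sum_k p_k log10 p_k`` with
  ``p_k = N_k / N`` — a base-10 emergence-evenness entropy whose maximum over
  the 10-day window is exactly 1 at perfectly even emergence.

Both are undefined on an empty series; this is flagged explicitly, never
silently reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .tables import EMERGENCE_DAYS, EmergenceSeries

__all__ = [
    "CultureIndexResult",
    "colony_development_index",
    "ecophysiological_diversity",
    "cfu_per_kg_dm",
    "culture_index_table",
]


@dataclass(frozen=True)
class CultureIndexResult:
    sample_id: str
    organism_group: str
    cd: float  # NaN when undefined
    ep: float  # NaN when undefined
    total_colonies: int

    @property
    def defined(self) -> bool:
        return self.total_colonies >= 1


def colony_development_index(series: EmergenceSeries) -> float:
    """CD index of an emergence series; NaN (undefined) when no colonies grew."""
    total = series.total
    if total == 0:
        return math.nan
    return 100.0 * sum(
        (n / total) / day for day, n in enumerate(series.counts, start=1)
    )


def ecophysiological_diversity(series: EmergenceSeries) -> float:
    """EP index (base-10 emergence entropy); NaN when no colonies grew.

    Terms with ``p_k = 0`` contribute 0 (the ``0 * log 0`` limit).
    """
    total = series.total
    if total == 0:
        return math.nan
    ep = 0.0
    for n in series.counts:
        if n > 0:
            p = n / total
            ep -= p * math.log10(p)
    return ep


def cfu_per_kg_dm(colonies: float, dilution_factor: float, dry_mass_kg: float) -> float:
    """Convert a plate count to cfu per kg dry soil.

    ``colonies`` colonies observed after plating a ``1/dilution_factor``
    dilution of a suspension of ``dry_mass_kg`` kg dry soil.
    """
    if colonies < 0:
        raise ValueError("colony count must be non-negative")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    if dry_mass_kg <= 0:
        raise ValueError("dry mass must be positive")
    return colonies * dilution_factor / dry_mass_kg


def culture_index_table(series: Iterable[EmergenceSeries]) -> pd.DataFrame:
    """Per-sample CD/EP table (one row per series, replicate-level values)."""
    results = [
        CultureIndexResult(
            sample_id=s.sample_id,
            organism_group=s.organism_group,
            cd=colony_development_index(s),
            ep=ecophysiological_diversity(s),
            total_colonies=s.total,
        )
        for s in series
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "organism_group": [r.organism_group for r in results],
            "cd": [r.cd for r in results],
            "ep": [r.ep for r in results],
            "total_colonies": [r.total_colonies for r in results],
        }
    )


# re-export for callers working at the series level
__emergence_days__ = EMERGENCE_DAYS
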