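"""Readers and writers for every tidy table the pipeline touches.

All files are tab-separated UTF-8 with a mandatory header; missing values are
written as ``NA``; optional ``#`` comment lines (tool version, RNG seed) may
precede the header.  Taxon tables are laid out taxa-as-rows x samples-as-
columns with a final ``lineage`` column in the GreenGenes dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .lineage import Lineage, format_lineage, parse_lineage

__all__ = [
    "ORGANISM_GROUPS",
    "QUANTITIES",
    "EmergenceSeries",
    "TaxonTable",
    "read_measurements",
    "write_measurements",
    "read_emergence",
    "write_emergence",
    "read_taxon_table",
    "write_taxon_table",
    "read_letter_table",
    "write_letter_table",
]

#: culturable functional groups enumerated on selective media
ORGANISM_GROUPS = ("Org", "Olig", "Cop", "Act")

#: measured quantities and their units
QUANTITIES = {
    "cfu_Org": "cfu kg^-1 DM",
    "cfu_Olig": "cfu kg^-1 DM",
    "cfu_Cop": "cfu kg^-1 DM",
    "cfu_Act": "cfu kg^-1 DM",
    "Deh": "umol TPF kg^-1 DM h^-1",
    "Cat": "mol O2 kg^-1 DM h^-1",
    "yield_shoots": "g DM pot^-1",
    "yield_roots": "g DM pot^-1",
    "SPAD_4leaf": "SPAD",
    "SPAD_8leaf": "SPAD",
}

EMERGENCE_DAYS = 10


@dataclass(frozen=True)
class EmergenceSeries:
    """New-colony counts per observation day for one sample and group.

    ``counts[k]`` is the number of colonies first appearing on day ``k + 1``
    of the 10-day incubation window.
    """

    sample_id: str
    organism_group: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != EMERGENCE_DAYS:
            raise ValueError(
                f"emergence series must cover exactly {EMERGENCE_DAYS} days, "
                f"got {len(self.counts)}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError("colony counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


class TaxonTable:
    """OTU counts per taxon per sample with positional rank lineages."""

    def __init__(self, counts: pd.DataFrame, lineages: Sequence[Lineage]):
        if len(lineages) != len(counts):
            raise ValueError("one lineage required per taxon row")
        if (counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.lineages = list(lineages)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def lineage_frame(self) -> pd.DataFrame:
        from .lineage import RANKS

        return pd.DataFrame(self.lineages, index=self.counts.index, columns=RANKS)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TaxonTable)
            and self.counts.equals(other.counts)
            and self.lineages == other.lineages
        )


# ---------------------------------------------------------------------------
# measurements (long format: sample_id, quantity, value)

def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str}, na_values=["NA"])
    _require(df, ("sample_id", "quantity", "value"), "measurement")
    bad = df["value"].dropna() < 0
    if bad.any():
        raise ValueError(f"negative measurement value(s) at rows {list(df.index[df['value'] < 0])}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    _require(df, ("sample_id", "quantity", "value"), "measurement")
    _write(df, path, header_comment)


# ---------------------------------------------------------------------------
# emergence series (sample_id, organism_group, day_1 .. day_10)

_DAY_COLS = [f"day_{k}" for k in range(1, EMERGENCE_DAYS + 1)]


def read_emergence(path: str | Path) -> list[EmergenceSeries]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    _require(df, ("sample_id", "organism_group", *_DAY_COLS), "emergence")
    return [
        EmergenceSeries(
            sample_id=str(r.sample_id),
            organism_group=str(r.organism_group),
            counts=tuple(int(getattr(r, c)) for c in _DAY_COLS),
        )
        for r in df.itertuples(index=False)
    ]


def write_emergence(series: Sequence[EmergenceSeries], path: str | Path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {"sample_id": s.sample_id, "organism_group": s.organism_group,
             **dict(zip(_DAY_COLS, s.counts))}
            for s in series
        ]
    )
    _write(df, path, header_comment)


# ---------------------------------------------------------------------------
# taxon table (taxa rows x sample columns + lineage column)

def read_taxon_table(path: str | Path) -> TaxonTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "lineage" not in df.columns:
        raise ValueError("taxon table must carry a final 'lineage' column")
    lineages = [parse_lineage(s) for s in df["lineage"]]
    counts = df.drop(columns="lineage")
    return TaxonTable(counts, lineages)


def write_taxon_table(table: TaxonTable, path: str | Path, header_comment: str | None = None) -> None:
    df = table.counts.copy()
    df["lineage"] = [format_lineage(l) for l in table.lineages]
    df.index.name = "taxon_id"
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# letter tables (mean +/- sd with homogeneous-group letters, Tables 3-9 style)

def write_letter_table(df: pd.DataFrame, path: str | Path, precision: int = 3,
                       header_comment: str | None = None) -> None:
    """Write a homogeneous-groups table (columns: group, mean, sd, letters).

    Means and sds are displayed half-up at *precision* decimals; the file
    round-trips losslessly through :func:`read_letter_table` at that
    precision.
    """
    _require(df, ("group", "mean", "sd", "letters"), "letter")
    if df["letters"].isna().any() or (df["letters"].astype(str).str.len() == 0).any():
        raise ValueError("letter table rows must all carry letters")
    out = df.copy()
    for col in ("mean", "sd"):
        out[col] = [format(round_half_up(v, precision), f".{precision}f") for v in out[col]]
    _write(out, path, header_comment)


def read_letter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"group": str, "letters": str})
    _require(df, ("group", "mean", "sd", "letters"), "letter")
    return df


# ---------------------------------------------------------------------------

def _require(df: pd.DataFrame, cols: Sequence[str], kind: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table missing column(s): {sorted(missing)}")


def _write(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
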