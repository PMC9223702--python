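"""Treatment design of the factorial soil microcosm.

The experiment crosses three binary factors — tetracycline contamination
(Tc, 100 mg kg^-1 DM soil), grass-compost fertilization (G, 4 g C kg^-1 DM
soil) and Zea mays cultivation (Zm) — giving eight variants, each analysed on
day 25 and day 50 in several replicates.  Variant codes follow the field
convention: non-sown soils are prefixed "C" (control), sown soils "Zm", with
"Tc" and "G" appended for the active amendments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TreatmentDesign",
    "VARIANT_CODES",
    "variant_code",
    "read_design",
    "write_design",
]

#: canonical ordering of the eight variants (non-sown block first)
VARIANT_CODES = ("C", "CTc", "CG", "CTcG", "Zm", "ZmTc", "ZmG", "ZmTcG")

DESIGN_COLUMNS = ("sample_id", "tc_dose", "compost_dose", "sown", "day", "replicate")


def variant_code(tc: bool, compost: bool, sown: bool) -> str:
    """Variant label as a pure function of the three binary factor levels."""
    code = "Zm" if sown else "C"
    if tc:
        code += "Tc"
    if compost:
        code += "G"
    return code


@dataclass(frozen=True)
class TreatmentDesign:
    """One experimental unit (pot x analysis day x replicate)."""

    sample_id: str
    tc_dose: float  # mg kg^-1 DM soil (0 or 100)
    compost_dose: float  # g C kg^-1 DM soil (0 or 4)
    sown: bool
    day: int  # 25 or 50
    replicate: int
    variant_code: str = field(init=False)

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be positive, got {self.replicate}")
        if self.tc_dose < 0 or self.compost_dose < 0:
            raise ValueError("doses must be non-negative")
        object.__setattr__(
            self,
            "variant_code",
            variant_code(self.tc_dose > 0, self.compost_dose > 0, self.sown),
        )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.variant_code, self.day, self.replicate)


def _check_unique(rows: Sequence[TreatmentDesign]) -> None:
    seen: dict[tuple, int] = {}
    for i, r in enumerate(rows):
        if r.key in seen:
            raise ValueError(
                f"duplicate (variant, day, replicate) triple {r.key}: "
                f"rows {seen[r.key]} and {i}"
            )
        seen[r.key] = i


def design_frame(rows: Iterable[TreatmentDesign]) -> pd.DataFrame:
    """Tidy DataFrame view of a design collection (derived variant included)."""
    recs = [
        {
            "sample_id": r.sample_id,
            "tc_dose": r.tc_dose,
            "compost_dose": r.compost_dose,
            "sown": r.sown,
            "day": r.day,
            "replicate": r.replicate,
            "variant_code": r.variant_code,
        }
        for r in rows
    ]
    return pd.DataFrame(recs)


def read_design(path: str | Path) -> list[TreatmentDesign]:
    """Read a treatment-design TSV.

    Required columns: sample_id, tc_dose, compost_dose, sown, day, replicate.
    ``variant_code`` is always re-derived, never trusted from the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    extra = set(df.columns) - set(DESIGN_COLUMNS) - {"variant_code"}
    if extra:
        raise ValueError(f"unknown design column(s): {sorted(extra)}")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing design column(s): {sorted(missing)}")
    rows = [
        TreatmentDesign(
            sample_id=str(rec.sample_id),
            tc_dose=float(rec.tc_dose),
            compost_dose=float(rec.compost_dose),
            sown=_parse_bool(rec.sown),
            day=int(rec.day),
            replicate=int(rec.replicate),
        )
        for rec in df.itertuples(index=False)
    ]
    _check_unique(rows)
    return rows


def write_design(rows: Sequence[TreatmentDesign], path: str | Path, header_comment: str | None = None) -> None:
    _check_unique(list(rows))
    df = design_frame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean field: {v!r}")
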