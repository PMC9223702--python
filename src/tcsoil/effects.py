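"""Treatment impact-factor (IF) indices and derived soil chemistry.

The impact factor of a treatment on a measured quantity is the ratio of the
treated to the control replicate mean, minus one:

    IF = A_treated / A_control - 1

computed separately within every stratum of the remaining factors and every
analysis day.  Negative values indicate suppression, positive stimulation.
Three factors are assessed this way: tetracycline contamination (IF_Tc),
grass-compost fertilization (IF_G) and Zea mays cultivation (IF_Zm).

Derived soil chemistry: the cation exchange capacity is the sum of the
exchangeable base cations and hydrolytic acidity, ``CEC = EBC + HAC``; the
alkaline cation saturation is the base share of it, ``ACS = 100 * EBC / CEC``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import mean
from typing import Sequence

import pandas as pd

from ._rounding import round_half_up
from .design import TreatmentDesign, design_frame

logger = logging.getLogger(__name__)

__all__ = [
    "FACTORS",
    "EffectIndexResult",
    "impact_factor",
    "if_table",
    "mean_index_over_days",
    "percent_change",
    "derive_cec",
    "derive_acs",
]

FACTORS = ("Tc", "G", "Zm")

# which design column the factor toggles, and which columns stratify it
_FACTOR_COLUMN = {"Tc": "tc_dose", "G": "compost_dose", "Zm": "sown"}
_STRATUM_COLUMNS = {
    "Tc": ("sown", "compost_dose"),
    "G": ("sown", "tc_dose"),
    "Zm": ("compost_dose", "tc_dose"),
}


@dataclass(frozen=True)
class EffectIndexResult:
    factor: str
    quantity: str
    stratum: tuple[tuple[str, object], ...]  # co-factor levels held fixed
    day: int
    value: float  # NaN when the control mean is 0
    n_treated: int
    n_control: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def impact_factor(treated_mean: float, control_mean: float) -> float:
    """``treated/control - 1``; NaN (undefined) when the control mean is 0."""
    if treated_mean < 0 or control_mean < 0:
        raise ValueError("impact factor requires non-negative means")
    if control_mean == 0:
        logger.warning(
            "impact factor undefined: control mean is 0 (treated mean %g)",
            treated_mean,
        )
        return math.nan
    return treated_mean / control_mean - 1.0


def if_table(
    measurements: pd.DataFrame,
    design: Sequence[TreatmentDesign],
    factor: str,
) -> list[EffectIndexResult]:
    """All IF values of *factor*, per (quantity, co-factor stratum, day).

    The index is computed on replicate means (mean of the treated samples
    over mean of the controls).  A stratum missing either factor level is
    omitted with a warning, never imputed.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    ddf = design_frame(design)
    merged = measurements.merge(ddf, on="sample_id", validate="many_to_one")
    fac_col = _FACTOR_COLUMN[factor]
    strat_cols = _STRATUM_COLUMNS[factor]
    results: list[EffectIndexResult] = []
    for (quantity, day, *strat), grp in merged.groupby(
        ["quantity", "day", *strat_cols], sort=True
    ):
        active = grp[fac_col].astype(float) > 0 if fac_col != "sown" else grp[fac_col].astype(bool)
        treated = grp.loc[active, "value"].dropna()
        control = grp.loc[~active, "value"].dropna()
        if treated.empty or control.empty:
            logger.warning(
                "IF_%s omitted for quantity=%s day=%s stratum=%s: "
                "missing %s level",
                factor, quantity, day, dict(zip(strat_cols, strat)),
                "treated" if treated.empty else "control",
            )
            continue
        results.append(
            EffectIndexResult(
                factor=factor,
                quantity=quantity,
                stratum=tuple(zip(strat_cols, strat)),
                day=int(day),
                value=impact_factor(treated.mean(), control.mean()),
                n_treated=len(treated),
                n_control=len(control),
            )
        )
    return results


def if_frame(results: Sequence[EffectIndexResult]) -> pd.DataFrame:
    """Tidy DataFrame of IF results (one stratum column per co-factor)."""
    recs = []
    for r in results:
        rec = {"factor": r.factor, "quantity": r.quantity, "day": r.day}
        rec.update({f"stratum_{k}": v for k, v in r.stratum})
        rec.update({"value": r.value, "n_treated": r.n_treated, "n_control": r.n_control})
        recs.append(rec)
    return pd.DataFrame(recs)


def mean_index_over_days(per_day_values: Sequence[float], ndigits: int = 3) -> float:
    """Arithmetic mean over analysis days, displayed half-up at 3 decimals."""
    if len(per_day_values) == 0:
        raise ValueError("cannot average an empty set of per-day values")
    return round_half_up(mean(per_day_values), ndigits)


def percent_change(treated: float, control: float, ndigits: int = 1) -> float:
    """Relative change in percent, displayed half-up at 1 decimal."""
    if control <= 0:
        raise ValueError("percent change requires a positive control value")
    if treated < 0:
        raise ValueError("treated value must be non-negative")
    return round_half_up(100.0 * (treated / control - 1.0), ndigits)


def derive_cec(ebc: float, hac: float) -> float:
    """Cation exchange capacity: EBC + HAC, mmol(+) kg^-1 DM."""
    if ebc < 0 or hac < 0:
        raise ValueError("EBC and HAC must be non-negative")
    return ebc + hac


def derive_acs(ebc: float, cec: float, ndigits: int = 2) -> float:
    """Alkaline cation saturation: 100 * EBC / CEC, percent (half-up, 2 dp)."""
    if cec <= 0:
        raise ValueError("CEC must be positive")
    if ebc < 0 or ebc > cec:
        raise ValueError("EBC must lie in [0, CEC]")
    return round_half_up(100.0 * ebc / cec, ndigits)
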