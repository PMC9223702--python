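"""Synthetic factorial microcosm generator with known ground truth.

The generator emulates the structure of the greenhouse microcosm: eight
variants crossing tetracycline (Tc), grass compost (G) and Zea mays (Zm),
analysed on days 25 and 50, with 4 replicates for plate counts and 3 for
enzyme activities; 10-day colony-emergence series for the organotroph and
actinomycete plates; and a Dirichlet-multinomial OTU table of ~70,000 reads
per sample over a genus panel with full GreenGenes lineages.

Treatment effects are multiplicative.  A measured value is

    baseline * prod(active-factor multipliers, day-modified) * lognormal noise

with the lognormal parametrized to mean 1 (``mu = -sigma^2/2``), so the
expected impact factor of factor F equals ``multiplier - 1`` in every stratum
— the recoverable target recorded in ``truth``.  Compositional effects act as
log-fold changes on the Dirichlet mean so factor effects compose additively
on the log scale, mirroring the factorial design.

All stages draw from per-stage streams derived from one global seed, so the
same configuration reproduces a byte-identical dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import TreatmentDesign
from .lineage import parse_lineage
from .tables import EmergenceSeries, TaxonTable

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "generate_experiment",
    "generate_measurements",
    "generate_emergence",
    "generate_taxon_table",
    "make_design",
]

_DAYS = (25, 50)

#: baseline levels of the uncontaminated, unfertilized, non-sown soil
DEFAULT_BASELINES: dict[str, float] = {
    "cfu_Org": 36.728e9,
    "cfu_Olig": 7.740e9,
    "cfu_Cop": 11.240e9,
    "cfu_Act": 17.008e9,
    "Deh": 4.042,   # umol TPF kg^-1 DM h^-1
    "Cat": 0.212,   # mol O2 kg^-1 DM h^-1
    "yield_shoots": 55.33,
    "yield_roots": 13.51,
    "SPAD_4leaf": 38.10,
    "SPAD_8leaf": 22.62,
}

#: multiplicative treatment effects (factor -> quantity -> multiplier);
#: chosen to echo the sign and scale of the observed factorial responses
DEFAULT_MULTIPLIERS: dict[str, dict[str, float]] = {
    "Tc": {"cfu_Org": 0.6, "cfu_Olig": 0.85, "cfu_Cop": 1.3, "cfu_Act": 0.7,
           "Deh": 0.92, "Cat": 1.0,
           "yield_shoots": 1.02, "yield_roots": 1.09,
           "SPAD_4leaf": 1.0, "SPAD_8leaf": 1.24},
    "G": {"cfu_Org": 1.5, "cfu_Olig": 0.85, "cfu_Cop": 1.1, "cfu_Act": 2.0,
          "Deh": 1.2, "Cat": 1.1,
          "yield_shoots": 1.09, "yield_roots": 0.95,
          "SPAD_4leaf": 0.92, "SPAD_8leaf": 1.25},
    "Zm": {"cfu_Org": 2.2, "cfu_Olig": 1.4, "cfu_Cop": 1.1, "cfu_Act": 2.2,
           "Deh": 1.6, "Cat": 1.05},
}

#: quantities measured only on sown pots, once (reported under day 50)
PLANT_QUANTITIES = ("yield_shoots", "yield_roots", "SPAD_4leaf", "SPAD_8leaf")

ENZYME_QUANTITIES = ("Deh", "Cat")

#: emergence-day distributions (day 1..10); organotrophs emerge faster
DEFAULT_EMERGENCE_PROBS: dict[str, tuple[float, ...]] = {
    "Org": (0.04, 0.22, 0.22, 0.16, 0.11, 0.08, 0.06, 0.05, 0.03, 0.03),
    "Act": (0.02, 0.12, 0.18, 0.17, 0.14, 0.11, 0.09, 0.07, 0.05, 0.05),
}

#: genus panel: (phylum, base relative abundance); the residual mass goes to
#: an unclassified bucket.  Core genera sit well above 1 %; Kutzneria,
#: Ralstonia and DA101 start below 1 % and are pushed over it by Tc.
DEFAULT_PANEL: dict[str, tuple[str, float]] = {
    "Kaistobacter": ("Proteobacteria", 0.14),
    "Rhodoplanes": ("Proteobacteria", 0.08),
    "Sphingomonas": ("Proteobacteria", 0.05),
    "Sphingobium": ("Proteobacteria", 0.03),
    "Burkholderia": ("Proteobacteria", 0.03),
    "Rhodanobacter": ("Proteobacteria", 0.02),
    "Luteibacter": ("Proteobacteria", 0.02),
    "Steroidobacter": ("Proteobacteria", 0.02),
    "Ralstonia": ("Proteobacteria", 0.004),
    "Cellulosimicrobium": ("Actinobacteria", 0.10),
    "Nocardioides": ("Actinobacteria", 0.07),
    "Streptomyces": ("Actinobacteria", 0.05),
    "Terracoccus": ("Actinobacteria", 0.04),
    "Arthrobacter": ("Actinobacteria", 0.03),
    "Phycicoccus": ("Actinobacteria", 0.02),
    "Amycolatopsis": ("Actinobacteria", 0.015),
    "Kutzneria": ("Actinobacteria", 0.004),
    "Candidatus Solibacter": ("Acidobacteria", 0.06),
    "Bacillus": ("Firmicutes", 0.04),
    "DA101": ("Verrucomicrobia", 0.006),
}

#: log-fold compositional effects per factor
DEFAULT_LOG_FOLD_EFFECTS: dict[str, dict[str, float]] = {
    "Tc": {"Kutzneria": 2.0, "Ralstonia": 2.0, "DA101": 1.2,
           "Kaistobacter": 0.4, "Nocardioides": 0.3, "Streptomyces": 0.2,
           "Sphingomonas": -0.4, "Luteibacter": -0.3},
    "Zm": {"Kaistobacter": 0.3, "Sphingomonas": 0.5, "Sphingobium": 0.5,
           "Burkholderia": 0.5, "Luteibacter": 0.4,
           "Cellulosimicrobium": -0.4, "Nocardioides": -0.5,
           "Terracoccus": -0.5, "Streptomyces": -0.3},
    "G": {"Bacillus": 0.8, "Candidatus Solibacter": -0.4,
          "Cellulosimicrobium": 0.2, "Nocardioides": -0.2},
}


def _default_composition() -> dict[str, float]:
    comp = {g: b for g, (_, b) in DEFAULT_PANEL.items()}
    comp["unclassified"] = 1.0 - sum(comp.values())
    return comp


def _default_lineages() -> dict[str, str]:
    lins = {
        g: f"k__Bacteria; p__{phylum}; c__; o__; f__; g__{g}"
        for g, (phylum, _) in DEFAULT_PANEL.items()
    }
    lins["unclassified"] = "k__Bacteria; p__; c__; o__; f__; g__"
    return lins


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; defaults emulate the microcosm."""

    seed: int = 0
    n_rep_counts: int = 4
    n_rep_enzymes: int = 3
    days: tuple[int, ...] = _DAYS
    baselines: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {f: dict(q) for f, q in DEFAULT_MULTIPLIERS.items()})
    #: per-factor multiplier modifier applied on day 50 (effects drift in time)
    day50_modifiers: Mapping[str, float] = field(
        default_factory=lambda: {"Tc": 1.0, "G": 1.0, "Zm": 1.0})
    cv_noise: float = 0.05
    emergence_total_colonies: int = 200
    emergence_day_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {g: tuple(p) for g, p in DEFAULT_EMERGENCE_PROBS.items()})
    otu_depth: int = 70_000
    genus_base_composition: Mapping[str, float] = field(default_factory=_default_composition)
    genus_lineages: Mapping[str, str] = field(default_factory=_default_lineages)
    genus_log_fold_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {f: dict(g) for f, g in DEFAULT_LOG_FOLD_EFFECTS.items()})
    dispersion: float = 500.0

    def __post_init__(self) -> None:
        if self.n_rep_counts < 1 or self.n_rep_enzymes < 1:
            raise ValueError("replicate counts must be positive")
        if self.otu_depth < 1:
            raise ValueError("OTU depth must be positive")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be non-negative")
        comp = np.array(list(self.genus_base_composition.values()), dtype=float)
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("genus base composition must sum to 1")
        for f, m in self.multipliers.items():
            if any(v <= 0 for v in m.values()):
                raise ValueError(f"multipliers for factor {f} must be positive")
        for g, probs in self.emergence_day_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"emergence-day probabilities for {g} must sum to 1")


@dataclass
class SimulatedExperiment:
    design: list[TreatmentDesign]
    measurements: pd.DataFrame
    emergence: list[EmergenceSeries]
    taxon_table: TaxonTable
    truth: dict


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # fixed per-stage offsets: stages regenerate independently of each other
    return np.random.default_rng([int(config.seed), stage])


def _active_factors(d: TreatmentDesign) -> list[str]:
    active = []
    if d.tc_dose > 0:
        active.append("Tc")
    if d.compost_dose > 0:
        active.append("G")
    if d.sown:
        active.append("Zm")
    return active


def effective_multiplier(config: SimulationConfig, factor: str, quantity: str, day: int) -> float:
    base = config.multipliers.get(factor, {}).get(quantity, 1.0)
    if day == 50 and base != 1.0:
        base = 1.0 + (base - 1.0) * config.day50_modifiers.get(factor, 1.0)
    return base


def make_design(config: SimulationConfig) -> list[TreatmentDesign]:
    """Full factorial design: 8 variants x analysis days x replicates."""
    rows = []
    n_rep = max(config.n_rep_counts, config.n_rep_enzymes)
    for sown in (False, True):
        for tc in (0.0, 100.0):
            for g in (0.0, 4.0):
                for day in config.days:
                    for rep in range(1, n_rep + 1):
                        d = TreatmentDesign(
                            sample_id="", tc_dose=tc, compost_dose=g,
                            sown=sown, day=day, replicate=rep,
                        )
                        rows.append(TreatmentDesign(
                            sample_id=f"{d.variant_code}_d{day}_r{rep}",
                            tc_dose=tc, compost_dose=g, sown=sown,
                            day=day, replicate=rep,
                        ))
    return rows


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate_measurements(config: SimulationConfig,
                          design: Sequence[TreatmentDesign]) -> pd.DataFrame:
    """Long measurement table (sample_id, quantity, value) for the design.

    Plate counts use replicates 1..n_rep_counts, enzymes 1..n_rep_enzymes;
    plant quantities are emitted for sown pots at the final analysis day only.
    """
    rng = _rng(config, 1)
    records = []
    final_day = max(config.days)
    for quantity, baseline in config.baselines.items():
        is_plant = quantity in PLANT_QUANTITIES
        n_rep = (config.n_rep_enzymes if quantity in ENZYME_QUANTITIES
                 else config.n_rep_counts)
        for d in design:
            if d.replicate > n_rep:
                continue
            if is_plant and (not d.sown or d.day != final_day):
                continue
            mult = 1.0
            for f in _active_factors(d):
                if is_plant and f == "Zm":
                    continue  # plant traits have no "cultivation vs none" contrast
                mult *= effective_multiplier(config, f, quantity, d.day)
            noise = _lognormal_noise(rng, config.cv_noise, 1)[0]
            records.append({
                "sample_id": d.sample_id,
                "quantity": quantity,
                "value": baseline * mult * noise,
            })
    return pd.DataFrame(records)


def generate_emergence(total_colonies: int, day_probs: Sequence[float],
                       rng: np.random.Generator | int) -> np.ndarray:
    """Multinomial colony-emergence draw over the 10-day window."""
    if total_colonies < 0:
        raise ValueError("total colony count must be non-negative")
    probs = np.asarray(day_probs, dtype=float)
    if len(probs) != 10:
        raise ValueError("exactly 10 day probabilities are required")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("day probabilities must sum to 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return rng.multinomial(total_colonies, probs)


def generate_emergence_series(config: SimulationConfig,
                              design: Sequence[TreatmentDesign]) -> list[EmergenceSeries]:
    rng = _rng(config, 2)
    series = []
    for d in design:
        if d.replicate > config.n_rep_counts:
            continue
        for group, probs in config.emergence_day_probs.items():
            counts = generate_emergence(config.emergence_total_colonies, probs, rng)
            series.append(EmergenceSeries(
                sample_id=d.sample_id, organism_group=group,
                counts=tuple(int(c) for c in counts),
            ))
    return series


def generate_taxon_table(config: SimulationConfig,
                         design: Sequence[TreatmentDesign]) -> TaxonTable:
    """Dirichlet-multinomial OTU table, one sample per (variant, day).

    Per-sample mean composition is the base composition with the active
    factors' log-fold effects applied and renormalized; the realized
    composition is a Dirichlet draw around it (concentration =
    ``dispersion``), and counts a multinomial of ``otu_depth`` reads.
    """
    panel = list(config.genus_base_composition)
    for factor, effects in config.genus_log_fold_effects.items():
        missing = set(effects) - set(panel)
        if missing:
            raise ValueError(
                f"log-fold effects for factor {factor} name genera absent "
                f"from the panel: {sorted(missing)}"
            )
    rng = _rng(config, 3)
    base = np.array([config.genus_base_composition[g] for g in panel], dtype=float)
    log_base = np.log(base)
    seen: dict[str, list[str]] = {}
    for d in design:
        key = f"{d.variant_code}_d{d.day}"
        seen.setdefault(key, []).append(d.variant_code)
    columns = {}
    for sample_key in seen:
        variant = seen[sample_key][0]
        d = next(x for x in design if f"{x.variant_code}_d{x.day}" == sample_key)
        shift = np.zeros(len(panel))
        for f in _active_factors(d):
            eff = config.genus_log_fold_effects.get(f, {})
            shift += np.array([eff.get(g, 0.0) for g in panel])
        logits = log_base + shift
        mean = np.exp(logits - logits.max())
        mean /= mean.sum()
        p = rng.dirichlet(config.dispersion * mean)
        columns[sample_key] = rng.multinomial(config.otu_depth, p)
    counts = pd.DataFrame(columns, index=panel)
    counts.index.name = "taxon_id"
    lineages = [parse_lineage(config.genus_lineages[g]) for g in panel]
    return TaxonTable(counts, lineages)


def generate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate the complete synthetic dataset plus its ground truth."""
    design = make_design(config)
    measurements = generate_measurements(config, design)
    emergence = generate_emergence_series(config, design)
    taxon_table = generate_taxon_table(config, design)
    truth = {
        "seed": config.seed,
        "cv_noise": config.cv_noise,
        "multipliers": {f: dict(m) for f, m in config.multipliers.items()},
        "expected_if": {
            f: {
                q: {day: effective_multiplier(config, f, q, day) - 1.0
                    for day in config.days}
                for q in config.baselines
            }
            for f in config.multipliers
        },
        "genus_log_fold_effects": {
            f: dict(m) for f, m in config.genus_log_fold_effects.items()
        },
    }
    return SimulatedExperiment(design, measurements, emergence, taxon_table, truth)
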