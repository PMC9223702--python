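"""Community composition: rank profiles, Shannon-Wiener diversity, core/unique
genus sets, and two-sample proportion comparison.

Relative abundances are expressed per sample, per taxonomic rank, as
percentages summing to 100.  Reporting follows the 1 % abundance convention:
taxa below threshold are folded into an ``other`` bucket so totals stay
auditable.  Diversity uses the natural-log Shannon-Wiener index
``H' = -sum p_i ln p_i`` on proportions renormalized over the included taxa.

The core microbiome of a scope (e.g. the four non-sown variants) is the
intersection of the per-variant above-threshold genus sets; a variant's
unique set is what no other variant in the scope reaches threshold for.

Phylum-level proportions between two communities are compared with a
Yates-corrected G-test plus Fisher's exact test and a Newcombe score 95 %
confidence interval for the difference — the classic STAMP-style two-sample
battery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import confint_proportions_2indep

from .lineage import RANKS
from .tables import TaxonTable

logger = logging.getLogger(__name__)

__all__ = [
    "RankProfile",
    "SetReport",
    "ProportionTestResult",
    "relative_abundance",
    "threshold_filter",
    "shannon_wiener",
    "rankwise_diversity",
    "core_and_unique",
    "abundance_difference",
    "two_sample_proportion_test",
    "genus_sets",
    "filtered_matrix",
]

#: ranks diversity is reported at (kingdom is a single bucket here)
DIVERSITY_RANKS = ("phylum", "class", "order", "family", "genus")

OTHER = "other"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class RankProfile:
    """Percent relative abundance of each taxon at one rank in one sample."""

    sample_id: str
    rank: str
    proportions: pd.Series  # percent, name -> %

    @property
    def total(self) -> float:
        return float(self.proportions.sum())


@dataclass(frozen=True)
class SetReport:
    """Core/unique genus sets over the variants of one scope."""

    variant_sets: dict[str, frozenset[str]]
    core: frozenset[str]
    unique: dict[str, frozenset[str]]

    def to_json_dict(self) -> dict:
        return {
            "variants": {v: sorted(s) for v, s in self.variant_sets.items()},
            "core": sorted(self.core),
            "unique": {v: sorted(s) for v, s in self.unique.items()},
        }


def _rank_counts(table: TaxonTable, rank: str) -> pd.DataFrame:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    idx = RANKS.index(rank)
    labels = [lin[idx] if lin[idx] else UNCLASSIFIED for lin in table.lineages]
    return table.counts.groupby(pd.Index(labels, name=rank)).sum()


def relative_abundance(table: TaxonTable, rank: str) -> list[RankProfile]:
    """Per-sample percentage profiles at *rank* (empty rank -> 'unclassified').

    Samples with zero total are skipped with a warning.
    """
    agg = _rank_counts(table, rank)
    profiles = []
    for sample in agg.columns:
        total = agg[sample].sum()
        if total == 0:
            logger.warning("sample %s has zero total count; skipped", sample)
            continue
        profiles.append(
            RankProfile(sample_id=sample, rank=rank,
                        proportions=100.0 * agg[sample] / total)
        )
    return profiles


def threshold_filter(profile: RankProfile, threshold: float = 1.0,
                     strict: bool = False) -> RankProfile:
    """Fold taxa below the abundance threshold into an ``other`` bucket.

    Default retains taxa at >= *threshold* percent; ``strict=True`` requires
    strictly greater.  The ``other`` mass keeps the profile summing to its
    original total.
    """
    if not (0 < threshold < 100):
        raise ValueError("threshold must lie strictly between 0 and 100 percent")
    p = profile.proportions
    keep = p > threshold if strict else p >= threshold
    kept = p[keep]
    other = float(p[~keep].sum())
    if other > 0:
        kept = pd.concat([kept, pd.Series({OTHER: other})])
    return RankProfile(profile.sample_id, profile.rank, kept)


def shannon_wiener(proportions) -> float:
    """Natural-log Shannon-Wiener H' of a profile (renormalized to sum 1).

    Accepts a :class:`RankProfile`, a mapping or a sequence of non-negative
    weights (percent or fractions — any positive scale).  ``0 * ln 0 := 0``.
    Returns NaN for an empty (all-zero) profile.
    """
    if isinstance(proportions, RankProfile):
        values = proportions.proportions.to_numpy(dtype=float)
    elif isinstance(proportions, Mapping):
        values = np.asarray(list(proportions.values()), dtype=float)
    else:
        values = np.asarray(list(proportions), dtype=float)
    if (values < 0).any():
        raise ValueError("proportions must be non-negative")
    total = values.sum()
    if total == 0:
        return math.nan
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def rankwise_diversity(table: TaxonTable, ranks: Sequence[str] = DIVERSITY_RANKS) -> pd.DataFrame:
    """H' per sample per rank, computed on unfiltered proportions.

    Returns a samples x ranks DataFrame.
    """
    out = {}
    for rank in ranks:
        agg = _rank_counts(table, rank)
        out[rank] = {s: shannon_wiener(agg[s]) for s in agg.columns}
    return pd.DataFrame(out).loc[table.sample_ids]


def core_and_unique(variant_sets: Mapping[str, set[str] | frozenset[str]]) -> SetReport:
    """Core (intersection) and per-variant unique genus sets of one scope."""
    if not variant_sets:
        raise ValueError("at least one variant set is required")
    sets = {v: frozenset(s) for v, s in variant_sets.items()}
    core = frozenset.intersection(*sets.values())
    unique = {
        v: s - frozenset().union(*(w for u, w in sets.items() if u != v))
        for v, s in sets.items()
    }
    return SetReport(variant_sets=sets, core=core, unique=unique)


def abundance_difference(profile_a: RankProfile, profile_b: RankProfile) -> pd.Series:
    """Per-taxon difference a - b in percentage points (missing taxa = 0)."""
    if profile_a.rank != profile_b.rank:
        raise ValueError(
            f"rank mismatch: {profile_a.rank!r} vs {profile_b.rank!r}"
        )
    a, b = profile_a.proportions.align(profile_b.proportions, fill_value=0.0)
    return a - b


@dataclass(frozen=True)
class ProportionTestResult:
    g_yates: float  # NaN when a margin is degenerate
    p_g: float
    p_fisher: float
    diff: float
    diff_ci_95: tuple[float, float]


def two_sample_proportion_test(success_a: int, total_a: int,
                               success_b: int, total_b: int) -> ProportionTestResult:
    """Yates-corrected G-test + Fisher exact + Newcombe 95 % CI on a 2x2 table.

    The Yates correction shrinks every |O - E| by 0.5 (clamped at 0) before
    forming ``G = 2 sum O' ln(O'/E)`` with 1 df.  When a margin is zero the G
    statistic is undefined (NaN) but Fisher's exact test is still computed.
    """
    for s, t in ((success_a, total_a), (success_b, total_b)):
        if t <= 0:
            raise ValueError("totals must be positive")
        if not 0 <= s <= t:
            raise ValueError("successes must lie in [0, total]")
    table = np.array(
        [[success_a, total_a - success_a], [success_b, total_b - success_b]],
        dtype=float,
    )
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if (row == 0).any() or (col == 0).any():
        g, p_g = math.nan, math.nan
    else:
        expected = np.outer(row, col) / n
        adj = np.sign(table - expected) * np.minimum(np.abs(table - expected), 0.5)
        o = table - adj
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(o > 0, o * np.log(o / expected), 0.0)
        g = float(2.0 * terms.sum())
        g = max(g, 0.0)
        p_g = float(stats.chi2.sf(g, df=1))
    p_fisher = float(stats.fisher_exact(table.astype(int), alternative="two-sided")[1])
    diff = success_a / total_a - success_b / total_b
    lo, hi = confint_proportions_2indep(
        success_a, total_a, success_b, total_b, compare="diff", method="newcomb"
    )
    return ProportionTestResult(
        g_yates=g, p_g=p_g, p_fisher=p_fisher,
        diff=diff, diff_ci_95=(float(lo), float(hi)),
    )


# ---------------------------------------------------------------------------
# variant-level helpers used by the set analysis and the heatmap export

def _variant_profiles(table: TaxonTable, sample_variants: Mapping[str, str],
                      rank: str) -> list[RankProfile]:
    """Pool sample counts by variant, then profile at *rank*."""
    missing = set(table.sample_ids) - set(sample_variants)
    if missing:
        raise ValueError(f"samples without a variant assignment: {sorted(missing)}")
    pooled = table.counts.T.groupby(
        pd.Index([sample_variants[s] for s in table.sample_ids], name="variant")
    ).sum().T
    return relative_abundance(TaxonTable(pooled, table.lineages), rank)


def genus_sets(table: TaxonTable, sample_variants: Mapping[str, str],
               threshold: float = 1.0, strict: bool = False) -> dict[str, frozenset[str]]:
    """Above-threshold genus set per variant (counts pooled over samples)."""
    out = {}
    for prof in _variant_profiles(table, sample_variants, "genus"):
        filt = threshold_filter(prof, threshold=threshold, strict=strict)
        out[prof.sample_id] = frozenset(
            t for t in filt.proportions.index if t not in (OTHER, UNCLASSIFIED)
        )
    return out


def filtered_matrix(table: TaxonTable, sample_variants: Mapping[str, str],
                    rank: str, threshold: float = 1.0,
                    strict: bool = False) -> pd.DataFrame:
    """Heatmap-ready taxa x variants matrix of filtered percentages.

    A taxon is a row if it passes the threshold in at least one variant;
    sub-threshold mass is summed into an ``other`` row.
    """
    profiles = _variant_profiles(table, sample_variants, rank)
    cols = {}
    keep: set[str] = set()
    for prof in profiles:
        filt = threshold_filter(prof, threshold=threshold, strict=strict)
        keep |= set(filt.proportions.index) - {OTHER}
        cols[prof.sample_id] = prof.proportions
    full = pd.DataFrame(cols).fillna(0.0)
    kept = full.loc[sorted(keep)]
    other = full.drop(index=sorted(keep)).sum(axis=0)
    if (other > 0).any():
        kept.loc[OTHER] = other
    return kept
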