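"""Homogeneous-group machinery for the factorial tables.

The comparison pipeline mirrors common practice in soil-science tables:

1. a normality gate — Shapiro-Wilk on the pooled within-group residuals
   decides between the parametric and the rank-based branch;
2. two-way ANOVA (type-II sums of squares; in the balanced case identical to
   the classical decomposition) for the factorial effects;
3. Duncan's multiple range test on the parametric branch, with protected
   levels ``alpha_p = 1 - (1 - alpha)^(p-1)`` and studentized-range critical
   values; or Dunn's rank test with Bonferroni adjustment on the rank branch;
4. a compact letter display (insert-and-absorb) turning the pairwise decision
   matrix into the familiar superscript letters: two groups share a letter
   iff they were not declared different.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GateResult",
    "DuncanResult",
    "normality_gate",
    "two_way_anova",
    "duncan_mrt",
    "dunn_bonferroni",
    "compact_letter_display",
    "letter_table",
]

GroupData = Mapping[str, Sequence[float]]


@dataclass(frozen=True)
class GateResult:
    path: str  # "parametric" | "rank_based"
    shapiro_p: float  # NaN when the test is undefined


def _residuals(groups: GroupData) -> np.ndarray:
    res = []
    for vals in groups.values():
        arr = np.asarray(vals, dtype=float)
        res.append(arr - arr.mean())
    return np.concatenate(res)


def normality_gate(groups: GroupData, alpha: float = 0.05) -> GateResult:
    """Choose the parametric path iff Shapiro-Wilk on pooled residuals p >= alpha."""
    res = _residuals(groups)
    if len(res) < 3:
        logger.warning("fewer than 3 residuals; falling back to the rank-based path")
        return GateResult("rank_based", math.nan)
    if np.ptp(res) == 0:
        logger.warning("constant data; Shapiro-Wilk undefined, using rank-based path")
        return GateResult("rank_based", math.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large-n p-value accuracy note
        p = float(stats.shapiro(res).pvalue)
    path = "parametric" if p >= alpha else "rank_based"
    logger.info("normality gate: Shapiro-Wilk p=%.4g -> %s", p, path)
    return GateResult(path, p)


def two_way_anova(values: Sequence[float], factor_a: Sequence, factor_b: Sequence) -> pd.DataFrame:
    """Type-II two-way ANOVA; returns a terms x (ss, df, F, p) DataFrame.

    With no replication the interaction is dropped (and logged).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "a": [str(x) for x in factor_a],
        "b": [str(x) for x in factor_b],
    })
    replicated = (df.groupby(["a", "b"]).size() > 1).any()
    formula = "y ~ C(a) + C(b)" + (" + C(a):C(b)" if replicated else "")
    if not replicated:
        logger.warning("no replication in any cell; interaction term dropped")
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    tab = tab.rename(
        index={"C(a)": "A", "C(b)": "B", "C(a):C(b)": "A:B", "Residual": "residual"},
        columns={"sum_sq": "ss", "PR(>F)": "p"},
    )
    return tab[["ss", "df", "F", "p"]]


@dataclass(frozen=True)
class DuncanResult:
    different: pd.DataFrame  # boolean pairwise decision matrix
    means: pd.Series
    mse: float
    df_resid: int


def _pooled_mse(groups: GroupData) -> tuple[float, int]:
    sse, df = 0.0, 0
    for vals in groups.values():
        arr = np.asarray(vals, dtype=float)
        sse += float(((arr - arr.mean()) ** 2).sum())
        df += len(arr) - 1
    return (sse / df if df > 0 else math.nan), df


def duncan_mrt(groups: GroupData, alpha: float = 0.05,
               mse: float | None = None, df_resid: int | None = None,
               blocking: bool = True) -> DuncanResult:
    """Duncan's multiple range test.

    Means are ranked; a pair spanning ``p`` ordered means differs iff its
    range exceeds ``R_p = q(1 - alpha_p, p, df) * sqrt(MSE / n_h)`` with the
    protected level ``alpha_p = 1 - (1 - alpha)^(p-1)`` and ``n_h`` the
    harmonic mean group size.  With *blocking* (textbook stepping) a
    non-significant outer span suppresses all declarations inside it.

    *mse*/*df_resid* default to the one-way pooled within-group values; pass
    the residual MS of a wider ANOVA to test within its scope.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    if mse is None or df_resid is None:
        mse, df_resid = _pooled_mse(groups)
    if df_resid <= 0 or not math.isfinite(mse):
        raise ValueError("Duncan test requires positive residual df")
    sizes = np.array([len(groups[g]) for g in labels], dtype=float)
    n_h = len(sizes) / (1.0 / sizes).sum()
    means = pd.Series({g: float(np.mean(groups[g])) for g in labels})
    order = means.sort_values().index.tolist()  # ascending
    k = len(order)
    se = math.sqrt(mse / n_h)

    def crit(p: int) -> float:
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df_resid)) * se

    different = pd.DataFrame(False, index=labels, columns=labels)
    blocked: list[tuple[int, int]] = []  # non-significant spans (by rank index)
    for p in range(k, 1, -1):
        r_p = crit(p)
        for i in range(0, k - p + 1):
            j = i + p - 1
            gi, gj = order[i], order[j]
            if blocking and any(bi <= i and j <= bj for bi, bj in blocked):
                continue
            if means[gj] - means[gi] > r_p:
                different.loc[gi, gj] = different.loc[gj, gi] = True
            elif blocking:
                blocked.append((i, j))
    return DuncanResult(different=different, means=means, mse=mse, df_resid=df_resid)


def dunn_bonferroni(groups: GroupData, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's rank test with tie correction; Bonferroni-adjusted p matrix."""
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks, pos = {}, 0
    for g in labels:
        mean_ranks[g] = ranks[pos:pos + sizes[g]].mean()
        pos += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1)))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    padj = pd.DataFrame(1.0, index=labels, columns=labels)
    for gi, gj in itertools.combinations(labels, 2):
        se = math.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        if se == 0:  # all observations tied
            p = 1.0
        else:
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))) * m)
        padj.loc[gi, gj] = padj.loc[gj, gi] = p
    return padj


def compact_letter_display(different: pd.DataFrame, means: pd.Series) -> pd.Series:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff they were not declared different.  Letter
    classes are ordered so the highest-mean groups take 'a'.
    """
    labels = list(different.index)
    mat = different.to_numpy()
    if not np.array_equal(mat, mat.T) or mat.diagonal().any():
        raise ValueError("decision matrix must be symmetric with a False diagonal")
    order = means.loc[labels].sort_values(ascending=False).index.tolist()
    classes: list[set[str]] = [set(order)]
    for gi, gj in itertools.combinations(order, 2):
        if not different.loc[gi, gj]:
            continue
        for cls in [c for c in classes if gi in c and gj in c]:
            classes.remove(cls)
            a, b = cls - {gi}, cls - {gj}
            for new in (a, b):
                if not any(new <= c for c in classes):
                    classes.append(new)
        # absorb any class now contained in another
        classes = [c for c in classes if not any(c < d for d in classes)]
    rank = {g: i for i, g in enumerate(order)}
    classes.sort(key=lambda c: min(rank[g] for g in c))
    if len(classes) > 26:
        raise ValueError("more than 26 letter classes are not representable")
    letters = {g: "" for g in labels}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in cls:
            letters[g] += letter
    return pd.Series({g: "".join(sorted(letters[g])) for g in labels})


def letter_table(groups: GroupData, alpha: float = 0.05) -> pd.DataFrame:
    """Full homogeneous-groups table: gate, post-hoc, letters.

    Returns columns group/mean/sd/letters plus the chosen path, ordered by
    descending mean.
    """
    gate = normality_gate(groups, alpha=alpha)
    if gate.path == "parametric":
        res = duncan_mrt(groups, alpha=alpha)
        different = res.different
    else:
        padj = dunn_bonferroni(groups, alpha=alpha)
        different = padj < alpha
        np.fill_diagonal(different.values, False)
    means = pd.Series({g: float(np.mean(groups[g])) for g in groups})
    sds = pd.Series({g: float(np.std(groups[g], ddof=1)) if len(groups[g]) > 1 else 0.0
                     for g in groups})
    letters = compact_letter_display(different, means)
    out = pd.DataFrame({
        "group": list(groups),
        "mean": [means[g] for g in groups],
        "sd": [sds[g] for g in groups],
        "letters": [letters[g] for g in groups],
    })
    out["path"] = gate.path
    return out.sort_values("mean", ascending=False).reset_index(drop=True)
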