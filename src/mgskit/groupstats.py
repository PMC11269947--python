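"""Nonparametric group comparison and effect-size statistics.

The inferential layer of the pipeline: Fisher's exact test (two-sided,
point-probability method) for 2x2 categorical tables, Mann-Whitney U for
two-group continuous contrasts, Kruskal-Wallis for three groups, Spearman
rank correlation, Hedges' g effect size with the small-sample correction,
Bonferroni adjustment, and a per-taxon screening routine that labels
significance tiers the way the figures do (*, **, *** plus a 0.05<p<0.1
trend tier).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

logger = logging.getLogger(__name__)

EXACT_MWU_MAX_N = 20  # combined n at or below which the exact MWU null is used


@dataclass(frozen=True)
class TestResult:
    label: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    effect_size: float | None = None
    n_per_group: tuple[int, ...] = ()


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]].

    Two-sided by the point-probability method: the sum of hypergeometric
    probabilities of all tables with the observed margins whose point
    probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise InputError("cell counts must be nonnegative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("empty margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    Exact null distribution when the combined sample size is at most 20 and
    there are no ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p (tie-corrected), df = k - 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InputError("need at least two nonempty groups")
    if all(np.all(g == groups[0][0]) for g in groups):
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (midrank ties) and two-sided p; constant input flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def hedges_g(x, y) -> float:
    """Bias-corrected standardized mean difference.

    g = J * (mean_x - mean_y) / s_pooled with J = 1 - 3 / (4(n1+n2-2) - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs at least two observations")
    s_pooled = np.sqrt(
        ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        logger.warning("zero pooled variance: Hedges' g undefined")
        return float("nan")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return float(j * (np.mean(x) - np.mean(y)) / s_pooled)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise InputError("p-values must be in [0, 1]")
    return multipletests(p, method="bonferroni")[1]


def significance_tier(p: float) -> str:
    """Figure-style tiers: *** / ** / * / trend (0.05 < p < 0.1) / ns."""
    if np.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "trend"
    return "ns"


def taxon_screen(
    matrix: pd.DataFrame,
    groups: pd.Series,
    test: str = "mannwhitney",
    adjust: bool = True,
    tier_on_adjusted: bool = False,
) -> pd.DataFrame:
    """Per-taxon group test over a samples x taxa abundance matrix.

    ``test`` is ``mannwhitney`` (exactly two group labels) or ``kruskal``.
    The Bonferroni family is all taxa screened in this one call. Output is
    sorted by raw p.
    """
    if matrix.empty:
        return pd.DataFrame(
            columns=["taxon", "statistic", "p_raw", "p_adjusted", "tier"]
        ).set_index("taxon")
    groups = groups.reindex(matrix.index)
    if groups.isna().any():
        raise InputError("group labels missing for some samples")
    labels = sorted(groups.unique())
    if test == "mannwhitney" and len(labels) != 2:
        raise InputError("mannwhitney screen needs exactly two groups")
    rows = []
    for taxon in matrix.columns:
        vals = [matrix.loc[groups == g, taxon].to_numpy() for g in labels]
        if test == "mannwhitney":
            stat, p = mann_whitney(vals[0], vals[1])
        elif test == "kruskal":
            stat, p = kruskal_wallis(vals)
        else:
            raise InputError(f"unknown test {test!r}")
        rows.append({"taxon": taxon, "statistic": stat, "p_raw": p})
    out = pd.DataFrame(rows).set_index("taxon")
    out["p_adjusted"] = bonferroni(out["p_raw"]) if adjust else np.nan
    tier_src = out["p_adjusted"] if (adjust and tier_on_adjusted) else out["p_raw"]
    out["tier"] = [significance_tier(p) for p in tier_src]
    return out.sort_values("p_raw")
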