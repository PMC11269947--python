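"""Interval discretization and association-rule mining.

Continuous clinical and diversity variables are cut into equal-width
interval bins; rules ``antecedent -> consequent`` over binned / categorical
variables are scored by support (percentage of all samples satisfying
antecedent and consequent) and confidence (percentage of
antecedent-satisfying samples that also satisfy the consequent). On an
n-sample cohort every support is therefore an exact multiple of 100/n.
Antecedents are conjunctions of up to ``max_order`` single-variable
predicates (Apriori-style enumeration); predictions apply the
highest-confidence matching rule, ties broken by support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalBin:
    """Half-open interval [lower, upper); the top bin of a partition is closed."""

    variable: str
    lower: float
    upper: float
    closed_right: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigError("bin lower bound must be below upper bound")

    def contains(self, value: float) -> bool:
        if self.closed_right:
            return self.lower <= value <= self.upper
        return self.lower <= value < self.upper

    def label(self, precision: int = 3) -> str:
        hi = "]" if self.closed_right else ")"
        return f"[{self.lower:.{precision}g}, {self.upper:.{precision}g}{hi}"


@dataclass(frozen=True)
class AssociationRule:
    """antecedent (conjunction of variable=value terms) -> consequent bin."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: tuple[str, str]
    support: float  # % of all samples with antecedent AND consequent
    confidence: float  # % of antecedent samples with the consequent
    n_antecedent: int
    n_joint: int

    def __str__(self) -> str:
        ante = " AND ".join(f"{v}={b}" for v, b in self.antecedent)
        return (
            f"{ante} -> {self.consequent[0]}={self.consequent[1]} "
            f"(support {self.support:.2f}%, confidence {self.confidence:.2f}%)"
        )


def discretize(
    values: Sequence[float],
    variable: str,
    n_bins: int = 4,
    edges: Sequence[float] | None = None,
) -> tuple[list[IntervalBin], np.ndarray]:
    """Assign each value to one interval bin.

    Default bins are equal-width over [min, max], right-open except for the
    top bin which is right-closed so the maximum is assigned. Explicit
    ``edges`` override the equal-width layout. Returns the bin list and the
    per-value bin index.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0 or not np.isfinite(vals).all():
        raise InputError("need at least one finite value")
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        if len(edges) < 2 or (np.diff(edges) <= 0).any():
            raise ConfigError("edges must be strictly increasing with length >= 2")
    else:
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            logger.warning("constant variable %r: single degenerate bin", variable)
            bins = [IntervalBin(variable, lo, lo + 1e-9, closed_right=True)]
            return bins, np.zeros(len(vals), dtype=int)
        if n_bins < 1:
            raise ConfigError("n_bins must be positive")
        edges = np.linspace(lo, hi, n_bins + 1)
    bins = [
        IntervalBin(variable, float(edges[i]), float(edges[i + 1]), closed_right=(i == len(edges) - 2))
        for i in range(len(edges) - 1)
    ]
    idx = np.searchsorted(edges, vals, side="right") - 1
    idx = np.clip(idx, 0, len(bins) - 1)
    for i, v in zip(idx, vals):
        if not bins[i].contains(v):
            raise InputError(f"value {v} outside the binned range of {variable!r}")
    return bins, idx


def bin_series(values: pd.Series, n_bins: int = 4, edges: Sequence[float] | None = None) -> tuple[pd.Series, list[IntervalBin]]:
    """Discretize a named Series into bin labels."""
    bins, idx = discretize(values.to_numpy(), str(values.name), n_bins, edges)
    labels = pd.Series([bins[i].label() for i in idx], index=values.index, name=values.name)
    return labels, bins


def mine_rules(
    table: pd.DataFrame,
    antecedent_vars: Sequence[str],
    consequent_var: str,
    min_support: float = 0.0,
    min_confidence: float = 0.0,
    max_order: int = 2,
) -> list[AssociationRule]:
    """Enumerate association rules over a table of bin/category labels.

    Support and confidence are plain relative frequencies in percent.
    Rules below either threshold, or with empty antecedents, are dropped.
    Output order: confidence desc, support desc, then lexicographic.
    """
    if not antecedent_vars:
        raise InputError("at least one antecedent variable is required")
    missing = set(antecedent_vars) | {consequent_var}
    missing -= set(table.columns)
    if missing:
        raise InputError(f"variables not in table: {sorted(missing)}")
    if consequent_var in antecedent_vars:
        raise ConfigError("consequent variable cannot also be an antecedent")
    n = len(table)
    if n == 0:
        return []
    rules = []
    cons_values = pd.unique(table[consequent_var].dropna())
    for order in range(1, max_order + 1):
        for var_combo in combinations(sorted(antecedent_vars), order):
            value_sets = [pd.unique(table[v].dropna()) for v in var_combo]
            for values in product(*value_sets):
                mask = np.ones(n, dtype=bool)
                for v, val in zip(var_combo, values):
                    mask &= (table[v] == val).to_numpy()
                n_ante = int(mask.sum())
                if n_ante == 0:
                    continue
                for cons in cons_values:
                    joint = mask & (table[consequent_var] == cons).to_numpy()
                    n_joint = int(joint.sum())
                    if n_joint == 0:
                        continue
                    support = 100.0 * n_joint / n
                    confidence = 100.0 * n_joint / n_ante
                    if support >= min_support and confidence >= min_confidence:
                        rules.append(
                            AssociationRule(
                                antecedent=tuple(
                                    (v, str(val)) for v, val in zip(var_combo, values)
                                ),
                                consequent=(consequent_var, str(cons)),
                                support=support,
                                confidence=confidence,
                                n_antecedent=n_ante,
                                n_joint=n_joint,
                            )
                        )
    rules.sort(key=lambda r: (-r.confidence, -r.support, str(r)))
    return rules


def predict_bin(
    rules: Sequence[AssociationRule], sample: Mapping[str, str]
) -> tuple[str, str] | None:
    """Consequent of the best applicable rule, or None.

    Best = highest confidence, ties broken by higher support (the mined
    list is already in that order).
    """
    for rule in rules:
        if all(sample.get(v) == val for v, val in rule.antecedent):
            return rule.consequent
    return None


def rules_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Rules as a tidy DataFrame (percentages to 2 dp)."""
    rows = []
    for r in rules:
        rows.append(
            {
                "antecedent": " AND ".join(f"{v}={b}" for v, b in r.antecedent),
                "consequent": f"{r.consequent[0]}={r.consequent[1]}",
                "support_pct": round(r.support, 2),
                "confidence_pct": round(r.confidence, 2),
                "n_antecedent": r.n_antecedent,
                "n_joint": r.n_joint,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["antecedent", "consequent", "support_pct", "confidence_pct", "n_antecedent", "n_joint"],
    )
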