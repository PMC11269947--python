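"""Rank-specific consensus taxonomy annotation of MGSs from blast-like hits.

At each rank an MGS is assigned taxon T iff at least M% of its member genes
resolve to T and no more than D% resolve to a different taxon at that rank,
considering only hits with alignment length >= 100 bp, query coverage >=
50% and percent identity >= a rank-specific PID. A gene resolves to the
taxon of its best eligible hit (highest identity, then longest alignment,
then lexicographic taxon). Ranks are annotated independently; the MGS label
is the most specific successful rank, and lineage conflicts between ranks
are resolved in favour of the more specific rank with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cohortsim import RANKS, MGSDefinition
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

MIN_ALIGNMENT_LENGTH = 100
MIN_QUERY_COVERAGE = 0.5

_DEFAULT_PID = dict(zip(RANKS, (95, 95, 85, 75, 65, 55, 50, 45)))
_DEFAULT_M = dict(zip(RANKS, (75, 75, 60, 50, 40, 30, 25, 20)))
_DEFAULT_D = dict(zip(RANKS, (10, 10, 10, 20, 20, 20, 20, 15)))


@dataclass(frozen=True)
class RankParams:
    """Per-rank PID / M / D percentage thresholds."""

    pid: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_PID))
    m: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_M))
    d: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_D))

    def validate(self) -> None:
        for table in (self.pid, self.m, self.d):
            missing = set(RANKS) - set(table)
            if missing:
                raise ConfigError(f"rank params missing ranks: {sorted(missing)}")


def filter_hits(hit_table: pd.DataFrame, rank: str, params: RankParams | None = None) -> pd.DataFrame:
    """Hits eligible at a rank: long enough, covered enough, identity >= PID."""
    params = params or RankParams()
    params.validate()
    if rank not in RANKS:
        raise ConfigError(f"unknown rank {rank!r}")
    keep = (
        (hit_table["alignment_length"] >= MIN_ALIGNMENT_LENGTH)
        & (hit_table["query_coverage"] >= MIN_QUERY_COVERAGE)
        & (hit_table["percent_identity"] >= params.pid[rank])
    )
    return hit_table[keep]


def gene_taxa_at_rank(eligible_hits: pd.DataFrame, rank: str) -> pd.Series:
    """Resolve each gene to the taxon of its best eligible hit at a rank.

    Best = highest identity, then longest alignment, then lexicographically
    smallest taxon. Genes whose hits carry no annotation at the rank are
    dropped.
    """
    hits = eligible_hits.dropna(subset=[rank])
    if hits.empty:
        return pd.Series(dtype=object)
    ordered = hits.sort_values(
        ["gene_id", "percent_identity", "alignment_length", rank],
        ascending=[True, False, False, True],
    )
    best = ordered.drop_duplicates("gene_id", keep="first")
    return best.set_index("gene_id")[rank]


def annotate_rank(
    mgs_def: MGSDefinition,
    eligible_hits: pd.DataFrame,
    rank: str,
    params: RankParams | None = None,
) -> str | None:
    """Consensus taxon for one MGS at one rank, or None.

    The denominator for both the M% support and D% disagreement fractions
    is the full member gene set of the MGS.
    """
    params = params or RankParams()
    gene_taxa = gene_taxa_at_rank(eligible_hits, rank)
    gene_taxa = gene_taxa[gene_taxa.index.isin(mgs_def.gene_ids)]
    n_genes = len(mgs_def.gene_ids)
    if gene_taxa.empty or n_genes == 0:
        return None
    counts = gene_taxa.value_counts()
    # candidate order: highest gene fraction, ties by lexicographic id
    for taxon in sorted(counts.index, key=lambda t: (-int(counts[t]), str(t))):
        support = counts[taxon] / n_genes
        disagree = (counts.sum() - counts[taxon]) / n_genes
        if support >= params.m[rank] / 100.0 and disagree <= params.d[rank] / 100.0:
            return str(taxon)
    return None


def annotate_mgs(
    mgs_def: MGSDefinition,
    hit_table: pd.DataFrame,
    params: RankParams | None = None,
) -> dict[str, str | None]:
    """Per-rank lineage for one MGS; ranks are evaluated independently."""
    params = params or RankParams()
    params.validate()
    mgs_hits = hit_table[hit_table["gene_id"].isin(mgs_def.gene_ids)]
    lineage: dict[str, str | None] = {}
    for rank in RANKS:
        eligible = filter_hits(mgs_hits, rank, params)
        lineage[rank] = annotate_rank(mgs_def, eligible, rank, params)
    _log_conflicts(mgs_def.mgs_id, lineage, hit_table)
    return lineage


def most_specific_rank(lineage: Mapping[str, str | None]) -> str | None:
    """The most specific rank (subspecies first) with an assignment."""
    for rank in RANKS:
        if lineage.get(rank) is not None:
            return rank
    return None


def _log_conflicts(mgs_id: str, lineage: dict, hit_table: pd.DataFrame) -> None:
    """Note parent/child disagreements; the more specific rank stands."""
    parent_of = {}
    for child_rank, taxon in lineage.items():
        if taxon is None:
            continue
        rows = hit_table[hit_table[child_rank] == taxon]
        if rows.empty:
            continue
        idx = RANKS.index(child_rank)
        for parent_rank in RANKS[idx + 1:]:
            expected = rows[parent_rank].dropna()
            if expected.empty:
                continue
            parent_of[(child_rank, parent_rank)] = expected.mode().iloc[0]
    for (child_rank, parent_rank), expected in parent_of.items():
        assigned = lineage.get(parent_rank)
        if assigned is not None and assigned != expected:
            logger.warning(
                "%s: %s assignment %r conflicts with %s-implied parent %r; keeping the more specific rank",
                mgs_id, parent_rank, assigned, child_rank, expected,
            )


def annotate_all(
    mgs_defs: Sequence[MGSDefinition],
    hit_table: pd.DataFrame,
    params: RankParams | None = None,
) -> pd.DataFrame:
    """Lineage table (MGS x ranks) plus the most specific assigned rank."""
    rows = {}
    for d in mgs_defs:
        lineage = annotate_mgs(d, hit_table, params)
        lineage["best_rank"] = most_specific_rank(lineage)
        rows[d.mgs_id] = lineage
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "mgs_id"
    return df[list(RANKS) + ["best_rank"]]
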