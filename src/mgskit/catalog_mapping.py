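"""Read-to-gene-catalog classification and gene count tables.

An individual read is *uniquely mapped* to a gene if MAPQ >= 20 and it
aligned with >= 95% identity over >= 100 bp; if more than 10 bases of the
read did not align to the gene (or extended beyond it) the read is
*unmapped* regardless of the other criteria; reads passing identity/length
with acceptable overhang but MAPQ < 20 are *multi-mapped*. A read pair is
counted as uniquely mapped to one gene if either mate is unique (read 1's
gene wins if both are, each to a different gene), multi-mapped if neither is
unique and at least one is multi, and unmapped otherwise. The gene count
table holds uniquely mapped pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InputError

UNIQUE, MULTI, UNMAPPED = "unique", "multi", "unmapped"


@dataclass(frozen=True)
class MappingThresholds:
    mapq_min: int = 20
    identity_min: float = 95.0
    length_min: int = 100
    max_overhang: int = 10


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's alignment evidence against one catalog gene."""

    read_id: str
    mate: int
    gene_id: str | None
    mapq: int
    percent_identity: float
    aligned_length: int
    unaligned_bases: int

    def __post_init__(self) -> None:
        if self.mapq < 0 or self.aligned_length < 0 or self.unaligned_bases < 0:
            raise InputError("alignment fields must be nonnegative")


def classify_read(
    record: AlignmentRecord, thresholds: MappingThresholds = MappingThresholds()
) -> str:
    """Classify a single read as unique / multi / unmapped."""
    if record.gene_id is None:
        return UNMAPPED
    if record.unaligned_bases > thresholds.max_overhang:
        return UNMAPPED
    if (
        record.percent_identity < thresholds.identity_min
        or record.aligned_length < thresholds.length_min
    ):
        return UNMAPPED
    if record.mapq >= thresholds.mapq_min:
        return UNIQUE
    return MULTI


def classify_pair(
    status1: str, gene1: str | None, status2: str, gene2: str | None
) -> tuple[str, str | None]:
    """Combine per-mate statuses into a pair status and the counted gene."""
    if status1 == UNIQUE and gene1 is None:
        raise InputError("unique read 1 without a gene")
    if status2 == UNIQUE and gene2 is None:
        raise InputError("unique read 2 without a gene")
    if status1 == UNIQUE:
        return UNIQUE, gene1
    if status2 == UNIQUE:
        return UNIQUE, gene2
    if MULTI in (status1, status2):
        return MULTI, None
    return UNMAPPED, None


def _classify_columns(
    df: pd.DataFrame, thresholds: MappingThresholds
) -> np.ndarray:
    """Vectorized per-read classification over an alignment table."""
    for col in ("mapq", "aligned_length", "unaligned_bases"):
        if (df[col].to_numpy() < 0).any():
            raise InputError(f"negative values in column {col!r}")
    mapped = df["gene_id"].notna().to_numpy()
    over = df["unaligned_bases"].to_numpy() > thresholds.max_overhang
    weak = (df["percent_identity"].to_numpy() < thresholds.identity_min) | (
        df["aligned_length"].to_numpy() < thresholds.length_min
    )
    unmapped = ~mapped | over | weak
    unique = ~unmapped & (df["mapq"].to_numpy() >= thresholds.mapq_min)
    out = np.full(len(df), MULTI, dtype=object)
    out[unmapped] = UNMAPPED
    out[unique] = UNIQUE
    return out


def build_gene_count_table(
    records: pd.DataFrame,
    thresholds: MappingThresholds = MappingThresholds(),
    drop_host: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene count table (genes x samples) plus a per-sample mapping summary.

    ``records`` holds one row per mate with columns sample_id, read_id,
    mate, gene_id, mapq, percent_identity, aligned_length, unaligned_bases
    and optionally host. Host-flagged pairs are removed first (they are not
    HQNH and never reach the mapper in the real workflow).
    """
    required = {"sample_id", "read_id", "mate", "gene_id", "mapq",
                "percent_identity", "aligned_length", "unaligned_bases"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"alignment table missing columns: {sorted(missing)}")
    if records.duplicated(subset=["sample_id", "read_id", "mate"]).any():
        raise InputError("duplicate (sample_id, read_id, mate) rows")

    counts: dict[str, pd.Series] = {}
    summaries = []
    for sample_id, df in records.groupby("sample_id", sort=True):
        if drop_host and "host" in df.columns:
            host_reads = df.loc[df["host"].astype(bool), "read_id"].unique()
            df = df[~df["read_id"].isin(host_reads)]
        genes, summary = _count_sample(df, thresholds)
        counts[sample_id] = genes
        summaries.append({"sample_id": sample_id, **summary})

    table = pd.DataFrame(counts).fillna(0).astype(int)
    table.index.name = "gene_id"
    summary_df = pd.DataFrame(summaries).set_index("sample_id")
    return table.sort_index(), summary_df


def _count_sample(df: pd.DataFrame, thresholds: MappingThresholds):
    status = _classify_columns(df, thresholds)
    read_ids, codes = np.unique(df["read_id"].to_numpy(), return_inverse=True)
    n_pairs = len(read_ids)
    mate = df["mate"].to_numpy()
    gene = df["gene_id"].to_numpy(dtype=object)

    # per-pair slots: status and gene for each mate
    stat = np.full((n_pairs, 2), UNMAPPED, dtype=object)
    gen = np.full((n_pairs, 2), None, dtype=object)
    m_idx = np.where(mate == 1, 0, 1)
    stat[codes, m_idx] = status
    gen[codes, m_idx] = gene

    u1 = stat[:, 0] == UNIQUE
    u2 = stat[:, 1] == UNIQUE
    is_unique = u1 | u2
    is_multi = ~is_unique & ((stat[:, 0] == MULTI) | (stat[:, 1] == MULTI))
    is_unmapped = ~is_unique & ~is_multi

    counted = np.where(u1, gen[:, 0], np.where(u2, gen[:, 1], None))
    counted = counted[is_unique]
    genes = pd.Series(counted, dtype=object).value_counts()
    genes.index.name = "gene_id"

    summary = {
        "hqnh_pairs": int(n_pairs),
        "frac_unique": float(is_unique.mean()) if n_pairs else 0.0,
        "frac_multi": float(is_multi.mean()) if n_pairs else 0.0,
        "frac_unmapped": float(is_unmapped.mean()) if n_pairs else 0.0,
    }
    return genes.astype(int), summary


def classify_records_frame(
    records: pd.DataFrame, thresholds: MappingThresholds = MappingThresholds()
) -> pd.Series:
    """Per-read statuses for an alignment table (diagnostic surface)."""
    return pd.Series(_classify_columns(records, thresholds), index=records.index)


def read_alignment_tsv(path) -> pd.DataFrame:
    """Load the documented alignment TSV (one mate per row)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "read_id": str})
    df["gene_id"] = df["gene_id"].where(df["gene_id"].notna(), None)
    return df


def records_from_frame(df: pd.DataFrame) -> Iterable[AlignmentRecord]:
    for row in df.itertuples(index=False):
        yield AlignmentRecord(
            read_id=str(row.read_id),
            mate=int(row.mate),
            gene_id=None if pd.isna(row.gene_id) else str(row.gene_id),
            mapq=int(row.mapq),
            percent_identity=float(row.percent_identity),
            aligned_length=int(row.aligned_length),
            unaligned_bases=int(row.unaligned_bases),
        )
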