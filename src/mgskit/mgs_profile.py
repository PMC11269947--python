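"""MGS abundance profiling from gene count tables.

The abundance of a metagenomic species (MGS) is the number of read pairs
uniquely mapped to its signature gene set (100 genes by default). An MGS is
*detected* in a sample only if reads hit at least three distinct signature
genes; weaker measurements are zeroed. Counts are normalized by the mean
effective signature-gene length of the MGS and then sample-wise to 100%.
Rarefied profiles down-sample a fixed number of signature-gene counts per
sample without replacement (multivariate hypergeometric over the gene-level
signature counts) before re-applying detection and normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohortsim import RANKS, MGSDefinition
from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 3
DEFAULT_RAREFACTION_DEPTH = 524050
DEFAULT_READ_LENGTH = 150


@dataclass
class AbundanceMatrix:
    """Samples x features abundance values with an explicit state.

    ``state`` is one of ``raw_counts``, ``rarefied_counts`` or ``relative``;
    relative rows sum to 100% (or 0% for an all-zero sample).
    """

    data: pd.DataFrame
    state: str
    total_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.state not in {"raw_counts", "rarefied_counts", "relative"}:
            raise InputError(f"unknown abundance state {self.state!r}")
        if self.state != "relative":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise InputError("counts must be nonnegative")


def signature_gene_counts(
    gene_counts: pd.DataFrame, mgs_defs: Sequence[MGSDefinition]
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict a genes x samples count table to signature genes.

    Returns the signature-gene count table (genes x samples, full signature
    index, zero-filled) and a gene -> MGS mapping. Unknown gene ids in the
    input are ignored with a logged warning.
    """
    sig_map = {}
    for d in mgs_defs:
        for g in d.signature_gene_ids:
            sig_map[g] = d.mgs_id
    known = gene_counts.index.isin(sig_map) | gene_counts.index.isin(
        {g for d in mgs_defs for g in d.gene_ids}
    )
    if not known.all():
        logger.warning("%d gene ids not in any MGS definition; ignored", (~known).sum())
    sig_index = pd.Index(sorted(sig_map), name="gene_id")
    table = gene_counts.reindex(sig_index).fillna(0).astype(int)
    mgs_of_gene = pd.Series({g: sig_map[g] for g in sig_index}, name="mgs_id")
    return table, mgs_of_gene


def count_signature_reads(
    gene_counts: pd.DataFrame, mgs_defs: Sequence[MGSDefinition]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MGS count matrix and detected-signature-gene count matrix.

    Both are samples x MGS. The MGS count is the sum of uniquely mapped pair
    counts over its signature genes only; member non-signature genes
    contribute nothing.
    """
    sig_table, mgs_of_gene = signature_gene_counts(gene_counts, mgs_defs)
    mgs_counts = sig_table.groupby(mgs_of_gene).sum().T
    detected = (sig_table > 0).groupby(mgs_of_gene).sum().T
    order = [d.mgs_id for d in mgs_defs]
    return (
        mgs_counts.reindex(columns=order, fill_value=0),
        detected.reindex(columns=order, fill_value=0),
    )


def apply_detection_filter(
    mgs_counts: pd.DataFrame,
    detected_gene_counts: pd.DataFrame,
    min_genes: int = DEFAULT_MIN_GENES,
) -> pd.DataFrame:
    """Zero measurements supported by fewer than ``min_genes`` signature genes."""
    if mgs_counts.shape != detected_gene_counts.shape:
        raise InputError("count and detection matrices are not aligned")
    return mgs_counts.where(detected_gene_counts >= min_genes, 0)


def rarefy_signature_counts(
    sig_gene_counts: pd.DataFrame,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Down-sample gene-level signature counts without replacement.

    Returns the rarefied genes x samples table (samples below ``depth``
    dropped) and the list of excluded sample ids. Per-sample totals after
    rarefaction equal ``depth`` exactly.
    """
    if depth <= 0:
        raise ConfigError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    kept = {}
    excluded = []
    for sample in sig_gene_counts.columns:
        col = sig_gene_counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            excluded.append(sample)
            logger.warning(
                "sample %s has %d signature counts < depth %d; excluded", sample, total, depth
            )
            continue
        if total == depth:
            kept[sample] = col
        else:
            kept[sample] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(kept, index=sig_gene_counts.index).astype(int)
    return out, excluded


def mean_effective_signature_length(
    catalog: pd.DataFrame, mgs_defs: Sequence[MGSDefinition]
) -> pd.Series:
    """Per-MGS mean effective length over its signature genes."""
    eff = catalog["effective_length"]
    if (eff <= 0).any():
        raise ConfigError("effective lengths must be positive")
    return pd.Series(
        {d.mgs_id: float(eff.loc[list(d.signature_gene_ids)].mean()) for d in mgs_defs},
        name="mean_effective_length",
    )


def effective_length(length: int, read_length: int = DEFAULT_READ_LENGTH) -> int:
    """Number of valid read start positions on a gene, floored at 1."""
    return max(1, int(length) - int(read_length) + 1)


def normalize_relative(
    counts: pd.DataFrame, effective_lengths: Mapping[str, float] | pd.Series
) -> AbundanceMatrix:
    """Length-normalize then scale each sample row to sum to 100%."""
    lens = pd.Series(effective_lengths).reindex(counts.columns)
    if lens.isna().any():
        raise ConfigError("missing effective length for some MGSs")
    if (lens <= 0).any():
        raise ConfigError("effective lengths must be positive")
    dens = counts.div(lens, axis=1)
    totals = dens.sum(axis=1)
    rel = dens.div(totals.where(totals > 0, 1.0), axis=0) * 100.0
    rel[totals == 0] = 0.0
    return AbundanceMatrix(rel, "relative", total_counts=counts.sum(axis=1))


def aggregate_by_rank(
    relative: AbundanceMatrix | pd.DataFrame,
    lineages: Mapping[str, Mapping[str, str | None]],
    rank: str,
    unclassified_label: str = "unclassified",
) -> pd.DataFrame:
    """Sum MGS columns into taxa at the given rank; row sums are preserved.

    MGSs without an annotation at that rank are pooled into an
    ``unclassified`` column.
    """
    if rank not in RANKS:
        raise ConfigError(f"unknown rank {rank!r}; expected one of {RANKS}")
    df = relative.data if isinstance(relative, AbundanceMatrix) else relative
    taxon_of = {}
    for mgs in df.columns:
        lin = lineages.get(mgs, {})
        taxon_of[mgs] = lin.get(rank) or unclassified_label
    grouped = df.T.groupby(pd.Series(taxon_of)).sum().T
    grouped.columns.name = rank
    return grouped


def profile_pipeline(
    gene_counts: pd.DataFrame,
    catalog: pd.DataFrame,
    mgs_defs: Sequence[MGSDefinition],
    min_genes: int = DEFAULT_MIN_GENES,
    rarefaction_depth: int | None = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
) -> dict:
    """Full profiling: counts, detection, optional rarefaction, normalization.

    Returns a dict with raw and (if requested) rarefied MGS count matrices,
    their relative AbundanceMatrix forms, and the excluded-sample list.
    """
    mgs_counts, detected = count_signature_reads(gene_counts, mgs_defs)
    filtered = apply_detection_filter(mgs_counts, detected, min_genes)
    lens = mean_effective_signature_length(catalog, mgs_defs)
    out = {
        "mgs_counts": AbundanceMatrix(filtered, "raw_counts"),
        "detected_genes": detected,
        "relative": normalize_relative(filtered, lens),
        "excluded_samples": [],
    }
    if rarefaction_depth is not None:
        sig_table, _ = signature_gene_counts(gene_counts, mgs_defs)
        rare_genes, excluded = rarefy_signature_counts(sig_table, rarefaction_depth, seed)
        r_counts, r_detected = count_signature_reads(rare_genes, mgs_defs)
        r_filtered = apply_detection_filter(r_counts, r_detected, min_genes)
        out["rarefied_counts"] = AbundanceMatrix(r_filtered, "rarefied_counts")
        out["rarefied_relative"] = normalize_relative(r_filtered, lens)
        out["excluded_samples"] = excluded
    return out


def detection_specificity_simulation(
    n_trials: int = 2000,
    signature_size: int = 100,
    background_rate: float = 0.01,
    min_genes: int = DEFAULT_MIN_GENES,
    seed: int = 0,
) -> float:
    """Specificity of the >=3-signature-gene detection rule under background noise.

    Simulates absent MGSs receiving spurious counts on each signature gene
    with a small Poisson rate and reports the fraction of trials correctly
    left undetected. Qualitative analogue of a vendor-style benchmark; not
    calibrated to any external figure.
    """
    rng = np.random.default_rng(seed)
    hits = rng.poisson(background_rate, size=(n_trials, signature_size)) > 0
    false_detect = (hits.sum(axis=1) >= min_genes).mean()
    return float(1.0 - false_detect)
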