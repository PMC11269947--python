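"""Synthetic cohort, gene-catalog and sequencing-evidence generator.

Everything the downstream pipeline consumes is produced here with known
ground truth: a neonatal cohort (preterm controls and medically / surgically
treated NEC survivors sampled at five years of age), per-sample true MGS
community profiles, a gene catalog with per-MGS signature gene sets and
taxonomic lineages, blast-like per-gene hit tables, and per-sample alignment
records (optionally FASTQ) emulating what a short-read aligner would report
against the catalog.

The community model is a per-group log-normal weight model mapped through a
Dirichlet draw: each sample draws per-MGS weights ``w_i = exp(sigma * z_i)``
with ``z_i ~ N(0, 1)`` and a sample-specific ``sigma`` that increases with
NEC severity (surgical > medical > control) and with antibiotic-exposure
days. Larger ``sigma`` concentrates the community on fewer MGSs, which lowers
Shannon entropy and raises dominance, reproducing the direction of the
group contrasts the pipeline is meant to detect. The Dirichlet draw around
the normalized weights adds compositional noise; the drawn profile is the
ground truth recorded for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

GROUPS = ("control", "nec_medical", "nec_surgical")

RANKS = (
    "subspecies",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortRecord:
    """One child: group label and the clinical covariates the analyses use."""

    sample_id: str
    group: str
    sex_female: int
    cesarean: int
    abdominal_surgery: int
    antibiotic_days: int
    pn_days: int
    age_at_sample: float


@dataclass(frozen=True)
class CohortConfig:
    """Group sizes and covariate distributions.

    Medians default to the study design this package emulates: 24 preterm
    controls, 7 medically and 8 surgically treated NEC children, with median
    antibiotic exposure of 10 / 28 / 36 days respectively.
    """

    n_control: int = 24
    n_medical: int = 7
    n_surgical: int = 8
    antibiotic_days_median: Mapping[str, float] = field(
        default_factory=lambda: {"control": 10.0, "nec_medical": 28.0, "nec_surgical": 36.0}
    )
    pn_days_median: Mapping[str, float] = field(
        default_factory=lambda: {"control": 9.0, "nec_medical": 28.0, "nec_surgical": 49.0}
    )
    days_log_sd: float = 0.35
    cesarean_rate: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.46, "nec_medical": 0.43, "nec_surgical": 0.75}
    )
    abdominal_surgery_rate: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.04, "nec_medical": 0.57, "nec_surgical": 1.0}
    )
    female_rate: float = 0.55
    age_mean: float = 5.1
    age_sd: float = 0.3

    def validate(self) -> None:
        if self.n_control < 1:
            raise ConfigError("the control group needs at least one sample")
        if self.n_medical < 0 or self.n_surgical < 0:
            raise ConfigError("group sizes cannot be negative")
        for m in (self.antibiotic_days_median, self.pn_days_median):
            if any(v < 0 for v in m.values()):
                raise ConfigError("day medians must be nonnegative")
        if self.days_log_sd < 0 or self.age_sd < 0:
            raise ConfigError("spread parameters must be nonnegative")
        for rates in (self.cesarean_rate, self.abdominal_surgery_rate):
            if any(not 0 <= r <= 1 for r in rates.values()):
                raise ConfigError("rates must be in [0, 1]")
        if not 0 <= self.female_rate <= 1:
            raise ConfigError("female_rate must be in [0, 1]")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "nec_medical": self.n_medical,
            "nec_surgical": self.n_surgical,
        }


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> list[CohortRecord]:
    """Draw a reproducible synthetic cohort.

    Antibiotic and parenteral-nutrition days are log-normal around the
    configured per-group medians, so the surgical > medical > control
    ordering holds stochastically.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    prefix = {"control": "C", "nec_medical": "M", "nec_surgical": "S"}
    records: list[CohortRecord] = []
    for group in GROUPS:
        n = config.group_sizes[group]
        ab = np.rint(
            config.antibiotic_days_median[group] * rng.lognormal(0.0, config.days_log_sd, n)
        ).astype(int)
        pn = np.rint(
            config.pn_days_median[group] * rng.lognormal(0.0, config.days_log_sd, n)
        ).astype(int)
        sex = rng.random(n) < config.female_rate
        ces = rng.random(n) < config.cesarean_rate[group]
        surg = rng.random(n) < config.abdominal_surgery_rate[group]
        age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 4.3, 6.0)
        for i in range(n):
            records.append(
                CohortRecord(
                    sample_id=f"{prefix[group]}{i + 1:02d}",
                    group=group,
                    sex_female=int(sex[i]),
                    cesarean=int(ces[i]),
                    abdominal_surgery=int(surg[i]),
                    antibiotic_days=int(ab[i]),
                    pn_days=int(pn[i]),
                    age_at_sample=round(float(age[i]), 2),
                )
            )
    return records


def cohort_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame indexed by sample_id."""
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# gene catalog, MGS definitions, taxon hit table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MGSDefinition:
    """An MGS: its member genes, the signature subset, and a true lineage."""

    mgs_id: str
    gene_ids: tuple[str, ...]
    signature_gene_ids: tuple[str, ...]
    lineage: Mapping[str, str | None]

    def __post_init__(self) -> None:
        if not set(self.signature_gene_ids) <= set(self.gene_ids):
            raise ConfigError("signature genes must be a subset of member genes")


@dataclass(frozen=True)
class CatalogConfig:
    n_mgs: int = 50
    genes_per_mgs: int = 300
    signature_size: int = 100
    read_length: int = 150
    median_gene_length: float = 900.0
    gene_length_log_sd: float = 0.5
    species_annotated_frac: float = 0.7
    n_genera: int = 15
    n_families: int = 8
    n_orders: int = 5
    n_classes: int = 4
    n_phyla: int = 4
    # per-gene hit probabilities for the synthetic blast table
    hit_rate_clean: float = 0.85
    hit_rate_coarse: float = 0.75
    contaminant_rate: float = 0.03
    junk_rate: float = 0.05

    def validate(self) -> None:
        if self.n_mgs < 1 or self.genes_per_mgs < 1:
            raise ConfigError("n_mgs and genes_per_mgs must be positive")
        if self.signature_size > self.genes_per_mgs:
            raise ConfigError("signature size cannot exceed member genes per MGS")
        if self.signature_size < 1:
            raise ConfigError("signature size must be positive")
        if not 0 <= self.species_annotated_frac <= 1:
            raise ConfigError("species_annotated_frac must be in [0, 1]")


def _lineage_tables(cfg: CatalogConfig, rng: np.random.Generator) -> list[dict[str, str | None]]:
    """Random nested taxonomy: each MGS gets a lineage through a random tree."""
    phyla = [f"Phylum{i + 1:02d}" for i in range(cfg.n_phyla)]
    classes = [f"Class{i + 1:02d}" for i in range(cfg.n_classes)]
    orders = [f"Order{i + 1:02d}" for i in range(cfg.n_orders)]
    families = [f"Family{i + 1:02d}" for i in range(cfg.n_families)]
    genera = [f"Genus{i + 1:02d}" for i in range(cfg.n_genera)]
    class_phylum = {c: phyla[rng.integers(cfg.n_phyla)] for c in classes}
    order_class = {o: classes[rng.integers(cfg.n_classes)] for o in orders}
    family_order = {f: orders[rng.integers(cfg.n_orders)] for f in families}
    genus_family = {g: families[rng.integers(cfg.n_families)] for g in genera}
    lineages = []
    for i in range(cfg.n_mgs):
        genus = genera[rng.integers(cfg.n_genera)]
        family = genus_family[genus]
        order = family_order[family]
        klass = order_class[order]
        lineages.append(
            {
                "subspecies": None,
                "species": f"Species{i + 1:03d}",
                "genus": genus,
                "family": family,
                "order": order,
                "class": klass,
                "phylum": class_phylum[klass],
                "superkingdom": "Bacteria",
            }
        )
    return lineages


def generate_catalog(
    config: CatalogConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, list[MGSDefinition], pd.DataFrame]:
    """Generate (gene catalog, MGS definitions, taxon hit table).

    The hit table is constructed so that a configurable fraction of MGSs has
    clean species-level support (high-identity hits on most genes) while the
    rest only carries coarse hits whose identity passes the genus threshold
    but not the species one, exercising the rank-specific annotation rules.
    A small contaminant and junk-hit rate is mixed in.
    """
    cfg = config or CatalogConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    lineages = _lineage_tables(cfg, rng)
    species_clean = rng.random(cfg.n_mgs) < cfg.species_annotated_frac

    gene_rows = []
    defs: list[MGSDefinition] = []
    hit_rows: list[dict] = []
    for i in range(cfg.n_mgs):
        mgs_id = f"MGS{i + 1:03d}"
        gene_ids = tuple(f"{mgs_id}_g{j + 1:04d}" for j in range(cfg.genes_per_mgs))
        lengths = np.maximum(
            100,
            np.rint(
                rng.lognormal(math.log(cfg.median_gene_length), cfg.gene_length_log_sd, cfg.genes_per_mgs)
            ).astype(int),
        )
        for gid, length in zip(gene_ids, lengths):
            gene_rows.append(
                {
                    "gene_id": gid,
                    "mgs_id": mgs_id,
                    "length": int(length),
                    "effective_length": max(1, int(length) - cfg.read_length + 1),
                }
            )
        sig = tuple(sorted(rng.choice(gene_ids, size=cfg.signature_size, replace=False)))
        defs.append(
            MGSDefinition(
                mgs_id=mgs_id,
                gene_ids=gene_ids,
                signature_gene_ids=sig,
                lineage=lineages[i],
            )
        )
        hit_rows.extend(
            _mgs_hits(cfg, rng, gene_ids, lineages[i], lineages, i, bool(species_clean[i]))
        )

    catalog = pd.DataFrame(gene_rows).set_index("gene_id")
    hits = pd.DataFrame(
        hit_rows,
        columns=["gene_id", "alignment_length", "query_coverage", "percent_identity", *RANKS],
    )
    return catalog, defs, hits


def _mgs_hits(cfg, rng, gene_ids, lineage, all_lineages, idx, clean: bool) -> list[dict]:
    rows = []
    hit_rate = cfg.hit_rate_clean if clean else cfg.hit_rate_coarse
    others = [j for j in range(len(all_lineages)) if j != idx]
    for gid in gene_ids:
        u = rng.random()
        if u < hit_rate:
            target = dict(lineage)
            if clean:
                identity = rng.uniform(96.0, 99.8)
            else:
                # neighbour species in the same genus: passes the genus PID
                # threshold (85) but not the species one (95)
                identity = rng.uniform(86.0, 94.0)
                target["species"] = f"{lineage['species']}_rel"
            rows.append(_hit(rng, gid, target, identity))
        elif u < hit_rate + cfg.contaminant_rate and others:
            other = all_lineages[int(rng.choice(others))]
            rows.append(_hit(rng, gid, other, rng.uniform(96.0, 99.0)))
        elif u < hit_rate + cfg.contaminant_rate + cfg.junk_rate:
            # fails length or coverage filters regardless of rank
            row = _hit(rng, gid, lineage, rng.uniform(96.0, 99.0))
            if rng.random() < 0.5:
                row["alignment_length"] = int(rng.integers(30, 99))
            else:
                row["query_coverage"] = float(rng.uniform(0.05, 0.45))
            rows.append(row)
    return rows


def _hit(rng, gene_id, lineage, identity) -> dict:
    row = {
        "gene_id": gene_id,
        "alignment_length": int(rng.integers(120, 500)),
        "query_coverage": float(rng.uniform(0.55, 1.0)),
        "percent_identity": float(identity),
    }
    row.update({r: lineage.get(r) for r in RANKS})
    return row


# ---------------------------------------------------------------------------
# ground-truth community profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthProfile:
    sample_id: str
    abundances: np.ndarray  # fractions over MGSs, sum to 1
    sigma: float

    def __post_init__(self) -> None:
        total = float(np.sum(self.abundances))
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"profile must sum to 1, got {total}")


@dataclass(frozen=True)
class EffectConfig:
    """Group and covariate effects on community evenness.

    ``sigma`` of the log-normal weights is base + group delta +
    per-antibiotic-day coupling; larger sigma means a more dominated, less
    diverse community. Defaults place synthetic Shannon entropy roughly in
    the 1.2-3.3 nats range with surgical < medical < control.
    """

    base_sigma: float = 1.0
    group_sigma_delta: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "nec_medical": 0.35, "nec_surgical": 0.8}
    )
    antibiotic_sigma_per_day: float = 0.015
    dirichlet_concentration: float = 200.0

    def validate(self) -> None:
        if self.base_sigma < 0:
            raise ConfigError("base_sigma must be nonnegative")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be positive")

    def null(self) -> "EffectConfig":
        """Exchangeable-groups version (no group or covariate effect)."""
        return replace(
            self,
            group_sigma_delta={g: 0.0 for g in GROUPS},
            antibiotic_sigma_per_day=0.0,
        )


def generate_truth_profiles(
    cohort: Sequence[CohortRecord],
    n_mgs: int,
    effects: EffectConfig | None = None,
    seed: int = 0,
) -> list[GroundTruthProfile]:
    """Draw one true relative-abundance profile per cohort sample."""
    eff = effects or EffectConfig()
    eff.validate()
    if n_mgs < 1:
        raise ConfigError("n_mgs must be positive")
    rng = np.random.default_rng(seed)
    profiles = []
    for rec in cohort:
        sigma = (
            eff.base_sigma
            + eff.group_sigma_delta[rec.group]
            + eff.antibiotic_sigma_per_day * rec.antibiotic_days
        )
        w = np.exp(sigma * rng.standard_normal(n_mgs))
        w /= w.sum()
        if n_mgs == 1:
            p = np.ones(1)
        else:
            p = rng.dirichlet(eff.dirichlet_concentration * w)
            # guard against exact zeros from extreme alpha; renormalize
            p = np.clip(p, 0.0, None)
            p /= p.sum()
        profiles.append(GroundTruthProfile(rec.sample_id, p, float(sigma)))
    return profiles


def truth_frame(profiles: Sequence[GroundTruthProfile], mgs_ids: Sequence[str]) -> pd.DataFrame:
    """Truth profiles as a samples x MGS DataFrame of fractions."""
    return pd.DataFrame(
        [p.abundances for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=list(mgs_ids),
    )


# ---------------------------------------------------------------------------
# read / alignment-record simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseConfig:
    """Fractions of mates violating each mapping threshold, and host rate."""

    host_fraction: float = 0.02
    multi_frac: float = 0.08  # MAPQ below 20
    low_identity_frac: float = 0.04  # identity below 95%
    overhang_frac: float = 0.04  # > 10 unaligned bases

    def validate(self) -> None:
        for v in (self.host_fraction, self.multi_frac, self.low_identity_frac, self.overhang_frac):
            if not 0 <= v <= 1:
                raise ConfigError("noise fractions must be in [0, 1]")
        if self.multi_frac + self.low_identity_frac + self.overhang_frac > 1:
            raise ConfigError("violation fractions must sum to at most 1")


ALIGNMENT_COLUMNS = (
    "sample_id",
    "read_id",
    "mate",
    "gene_id",
    "mapq",
    "percent_identity",
    "aligned_length",
    "unaligned_bases",
    "host",
)


def simulate_sample_reads(
    profile: GroundTruthProfile,
    catalog: pd.DataFrame,
    depth: int,
    noise: NoiseConfig | None = None,
    read_length: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one sample's paired-end alignment evidence.

    Returns a table with two rows (mates) per read pair. Non-host pairs pick
    a catalog gene with probability proportional to the truth abundance of
    the gene's MGS times the gene length; both mates carry the same gene.
    Configurable fractions of mates violate the MAPQ, identity and overhang
    thresholds so the downstream classifier is exercised. MAPQ and identity
    are nominal draws, not recomputed from sequences.
    """
    noise = noise or NoiseConfig()
    noise.validate()
    if depth < 0:
        raise ConfigError("depth must be nonnegative")
    rng = np.random.default_rng(seed)
    if depth == 0:
        return pd.DataFrame(columns=list(ALIGNMENT_COLUMNS))

    mgs_ids = catalog["mgs_id"].to_numpy()
    uniq_mgs, mgs_codes = np.unique(mgs_ids, return_inverse=True)
    if len(uniq_mgs) != len(profile.abundances):
        raise ConfigError("catalog MGS count does not match profile length")
    lengths = catalog["length"].to_numpy(dtype=float)
    w = profile.abundances[mgs_codes] * lengths
    w /= w.sum()

    host = rng.random(depth) < noise.host_fraction
    n_cat = int((~host).sum())
    gene_idx = rng.choice(len(lengths), size=n_cat, p=w)

    gene_col = np.full(depth, -1, dtype=np.int64)
    gene_col[~host] = gene_idx

    rows = []
    for mate in (1, 2):
        u = rng.random(depth)
        is_multi = u < noise.multi_frac
        is_lowid = (u >= noise.multi_frac) & (u < noise.multi_frac + noise.low_identity_frac)
        is_over = (u >= noise.multi_frac + noise.low_identity_frac) & (
            u < noise.multi_frac + noise.low_identity_frac + noise.overhang_frac
        )
        mapq = np.where(is_multi, rng.integers(0, 20, depth), rng.integers(20, 61, depth))
        identity = np.where(
            is_lowid, rng.uniform(85.0, 94.5, depth), rng.uniform(96.0, 100.0, depth)
        )
        unaligned = np.where(
            is_over, rng.integers(11, 41, depth), rng.integers(0, 11, depth)
        )
        aligned = read_length - unaligned
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": profile.sample_id,
                    "read_id": np.arange(depth),
                    "mate": np.int8(mate),
                    "gene_id": gene_col,
                    "mapq": mapq.astype(np.int16),
                    "percent_identity": identity.astype(np.float32),
                    "aligned_length": aligned.astype(np.int16),
                    "unaligned_bases": unaligned.astype(np.int16),
                    "host": host,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    gene_names = catalog.index.to_numpy()
    mapped = out["gene_id"].to_numpy() >= 0
    gene_series = pd.Series(pd.NA, index=out.index, dtype="object")
    gene_series[mapped] = gene_names[out.loc[mapped, "gene_id"].to_numpy()]
    out["gene_id"] = gene_series
    return out


# ---------------------------------------------------------------------------
# FASTQ emission (exercised by the read-QC module only)
# ---------------------------------------------------------------------------


def simulate_fastq_pairs(
    n_pairs: int,
    read_length: int = 150,
    host_fraction: float = 0.02,
    lowq_tail_frac: float = 0.2,
    lowq_tail_len: int = 60,
    seed: int = 0,
):
    """Random read pairs with Phred qualities for the QC filters.

    A ``lowq_tail_frac`` fraction of reads carries a Q2 3' tail of
    ``lowq_tail_len`` bases (emulating degraded cycle quality); host decoys
    are flagged, not drawn from a real genome. Returns a list of
    ``((seq1, quals1, host1), (seq2, quals2, host2))`` tuples.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pairs = []
    for _ in range(n_pairs):
        mates = []
        pair_host = rng.random() < host_fraction
        for _mate in (1, 2):
            seq = "".join(rng.choice(bases, size=read_length))
            quals = rng.integers(30, 41, size=read_length)
            if rng.random() < lowq_tail_frac:
                quals[-lowq_tail_len:] = 2
            host = bool(pair_host and rng.random() < 0.8)
            mates.append((seq, tuple(int(q) for q in quals), host))
        if pair_host and not (mates[0][2] or mates[1][2]):
            mates[0] = (mates[0][0], mates[0][1], True)
        pairs.append((mates[0], mates[1]))
    return pairs
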