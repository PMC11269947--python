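"""End-to-end orchestration: simulate, profile, analyze, report.

``run_all`` drives the whole pipeline on synthetic data and writes a
reproducible report bundle: cohort CSV, gene/MGS/taxon abundance TSVs,
diversity tables, per-taxon test tables with significance tiers,
Lorenz / PCA / Bray-Curtis plot data, mined rule tables, a cohort summary
in the median (min; max) / n (%) style, and a machine-readable manifest
with seeds and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortsim, diversity, groupstats, mgs_profile, rulemine, taxonomy_annot
from .catalog_mapping import MappingThresholds, build_gene_count_table
from .cohortsim import CatalogConfig, CohortConfig, EffectConfig, NoiseConfig
from .exceptions import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; serializable so a run is reproducible."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    depth_pairs: int = 500_000
    rarefaction_depth: int = 100_000
    min_genes: int = mgs_profile.DEFAULT_MIN_GENES
    thresholds: MappingThresholds = field(default_factory=MappingThresholds)
    shannon_bins: int = 4
    antibiotic_bins: int = 3
    min_support: float = 0.0
    min_confidence: float = 50.0
    top_taxa: int = 12

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=raw.get("seed", 0),
            cohort=CohortConfig(**raw.get("cohort", {})),
            catalog=CatalogConfig(**raw.get("catalog", {})),
            effects=EffectConfig(**raw.get("effects", {})),
            noise=NoiseConfig(**raw.get("noise", {})),
            **{
                k: raw[k]
                for k in (
                    "depth_pairs", "rarefaction_depth", "min_genes", "shannon_bins",
                    "antibiotic_bins", "min_support", "min_confidence", "top_taxa",
                )
                if k in raw
            },
        )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_inputs(config: RunConfig) -> dict:
    """Generate cohort, catalog, truth profiles and per-sample gene counts."""
    seeds = _spawn_seeds(config.seed, 4)
    cohort = cohortsim.generate_cohort(config.cohort, seed=seeds[0])
    catalog, mgs_defs, hits = cohortsim.generate_catalog(config.catalog, seed=seeds[1])
    profiles = cohortsim.generate_truth_profiles(
        cohort, config.catalog.n_mgs, config.effects, seed=seeds[2]
    )
    sample_seeds = _spawn_seeds(seeds[3], len(profiles))
    tables = []
    summaries = []
    for prof, s in zip(profiles, sample_seeds):
        records = cohortsim.simulate_sample_reads(
            prof, catalog, config.depth_pairs, config.noise,
            read_length=config.catalog.read_length, seed=s,
        )
        counts, summary = build_gene_count_table(records, config.thresholds)
        tables.append(counts)
        summaries.append(summary)
    gene_counts = pd.concat(tables, axis=1).fillna(0).astype(int) if tables else pd.DataFrame()
    mapping_summary = pd.concat(summaries) if summaries else pd.DataFrame()
    return {
        "cohort": cohort,
        "cohort_frame": cohortsim.cohort_frame(cohort),
        "catalog": catalog,
        "mgs_defs": mgs_defs,
        "hits": hits,
        "profiles": profiles,
        "truth": cohortsim.truth_frame(profiles, [d.mgs_id for d in mgs_defs]),
        "gene_counts": gene_counts,
        "mapping_summary": mapping_summary,
    }


def analyze(config: RunConfig, inputs: dict) -> dict:
    """Profiling, annotation, diversity, statistics and rule mining."""
    seeds = _spawn_seeds(config.seed + 1, 2)
    profile = mgs_profile.profile_pipeline(
        inputs["gene_counts"], inputs["catalog"], inputs["mgs_defs"],
        min_genes=config.min_genes, rarefaction_depth=config.rarefaction_depth,
        seed=seeds[0],
    )
    lineages = taxonomy_annot.annotate_all(inputs["mgs_defs"], inputs["hits"])
    lineage_map = {
        mgs: {r: (None if pd.isna(v) else v) for r, v in row.items() if r in cohortsim.RANKS}
        for mgs, row in lineages.iterrows()
    }
    rel = profile["rarefied_relative"] if "rarefied_relative" in profile else profile["relative"]

    by_rank = {
        rank: mgs_profile.aggregate_by_rank(rel, lineage_map, rank)
        for rank in ("species", "genus", "phylum")
    }
    alpha = diversity.alpha_diversity(rel.data)
    bc = diversity.bray_curtis(rel.data)
    scores, evr = diversity.pca_scores(rel.data)

    cohort_df = inputs["cohort_frame"].loc[alpha.index]
    groups = cohort_df["group"]
    kw_tables: dict[str, pd.DataFrame] = {}
    mwu_tables: dict[str, pd.DataFrame] = {}
    alpha_tests: dict[str, dict] = {}
    if groups.nunique() > 1:
        present = [g for g in cohortsim.GROUPS if (groups == g).any()]
        for rank, mat in by_rank.items():
            kw_tables[rank] = groupstats.taxon_screen(mat, groups, test="kruskal")
        nec = groups.map(lambda g: "control" if g == "control" else "nec")
        mwu_tables = {
            rank: groupstats.taxon_screen(mat, nec, test="mannwhitney")
            for rank, mat in by_rank.items()
        }
        for index_name in ("shannon", "simpson_dominance", "berger_parker", "richness"):
            vals = [alpha.loc[groups == g, index_name] for g in present]
            h, p = groupstats.kruskal_wallis(vals)
            alpha_tests[index_name] = {"H": h, "p": p}
    else:
        logger.warning("single-group cohort: group-comparison statistics skipped")

    rule_table = cohort_df[["group"]].copy()
    shannon_labels, shannon_bins = rulemine.bin_series(alpha["shannon"], config.shannon_bins)
    ab_labels, _ = rulemine.bin_series(cohort_df["antibiotic_days"], config.antibiotic_bins)
    rule_table["shannon"] = shannon_labels
    rule_table["antibiotic_days"] = ab_labels
    rules = rulemine.mine_rules(
        rule_table, ["group", "antibiotic_days"], "shannon",
        min_support=config.min_support, min_confidence=config.min_confidence,
    )

    return {
        "profile": profile,
        "lineages": lineages,
        "relative": rel,
        "by_rank": by_rank,
        "alpha": alpha,
        "alpha_tests": alpha_tests,
        "bray_curtis": bc,
        "pca_scores": scores,
        "pca_explained": evr,
        "kw_tables": kw_tables,
        "mwu_tables": mwu_tables,
        "rules": rules,
        "shannon_bins": shannon_bins,
    }


def top_taxa_table(rank_matrix: pd.DataFrame, n_top: int = 12) -> pd.DataFrame:
    """Top-n taxa by mean abundance, remainder pooled into 'others'.

    Rows keep summing to the original per-sample total.
    """
    means = rank_matrix.mean(axis=0).sort_values(ascending=False)
    top = list(means.index[:n_top])
    out = rank_matrix[top].copy()
    rest = [c for c in rank_matrix.columns if c not in top]
    if rest:
        out["others"] = rank_matrix[rest].sum(axis=1)
    return out


def table1_summary(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Per-group cohort summary: median (min; max) and n (%) with p-values.

    Continuous fields get Mann-Whitney p (each NEC subgroup vs control),
    binary fields get Fisher exact p on the 2x2 counts.
    """
    groups = cohortsim.GROUPS
    continuous = ["antibiotic_days", "pn_days", "age_at_sample"]
    binary = ["sex_female", "cesarean", "abdominal_surgery"]
    rows = []
    ctrl = cohort_df[cohort_df["group"] == "control"]
    for var in continuous:
        row = {"variable": var, "type": "continuous"}
        for g in groups:
            v = cohort_df.loc[cohort_df["group"] == g, var]
            row[g] = f"{v.median():g} ({v.min():g}; {v.max():g})"
        for g in groups[1:]:
            v = cohort_df.loc[cohort_df["group"] == g, var]
            if len(v) and len(ctrl):
                _, p = groupstats.mann_whitney(v, ctrl[var])
                row[f"p_{g}_vs_control"] = round(p, 3)
        rows.append(row)
    for var in binary:
        row = {"variable": var, "type": "categorical"}
        for g in groups:
            v = cohort_df.loc[cohort_df["group"] == g, var]
            row[g] = f"{int(v.sum())} ({100 * v.mean():.0f}%)"
        for g in groups[1:]:
            v = cohort_df.loc[cohort_df["group"] == g, var]
            if len(v) == 0 or len(ctrl) == 0:
                continue
            a, b = int(v.sum()), int((1 - v).sum())
            c, d = int(ctrl[var].sum()), int((1 - ctrl[var]).sum())
            row[f"p_{g}_vs_control"] = round(groupstats.fisher_exact_2x2(a, b, c, d), 3)
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Run the full pipeline and write the report bundle under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        inputs = simulate_inputs(config)
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise ConfigError(f"[simulate] stage failed: {exc}") from exc

    n_nec = sum(1 for r in inputs["cohort"] if r.group != "control")
    try:
        results = analyze(config, inputs)
    except Exception as exc:
        raise ConfigError(f"[analyze] stage failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    inputs["cohort_frame"].to_csv(out / "cohort.csv")
    inputs["catalog"].to_csv(out / "gene_catalog.tsv", sep="\t")
    inputs["gene_counts"].to_csv(out / "gene_counts.tsv", sep="\t")
    inputs["mapping_summary"].to_csv(out / "mapping_summary.tsv", sep="\t")
    inputs["truth"].to_csv(out / "truth_profiles.tsv", sep="\t")
    results["lineages"].to_csv(out / "mgs_lineages.tsv", sep="\t")
    results["relative"].data.to_csv(out / "mgs_relative_abundance.tsv", sep="\t")
    for rank, mat in results["by_rank"].items():
        mat.to_csv(out / f"abundance_{rank}.tsv", sep="\t")
        top_taxa_table(mat, config.top_taxa).to_csv(out / f"top_taxa_{rank}.tsv", sep="\t")
    results["alpha"].to_csv(out / "alpha_diversity.tsv", sep="\t")
    results["bray_curtis"].to_csv(out / "bray_curtis.tsv", sep="\t")
    results["pca_scores"].to_csv(out / "pca_scores.tsv", sep="\t")

    if n_nec == 0:
        logger.warning("no NEC samples in cohort: group-comparison stages skipped")
    else:
        for rank, table in results["kw_tables"].items():
            table.to_csv(out / f"tests_kruskal_{rank}.tsv", sep="\t")
        for rank, table in results["mwu_tables"].items():
            table.to_csv(out / f"tests_mannwhitney_{rank}.tsv", sep="\t")
        pd.DataFrame(results["alpha_tests"]).T.to_csv(out / "alpha_diversity_tests.tsv", sep="\t")
    rulemine.rules_frame(results["rules"]).to_csv(out / "rules.tsv", sep="\t", index=False)
    table1_summary(inputs["cohort_frame"]).to_csv(out / "cohort_summary.tsv", sep="\t")

    lorenz = []
    for sample, row in results["relative"].data.iterrows():
        if row.sum() > 0:
            pts, gini = diversity.lorenz_gini(row.to_numpy())
            lorenz.append(
                pd.DataFrame({"sample_id": sample, "x": pts[:, 0], "y": pts[:, 1], "gini": gini})
            )
    pd.concat(lorenz, ignore_index=True).to_csv(out / "lorenz_curves.tsv", sep="\t", index=False)

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "n_samples": len(inputs["cohort"]),
        "n_nec": n_nec,
        "excluded_rarefaction": results["profile"]["excluded_samples"],
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"inputs": inputs, "results": results, "manifest": manifest}
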