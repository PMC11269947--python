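"""Rank-specific consensus annotation rules and their monotonicity."""

import numpy as np
import pandas as pd
import pytest

from mgskit import taxonomy_annot as ta
from mgskit.cohortsim import RANKS, MGSDefinition
from mgskit.exceptions import ConfigError


def hit(gene, taxon_by_rank, alen=120, cov=0.6, pid=96.0):
    row = {"gene_id": gene, "alignment_length": alen, "query_coverage": cov, "percent_identity": pid}
    row.update({r: None for r in RANKS})
    row.update(taxon_by_rank)
    return row


def mgs_with_genes(n):
    genes = tuple(f"g{i}" for i in range(n))
    return MGSDefinition("M1", genes, genes[: max(1, n // 3)], {})


class TestFilterHits:
    def test_species_thresholds(self):
        hits = pd.DataFrame([hit("g0", {"species": "X"}, alen=120, cov=0.6, pid=96.0)])
        assert len(ta.filter_hits(hits, "species")) == 1

    def test_low_coverage_dropped(self):
        hits = pd.DataFrame([hit("g0", {"species": "X"}, cov=0.4)])
        assert ta.filter_hits(hits, "species").empty

    def test_short_alignment_dropped(self):
        hits = pd.DataFrame([hit("g0", {"species": "X"}, alen=99)])
        assert ta.filter_hits(hits, "species").empty

    def test_identity_rank_dependent(self):
        """90% identity fails the species PID (95) but passes genus (85)."""
        hits = pd.DataFrame([hit("g0", {"species": "X", "genus": "G"}, pid=90.0)])
        assert ta.filter_hits(hits, "species").empty
        assert len(ta.filter_hits(hits, "genus")) == 1

    def test_unknown_rank_rejected(self):
        with pytest.raises(ConfigError):
            ta.filter_hits(pd.DataFrame([hit("g0", {})]), "strain")


class TestAnnotateRank:
    def test_species_assignment_with_minor_disagreement(self):
        """80/100 genes to X, 5 to Y passes species (M=75, D=10)."""
        mgs = mgs_with_genes(100)
        rows = [hit(f"g{i}", {"species": "X"}) for i in range(80)]
        rows += [hit(f"g{i}", {"species": "Y"}) for i in range(80, 85)]
        hits = ta.filter_hits(pd.DataFrame(rows), "species")
        assert ta.annotate_rank(mgs, hits, "species") == "X"

    def test_insufficient_support_returns_none(self):
        mgs = mgs_with_genes(100)
        rows = [hit(f"g{i}", {"species": "X"}) for i in range(70)]
        hits = ta.filter_hits(pd.DataFrame(rows), "species")
        assert ta.annotate_rank(mgs, hits, "species") is None

    def test_genus_assignment(self):
        """65 genes to X, 8 elsewhere passes genus (M=60, D=10)."""
        mgs = mgs_with_genes(100)
        rows = [hit(f"g{i}", {"genus": "X"}, pid=88.0) for i in range(65)]
        rows += [hit(f"g{i}", {"genus": f"other{i}"}, pid=88.0) for i in range(65, 73)]
        hits = ta.filter_hits(pd.DataFrame(rows), "genus")
        assert ta.annotate_rank(mgs, hits, "genus") == "X"

    def test_excess_disagreement_blocks_assignment(self):
        mgs = mgs_with_genes(100)
        rows = [hit(f"g{i}", {"species": "X"}) for i in range(80)]
        rows += [hit(f"g{i}", {"species": "Y"}) for i in range(80, 95)]  # 15% > D=10
        hits = ta.filter_hits(pd.DataFrame(rows), "species")
        assert ta.annotate_rank(mgs, hits, "species") is None

    def test_best_hit_resolution_prefers_identity_then_length(self):
        mgs = mgs_with_genes(1)
        rows = [
            hit("g0", {"species": "LOW"}, pid=96.0, alen=400),
            hit("g0", {"species": "HIGH"}, pid=99.0, alen=120),
        ]
        hits = ta.filter_hits(pd.DataFrame(rows), "species")
        assert ta.annotate_rank(mgs, hits, "species") == "HIGH"


class TestAnnotateMgs:
    def test_clean_species_support_gives_full_lineage(self):
        mgs = mgs_with_genes(10)
        lineage = {"species": "S", "genus": "G", "family": "F", "order": "O",
                   "class": "C", "phylum": "P", "superkingdom": "Bacteria"}
        rows = [hit(f"g{i}", lineage, pid=98.0) for i in range(9)]
        out = ta.annotate_mgs(mgs, pd.DataFrame(rows))
        assert out["species"] == "S" and out["genus"] == "G" and out["phylum"] == "P"
        assert ta.most_specific_rank(out) == "species"

    def test_split_genus_can_still_pass_family(self):
        mgs = mgs_with_genes(100)
        rows = [hit(f"g{i}", {"genus": "G1", "family": "F"}, pid=90.0) for i in range(45)]
        rows += [hit(f"g{i}", {"genus": "G2", "family": "F"}, pid=90.0) for i in range(45, 90)]
        out = ta.annotate_mgs(mgs, pd.DataFrame(rows))
        assert out["genus"] is None
        assert out["family"] == "F"

    def test_empty_hit_table_all_none(self):
        mgs = mgs_with_genes(5)
        out = ta.annotate_mgs(mgs, pd.DataFrame(columns=["gene_id", "alignment_length",
                                                         "query_coverage", "percent_identity", *RANKS]))
        assert all(v is None for v in out.values())


class TestOracleAndMonotonicity:
    def naive_annotate(self, mgs, hits_df, rank, params):
        """Independent per-rank recount: filter, best hit per gene, M/D check."""
        p = params or ta.RankParams()
        elig = hits_df[
            (hits_df["alignment_length"] >= 100)
            & (hits_df["query_coverage"] >= 0.5)
            & (hits_df["percent_identity"] >= p.pid[rank])
        ].dropna(subset=[rank])
        elig = elig[elig["gene_id"].isin(mgs.gene_ids)]
        best = {}
        for _, row in elig.iterrows():
            key = row["gene_id"]
            cand = (row["percent_identity"], row["alignment_length"], row[rank])
            if key not in best or (-cand[0], -cand[1], cand[2]) < (-best[key][0], -best[key][1], best[key][2]):
                best[key] = cand
        counts = {}
        for _, (_, _, taxon) in best.items():
            counts[taxon] = counts.get(taxon, 0) + 1
        n = len(mgs.gene_ids)
        winners = sorted(counts, key=lambda t: (-counts[t], t))
        for t in winners:
            if counts[t] / n >= p.m[rank] / 100 and (sum(counts.values()) - counts[t]) / n <= p.d[rank] / 100:
                return t
        return None

    def random_hits(self, seed, n_genes=30):
        rng = np.random.default_rng(seed)
        taxa = ["T1", "T2", "T3"]
        rows = []
        for i in range(n_genes):
            for _ in range(rng.integers(0, 3)):
                rows.append(
                    hit(
                        f"g{i}",
                        {"species": str(rng.choice(taxa)), "genus": str(rng.choice(taxa))},
                        alen=int(rng.integers(80, 300)),
                        cov=float(rng.uniform(0.3, 1.0)),
                        pid=float(rng.uniform(80, 100)),
                    )
                )
        return pd.DataFrame(rows, columns=["gene_id", "alignment_length", "query_coverage",
                                           "percent_identity", *RANKS])

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("rank", ["species", "genus"])
    def test_matches_naive_recount(self, seed, rank):
        mgs = mgs_with_genes(30)
        hits_df = self.random_hits(seed)
        eligible = ta.filter_hits(hits_df, rank)
        got = ta.annotate_rank(mgs, eligible, rank)
        assert got == self.naive_annotate(mgs, hits_df, rank, None)

    @pytest.mark.parametrize("seed", range(8))
    def test_loosening_thresholds_never_unassigns(self, seed):
        """Lower PID/M or higher D keep any previously assigned taxon assignable."""
        mgs = mgs_with_genes(30)
        hits_df = self.random_hits(seed + 50)
        strict = ta.RankParams()
        loose = ta.RankParams(
            pid={r: v - 10 for r, v in strict.pid.items()},
            m={r: max(0, v - 20) for r, v in strict.m.items()},
            d={r: min(100, v + 20) for r, v in strict.d.items()},
        )
        for rank in ("species", "genus"):
            before = ta.annotate_rank(mgs, ta.filter_hits(hits_df, rank, strict), rank, strict)
            after = ta.annotate_rank(mgs, ta.filter_hits(hits_df, rank, loose), rank, loose)
            if before is not None:
                assert after is not None


class TestAnnotateAll:
    def test_synthetic_catalog_species_fraction(self, toy_catalog):
        """MGSs built with clean species hits annotate at species; coarse ones at genus."""
        _, _, defs, hits = toy_catalog
        out = ta.annotate_all(defs, hits)
        assert set(out["best_rank"].dropna()) <= {"species", "genus", "family"}
        n_species = (out["best_rank"] == "species").sum()
        assert 1 <= n_species <= len(defs)
        # species-annotated MGSs recover their true lineage
        for d in defs:
            got = out.loc[d.mgs_id, "species"]
            if got is not None and not pd.isna(got):
                assert got == d.lineage["species"]
                assert out.loc[d.mgs_id, "genus"] == d.lineage["genus"]
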