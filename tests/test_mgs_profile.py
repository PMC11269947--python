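"""Signature-gene counting, detection filtering, rarefaction, normalization."""

import numpy as np
import pandas as pd
import pytest

from mgskit import mgs_profile as mp
from mgskit.cohortsim import MGSDefinition
from mgskit.exceptions import ConfigError, InputError


def make_defs():
    """Two MGSs: 8 member genes each, 5-gene signatures."""
    defs = []
    for k in ("A", "B"):
        genes = tuple(f"{k}{i}" for i in range(8))
        defs.append(MGSDefinition(f"MGS_{k}", genes, genes[:5], {"species": f"sp{k}"}))
    return defs


def gene_counts_frame(counts: dict, samples=("s1",)):
    idx = [f"{k}{i}" for k in ("A", "B") for i in range(8)]
    df = pd.DataFrame(0, index=pd.Index(idx, name="gene_id"), columns=list(samples))
    for (gene, sample), v in counts.items():
        df.loc[gene, sample] = v
    return df


class TestCountSignatureReads:
    def test_counts_sum_over_signature_genes_only(self):
        defs = make_defs()
        gc = gene_counts_frame({("A0", "s1"): 10, ("A1", "s1"): 10, ("A2", "s1"): 10,
                                ("A3", "s1"): 5, ("A4", "s1"): 5, ("A5", "s1"): 99})
        counts, detected = mp.count_signature_reads(gc, defs)
        assert counts.loc["s1", "MGS_A"] == 40  # A5 is a member but not signature
        assert detected.loc["s1", "MGS_A"] == 5

    def test_nonsignature_member_counts_give_zero(self):
        defs = make_defs()
        gc = gene_counts_frame({("A6", "s1"): 50, ("A7", "s1"): 50})
        counts, detected = mp.count_signature_reads(gc, defs)
        assert counts.loc["s1", "MGS_A"] == 0
        assert detected.loc["s1", "MGS_A"] == 0

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(1)
        defs = make_defs()
        idx = [f"{k}{i}" for k in ("A", "B") for i in range(8)]
        gc = pd.DataFrame(
            rng.integers(0, 20, size=(16, 3)),
            index=pd.Index(idx, name="gene_id"),
            columns=["s1", "s2", "s3"],
        )
        counts, detected = mp.count_signature_reads(gc, defs)
        for d in defs:
            for s in gc.columns:
                sig = [g for g in d.signature_gene_ids]
                assert counts.loc[s, d.mgs_id] == gc.loc[sig, s].sum()
                assert detected.loc[s, d.mgs_id] == (gc.loc[sig, s] > 0).sum()


class TestDetectionFilter:
    @pytest.mark.parametrize("n_genes,expected", [(2, 0), (3, 40), (4, 40)])
    def test_min_three_signature_genes(self, n_genes, expected):
        counts = pd.DataFrame({"MGS_A": [40]}, index=["s1"])
        detected = pd.DataFrame({"MGS_A": [n_genes]}, index=["s1"])
        out = mp.apply_detection_filter(counts, detected)
        assert out.loc["s1", "MGS_A"] == expected

    def test_min_genes_one_is_identity_when_supported(self):
        counts = pd.DataFrame({"MGS_A": [7], "MGS_B": [0]}, index=["s1"])
        detected = pd.DataFrame({"MGS_A": [1], "MGS_B": [0]}, index=["s1"])
        out = mp.apply_detection_filter(counts, detected, min_genes=1)
        pd.testing.assert_frame_equal(out, counts)

    def test_misaligned_matrices_rejected(self):
        with pytest.raises(InputError):
            mp.apply_detection_filter(
                pd.DataFrame({"A": [1]}), pd.DataFrame({"A": [1], "B": [2]})
            )


class TestRarefaction:
    def test_depth_equals_total_is_identity(self):
        gc = gene_counts_frame({("A0", "s1"): 30, ("B0", "s1"): 70})
        sig, _ = mp.signature_gene_counts(gc, make_defs())
        out, excluded = mp.rarefy_signature_counts(sig, depth=100, seed=0)
        pd.testing.assert_series_equal(out["s1"], sig["s1"])
        assert excluded == []

    def test_totals_exactly_depth(self):
        rng = np.random.default_rng(2)
        sig = pd.DataFrame(rng.integers(0, 200, size=(10, 4)), columns=list("abcd"))
        out, _ = mp.rarefy_signature_counts(sig, depth=100, seed=1)
        assert (out.sum(axis=0) == 100).all()

    def test_shallow_sample_flagged_and_excluded(self):
        sig = pd.DataFrame({"deep": [500, 500], "shallow": [10, 5]})
        out, excluded = mp.rarefy_signature_counts(sig, depth=100, seed=2)
        assert excluded == ["shallow"]
        assert list(out.columns) == ["deep"]

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ConfigError):
            mp.rarefy_signature_counts(pd.DataFrame({"a": [10]}), depth=0)

    def test_hypergeometric_expectation(self):
        """Sampling 10% of 1000 counts keeps ~10% of each gene's count."""
        col = np.array([500, 300, 150, 50])
        sig = pd.DataFrame({"s": col})
        sums = np.zeros(4)
        n_seeds = 200
        for seed in range(n_seeds):
            out, _ = mp.rarefy_signature_counts(sig, depth=100, seed=seed)
            sums += out["s"].to_numpy()
        mean = sums / n_seeds
        # Monte-Carlo tolerance: ~4 x SE of the hypergeometric mean
        se = np.sqrt(col * 0.1 * 0.9 / n_seeds)
        assert np.all(np.abs(mean - col * 0.1) < 4 * se + 0.5)

    def test_rarefied_richness_not_above_unrarefied(self):
        rng = np.random.default_rng(3)
        sig = pd.DataFrame(rng.integers(0, 50, size=(30, 5)))
        out, _ = mp.rarefy_signature_counts(sig, depth=200, seed=4)
        for c in out.columns:
            assert (out[c] > 0).sum() <= (sig[c] > 0).sum()


class TestNormalizeRelative:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"A": [10], "B": [10]}, index=["s1"])
        rel = mp.normalize_relative(counts, {"A": 150.0, "B": 150.0})
        assert rel.data.loc["s1", "A"] == pytest.approx(50.0)
        assert rel.state == "relative"

    def test_length_normalization_arithmetic(self):
        """counts (10, 10) with effective lengths (100, 200) -> 66.67% / 33.33%."""
        counts = pd.DataFrame({"A": [10], "B": [10]}, index=["s1"])
        rel = mp.normalize_relative(counts, {"A": 100.0, "B": 200.0})
        assert rel.data.loc["s1", "A"] == pytest.approx(200 / 3, abs=1e-9)
        assert rel.data.loc["s1", "B"] == pytest.approx(100 / 3, abs=1e-9)

    def test_single_detected_mgs_is_100(self):
        counts = pd.DataFrame({"A": [5], "B": [0]}, index=["s1"])
        rel = mp.normalize_relative(counts, {"A": 100.0, "B": 100.0})
        assert rel.data.loc["s1", "A"] == pytest.approx(100.0)

    def test_all_zero_row_stays_zero(self):
        counts = pd.DataFrame({"A": [0], "B": [0]}, index=["s1"])
        rel = mp.normalize_relative(counts, {"A": 100.0, "B": 100.0})
        assert rel.data.loc["s1"].sum() == 0.0

    def test_zero_effective_length_rejected(self):
        counts = pd.DataFrame({"A": [1]}, index=["s1"])
        with pytest.raises(ConfigError):
            mp.normalize_relative(counts, {"A": 0.0})


class TestAggregateByRank:
    LIN = {
        "M1": {"phylum": "P1", "species": None},
        "M2": {"phylum": "P1", "species": None},
        "M3": {"phylum": "P1", "species": None},
        "M4": {"phylum": "P2", "species": None},
    }

    def test_phylum_additivity(self):
        rel = pd.DataFrame({"M1": [20.0], "M2": [20.0], "M3": [20.0], "M4": [40.0]}, index=["s1"])
        out = mp.aggregate_by_rank(rel, self.LIN, "phylum")
        assert out.loc["s1", "P1"] == pytest.approx(60.0)

    def test_unannotated_pooled_into_unclassified(self):
        rel = pd.DataFrame({"M1": [60.0], "M4": [40.0]}, index=["s1"])
        out = mp.aggregate_by_rank(rel, self.LIN, "species")
        assert list(out.columns) == ["unclassified"]
        assert out.loc["s1", "unclassified"] == pytest.approx(100.0)

    def test_row_sums_preserved_random_table(self):
        rng = np.random.default_rng(5)
        rel = pd.DataFrame(
            rng.uniform(0, 10, size=(6, 4)), columns=["M1", "M2", "M3", "M4"]
        )
        out = mp.aggregate_by_rank(rel, self.LIN, "phylum")
        np.testing.assert_allclose(out.sum(axis=1), rel.sum(axis=1), atol=1e-9)
        # brute-force group sum
        assert np.allclose(out["P1"], rel[["M1", "M2", "M3"]].sum(axis=1))

    def test_unknown_rank_rejected(self):
        with pytest.raises(ConfigError):
            mp.aggregate_by_rank(pd.DataFrame({"M1": [1.0]}), self.LIN, "kingdomish")


class TestProfilePipeline:
    def test_end_to_end_consistency(self, toy_catalog, toy_gene_counts):
        _, catalog, defs, _ = toy_catalog
        _, gene_counts = toy_gene_counts
        res = mp.profile_pipeline(gene_counts, catalog, defs, rarefaction_depth=2000, seed=0)
        rel = res["rarefied_relative"].data
        totals = rel.sum(axis=1)
        assert np.allclose(totals[totals > 0], 100.0)
        assert (res["rarefied_counts"].data.sum(axis=1) <= res["mgs_counts"].data.sum(axis=1)).all()

    def test_detection_specificity_high_under_background(self):
        spec = mp.detection_specificity_simulation(n_trials=500, seed=1)
        assert spec > 0.9
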