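import numpy as np
import pandas as pd
import pytest

from mgskit import cohortsim as cs


@pytest.fixture(scope="session")
def toy_catalog():
    """Small catalog: 8 MGSs x 60 genes, 20-gene signatures."""
    cfg = cs.CatalogConfig(n_mgs=8, genes_per_mgs=60, signature_size=20)
    catalog, defs, hits = cs.generate_catalog(cfg, seed=11)
    return cfg, catalog, defs, hits


@pytest.fixture(scope="session")
def toy_cohort():
    return cs.generate_cohort(cs.CohortConfig(n_control=6, n_medical=3, n_surgical=3), seed=7)


@pytest.fixture(scope="session")
def toy_gene_counts(toy_catalog, toy_cohort):
    """Gene count tables simulated end-to-end at modest depth."""
    from mgskit.catalog_mapping import build_gene_count_table

    _, catalog, defs, _ = toy_catalog
    profiles = cs.generate_truth_profiles(toy_cohort, 8, seed=5)
    tables = []
    for i, prof in enumerate(profiles):
        rec = cs.simulate_sample_reads(prof, catalog, 15000, seed=100 + i)
        counts, _ = build_gene_count_table(rec)
        tables.append(counts)
    gene_counts = pd.concat(tables, axis=1).fillna(0).astype(int)
    return profiles, gene_counts
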