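# mgskit

Quantification and analysis of gut metagenomes with the **metagenomic
species (MGS)** framework, built for studying long-term microbiome
consequences of necrotizing enterocolitis (NEC) in children born preterm.
The package implements the full analysis chain — high-quality non-host
(HQNH) read filtering, read-to-gene-catalog classification, signature-gene
abundance profiling with detection filtering and rarefaction,
rank-specific consensus taxonomy, alpha/beta diversity, nonparametric
group statistics, and association-rule prediction of alpha diversity from
clinical exposures — and exercises it end-to-end on a built-in synthetic
cohort generator with known ground truth (24 preterm controls, 7
medically and 8 surgically treated NEC children by default).

It is aimed at microbiome methodologists and pipeline developers who need
a transparent, fully testable reference implementation of MGS-style
profiling rules rather than a wrapper around external aligners.

## The model in brief

* **Mapping rules.** A read is *uniquely mapped* to a catalog gene if
  MAPQ ≥ 20, identity ≥ 95% over ≥ 100 bp, and at most 10 bases fail to
  align; identity/length-passing reads with MAPQ < 20 are *multi-mapped*.
  A pair counts toward one gene if either mate is unique (read 1 wins a
  tie), giving the gene count table G(g, s) of uniquely mapped pairs.
* **MGS abundance.** Each MGS *m* has a 100-gene signature set S(m);
  its count is C(m, s) = Σ_{g∈S(m)} G(g, s), zeroed unless reads hit ≥ 3
  distinct signature genes. Relative abundance is
  A(m, s) ∝ C(m, s) / L̄_eff(m), row-normalized to 100%, with
  L̄_eff(m) the mean effective signature-gene length
  (L_eff = max(1, L − r + 1), read length r = 150).
* **Rarefaction.** Gene-level signature counts are down-sampled without
  replacement (multivariate hypergeometric) to a fixed depth per sample
  before re-applying detection and normalization.
* **Taxonomy.** An MGS is assigned taxon T at a rank iff ≥ M% of its
  member genes resolve to T and ≤ D% to another taxon, over blast-like
  hits with alignment ≥ 100 bp, coverage ≥ 50% and identity ≥ a
  rank-specific PID; PID/M/D default to
  (95, 95, 85, 75, 65, 55, 50, 45) / (75, 75, 60, 50, 40, 30, 25, 20) /
  (10, 10, 10, 20, 20, 20, 20, 15) from subspecies to superkingdom.
* **Diversity.** Shannon H = −Σ p ln p, Simpson concentration
  λ = Σ p² (dominance form), richness, Berger-Parker max p, Lorenz/Gini,
  Bray-Curtis, rarefaction curves and PCA scores.
* **Statistics.** Fisher exact (two-sided, point-probability),
  Mann-Whitney U, Kruskal-Wallis, Spearman, Hedges' g with small-sample
  correction, Bonferroni adjustment, and per-taxon screens with
  */**/*** significance tiers.
* **Rule mining.** Equal-width interval discretization plus Apriori-style
  enumeration of conjunctive antecedents scored by support and confidence
  (plain relative frequencies in percent).

## Worked example

```bash
mgskit run-all --seed 7 --outdir demo --depth 50000 --rarefaction-depth 10000
```

writes a full report bundle (cohort CSV, gene/MGS/taxon abundance TSVs,
diversity and test tables, Lorenz/PCA/Bray-Curtis data, mined rules, and a
checksummed `manifest.json`). Inspecting it:

```python
>>> import pandas as pd
>>> alpha = pd.read_csv("demo/alpha_diversity.tsv", sep="\t", index_col=0)
>>> cohort = pd.read_csv("demo/cohort.csv", index_col=0)
>>> alpha.groupby(cohort["group"])[["shannon", "berger_parker"]].median().round(3)
              shannon  berger_parker
group
control         3.277          0.133
nec_medical     2.449          0.301
nec_surgical    1.848          0.386
>>> pd.read_csv("demo/alpha_diversity_tests.tsv", sep="\t", index_col=0).round(4)
                         H       p
shannon            21.5678  0.0000
simpson_dominance  18.8242  0.0001
berger_parker      15.1875  0.0005
richness           26.4212  0.0000
```

Surgically treated NEC children have the lowest median Shannon entropy
(1.848 vs 3.277 nats in controls) and the highest single-species
dominance (Berger-Parker 0.386 vs 0.133), significant by Kruskal-Wallis
across the three groups — the dysbiosis signature the simulator encodes
and the pipeline recovers.

```python
>>> pd.read_csv("demo/rules.tsv", sep="\t").head(3)[["antecedent", "consequent", "support_pct", "confidence_pct"]]
                                          antecedent            consequent  support_pct  confidence_pct
0   antibiotic_days=[52.3, 76] AND group=nec_medical  shannon=[2.01, 2.72)         2.56          100.00
1  antibiotic_days=[52.3, 76] AND group=nec_surgical   shannon=[1.3, 2.01)         2.56          100.00
2        antibiotic_days=[5, 28.7) AND group=control  shannon=[2.72, 3.42]        56.41           91.67
```

Each rule reads "samples whose antecedent variables fall in these
intervals land in this Shannon bin", with support the percentage of all
samples satisfying both sides and confidence the percentage of
antecedent samples that do — the interval-prediction form used to
forecast dysbiosis from antibiotic exposure.

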