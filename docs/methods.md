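# Methods

## Scope and data flow

`mgskit` quantifies a metagenome as relative abundances of *metagenomic
species* (MGS): clusters of catalog genes with coherent abundance behaviour,
each represented by a fixed signature gene set. The pipeline stages are

1. **readqc** — host-pair removal, adapter/quality trimming, HQNH length
   filter;
2. **catalog_mapping** — per-read and per-pair classification of alignment
   evidence into unique / multi-mapped / unmapped, and the uniquely mapped
   pair count table;
3. **mgs_profile** — signature-gene counting, the ≥ 3-gene detection
   filter, without-replacement rarefaction, effective-length and sample-wise
   normalization, and rank-level aggregation;
4. **taxonomy_annot** — rank-specific consensus annotation from blast-like
   hit tables;
5. **diversity / groupstats / rulemine** — the analysis layer;
6. **cohortsim / pipeline** — the synthetic data source and orchestration.

Every input is synthetic and produced by `cohortsim`, so ground truth is
known and recovery is testable.

## The synthetic cohort generator

The generator emulates a 39-child cohort (24 preterm controls, 7 medically
and 8 surgically treated NEC survivors, stool sampled around age 5).
Covariates are drawn per group: antibiotic and parenteral-nutrition days
are log-normal around configurable medians (defaults 10/28/36 and 9/28/49
days for control/medical/surgical), so the severity ordering holds
stochastically; binary fields use per-group rates consistent with the
cohort design being emulated.

**Community model.** Per sample, MGS weights are
`w_i = exp(sigma * z_i)`, `z_i ~ N(0, 1)`, and the profile is a Dirichlet
draw around the normalized weights with concentration 200. `sigma`
controls evenness: `sigma = 1.0 + delta_group + 0.015 * antibiotic_days`,
with `delta` 0 / 0.35 / 0.8 for control / medical / surgical. These
defaults were fixed once to place Shannon entropy roughly in the 1.2–3.3
nats range of a 5-year-old preterm gut community with the surgical group
visibly dominated, and to make antibiotic exposure negatively coupled to
diversity through a monotone link. The *drawn* Dirichlet profile is the
recorded ground truth, so recovery tests measure profiling and sampling
error only, not Dirichlet noise.

**Sequencing evidence.** Rather than writing reads and invoking an
aligner, the simulator emits per-mate alignment records directly: a
non-host pair picks a gene with probability ∝ truth abundance × gene
length (both mates on the same gene), and independent per-mate fractions
violate each mapping threshold (defaults: 2% host pairs, 8% MAPQ < 20, 4%
identity < 95%, 4% overhang > 10 bases). MAPQ and identity are nominal
draws, not recomputed from sequences. `aligned_length` is defined as read
length minus unaligned bases for internal coherence. FASTQ emission (with
`host=0/1` description flags and optional Q2 3' tails) exists solely to
exercise the read-QC stage.

**What the simulator does not emulate:** realistic error spectra,
real host genomes, multi-alignment resolution inside the aligner,
strain-level variation, compositional correlations between taxa, or batch
effects. Passing recovery tests therefore demonstrates correctness of the
quantification rules under the stated noise model, not performance on
real sequencing data.

## Profiling choices

* **Effective gene length** is `max(1, L − r + 1)` with nominal read
  length r = 150 — the count of valid read start positions. The MGS
  normalization denominator is the *mean* effective length over its
  signature set, keeping the signature-sum count model coherent.
  The simulator draws reads ∝ full gene length while the estimator divides
  by effective length; for genes ≫ r the per-MGS ratio distortion is a
  fraction of a percent and does not affect rank-based recovery.
* **Detection** requires uniquely mapped reads on ≥ 3 distinct signature
  genes; the filter is applied both at first profiling and again after
  rarefaction (the conservative reading). A small simulation
  (`detection_specificity_simulation`) shows the rule's specificity under
  Poisson background noise; it is illustrative, not a calibrated benchmark.
* **Rarefaction** operates on gene-level signature counts (the unit the
  depth is stated in), via `numpy`'s multivariate hypergeometric sampler;
  totals are exact by construction. Samples below the requested depth are
  excluded and flagged, never up-sampled. The library default depth is
  524 050 counts; the synthetic study-scale runs simulate 5×10⁵ read pairs
  per sample (≈ 1.5×10⁵ signature counts) and rarefy at 10⁵ — problem
  sizes chosen to keep a desk-scale run reproducible in about a minute.

## Taxonomy annotation choices

Ranks are evaluated independently with the PID/M/D arrays given in the
README. Points the rule statement leaves open, resolved here:

* a gene's taxon at a rank is that of its best eligible hit (identity,
  then alignment length, then lexicographic taxon);
* the M%/D% denominator is the full member gene set, not only genes with
  eligible hits (conservative);
* D% counts genes resolving to a *different taxon at the same rank*;
* candidate taxa are tried in order of gene support with lexicographic
  tie-break, and parent/child lineage conflicts are resolved in favour of
  the more specific rank with a logged notice.

An annotation-refinement hook (e.g. genome-completeness tools) is out of
scope; `annotate_all` output is the final lineage.

## Statistics

Fisher's exact test is two-sided by the point-probability method (the
convention of mainstream statistics packages), which reproduces the
published cohort-table p-values to printed precision and matches an
exhaustive enumeration oracle in tests. Mann-Whitney uses the exact null
for combined n ≤ 20 without ties, else the tie-corrected normal
approximation. Simpson is reported in the dominance form λ = Σp² (a
less diverse community shows a *higher* value, matching how the index is
used alongside Shannon here); `simpson_diversity = 1 − λ` is also
emitted. Shannon uses natural log by default with a configurable base.
The Bonferroni family is all taxa screened in one `taxon_screen` call;
tiers can be computed from raw or adjusted p (both are emitted, raw is
the default tier source).

Richness counts every MGS (or taxon column) with positive abundance as a
distinct unit, whether or not it carries a species-level name.

## Rule mining

Continuous variables are cut into equal-width bins over the observed
range (right-open, top bin closed); explicit edges are supported for
pre-registered intervals such as an antibiotic-days window of [36, 53).
Antecedents are conjunctions of up to two single-variable predicates by
default; support and confidence are plain relative frequencies in
percent, so on an n-sample cohort every support is an exact multiple of
100/n — a property the tests assert against brute-force counting. The
predictor applies the highest-confidence applicable rule, ties broken by
support.

## Numerical and degenerate-input conventions

* All randomness flows through `numpy.random.default_rng` seeds;
  per-sample seeds are spawned from a master `SeedSequence`, so runs are
  reproducible end-to-end and the pipeline manifest checksums its
  artifacts.
* All-zero samples are excluded (and flagged) from diversity; all-zero
  sample pairs give NaN Bray-Curtis entries; constant vectors give NaN
  Spearman/Hedges with a warning; empty 2×2 margins give p = 1 by
  convention.
* Relative abundance rows sum to 100% within 1e-9; aggregation at any
  rank preserves row sums exactly (grouped sums).
* A cohort may have zero NEC samples (the control group must be
  non-empty); group-comparison stages are then skipped with a logged
  reason rather than erroring.

## Known limitations

* MAPQ in the simulator is nominal; classifier behaviour under real
  aligner MAPQ distributions is untested.
* The trimming dialect (exact adapter prefix/suffix plus end-trimming
  while the terminal base is below Q30) is one of several plausible
  dialects of the cited tool class; internal low-quality bases survive.
* Effect-size defaults in the generator are calibration knobs of the
  synthetic study, not estimates of any real NEC effect.
* Hill-number extrapolation, heatmap rendering and real-data ingestion
  are out of scope; figures are emitted as plot-ready tables only.
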