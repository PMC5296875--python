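# Methods

This note documents the models, estimators and design choices behind
`haplerode`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the simulation-based tests do and do not
demonstrate about real data.

## Data model

A dataset joins four inputs: an aligned mtDNA FASTA, a per-sample metadata
TSV (`sample_id, era, collection_year, country, local_population,
modern_stock, lat, lon`), an optional diploid microsatellite CSV
(`locus_A1, locus_A2` pairs, `0` = missing) and an optional rooted Newick
haplotype tree with a leaf → haplogroup label map. Samples lacking both a
sequence and a genotype are rejected with a report. When the era is not
explicit it is derived from the collection year against a cutoff
(default **1990**): the study design contrasts a museum era (roughly
1850–1960) with post-decline sampling, and an explicit era column always
wins over the derivation. Sequences are stored uppercase with `U → T`.

## Haplotype collapsing

Museum sequences are fragmentary, so the default identity test
(`mask_pairwise`) ignores, per pair, any column holding a gap, `N` or an
IUPAC ambiguity code in either sequence; haplotype classes are the
transitive closure of this relation (union-find), because masked identity
is not transitive. The alternative `strict` policy requires byte
identity and will split otherwise-identical fragments — it inflates
haplotype counts on sparse historic data, which is why it is not the
default; both are available and the pipeline logs which was used.
Haplotype ids are `H001…` in order of first appearance, so numbering is
reproducible across runs. A sample without a `local_population` label
contributes to species-wide totals only, never to per-population sets —
mirroring how specimens of unknown origin are handled in range-wide
summaries.

Polymorphic sites count columns with ≥ 2 distinct unambiguous states.

## Diversity statistics

* **Haplotype diversity**: unbiased `h = n(1 − Σp²)/(n − 1)`. The
  unbiased form is required to reproduce the canonical worked examples
  (3:2 copies → 0.60; 2:1 → 0.67); the biased `1 − Σp²` form gives 0.48
  and 0.44 instead.
* **Nucleotide diversity** is reported in *mean pairwise difference*
  units (not per site), matching the magnitudes of published
  control-region tables; a per-site variant divides by the alignment
  length. Missing data are handled by pairwise deletion.
* **Heterozygosity**: per locus, `H_O` among individuals with complete
  calls and unbiased `H_E = (2N/(2N−1))(1 − Σp²)`; the multilocus value
  is the unweighted mean over loci with data.
* **Rarefied allelic richness**: `A_g = Σ_a [1 − C(N−N_a, g)/C(N, g)]`,
  the exact expectation of the allele count in a subsample of `g` gene
  copies. By default `g` is the smallest non-missing gene-copy count
  across the loci/groups being compared (the convention of rarefaction
  software); the value of `g` used is reported alongside every table.
  Published rarefied values whose `g` is unknown cannot be reproduced
  exactly, so the tables report `A_g` with its `g` rather than chasing a
  hidden standard.

Groups with fewer than 5 samples are emitted but flagged, following the
usual practice of interpreting only populations with n ≥ 5.

## Extinction categories and loss partitioning

For an extirpated population (no extant samples), tested in severity
order: **globally extinct** when none of its historic haplotypes occurs in
any extant sample anywhere; otherwise **genetically extinct** when at
least one of its *private* historic haplotypes (private among historic
local populations — the modern consolidation of stocks makes extant
privacy uninformative) is absent from every extant sample; otherwise
**locally extinct**. "Surviving" means observed in ≥ 1 extant sample —
presence, not abundance. A population with extant samples is **extant**
regardless of its losses (those appear as the `eroded` flag and the
SH < H tally instead).

Species-wide loss is decomposed with a first-match-wins rule in severity
order: a lost haplotype observed in any globally-extinct population counts
against global extinctions; otherwise, if private to a genetically-extinct
population, against genetic extinctions; the remainder is drift loss
within surviving populations. The rule guarantees the components always
sum to the total loss.

**Persistence tracing** maps every historic haplotype to the modern
stocks carrying it. A stock is an *extralimital* carrier when its samples'
country is outside the set of countries where the haplotype was
historically collected; the country is the range unit because historic
locality data are rarely finer. The population-level
`extralimital_introduction` flag marks populations that *received* such a
haplotype (some extant sample of theirs carries it in a flagged stock).
Note the definition is sharing-based: a haplotype historically sampled
only on one side of a recent range subdivision can be flagged without any
management action — interpret flags together with known translocation
records.

## Conservation units

* **Monophyly**: branches with support below `support_min` (default
  **0.95**; unannotated trees are taken at face value) are collapsed to
  polytomies, then a group is monophyletic iff its leaves form an
  exclusive clade. On a rooted tree an exclusive clade is exactly a
  bipartition of the leaves, so group and complement are mutually
  exclusive in the unrooted sense — this is the working definition of
  reciprocal monophyly here, and it is the one under which several
  haplogroups on a single tree can each be called monophyletic.
* **Frequency differentiation**: per locus, a Monte-Carlo exact
  contingency test on allele counts under the probability-ordering
  criterion (the r×c generalization of Fisher's exact test; `n_mc`
  default 2000, add-one rule so p is never 0), combined across loci by
  Fisher's method. This replaces assignment-based significance from a
  clustering run, which is not reproducible without re-running the
  clustering; the substitution is deliberate and documented.
* **Spatial exclusivity**: per-group ordinary kriging of membership
  probabilities (see below); a group's *range* is the set of grid cells,
  within the data's spatial support, where its surface reaches
  `range_threshold` (default **0.4**) times the group's surface peak.
  Two groups are mutually exclusive when the Jaccard overlap of their
  ranges is ≤ `overlap_max` (default **0.05**). The relative cut is used
  because an ordinary-kriging surface reverts to a mean far from data,
  so an absolute probability cut makes common groups' ranges unbounded;
  the 0.4/0.05 operating point was chosen once on simulated sympatric vs
  allopatric configurations and is exposed in the run config.
* **Decision rule**: monophyletic ∧ exclusive → ESU; monophyletic ∧
  overlapping → member of a higher-order ESU, the smallest supported
  clade containing the overlapping groups (smallest-cardinality superset;
  if none exists short of the root, a root-level unit is reported with a
  warning); non-monophyletic ∧ differentiated → MU (overlap does not
  revoke MU status); otherwise no unit. The rule is a pure function of
  the three assessments, so the eight boolean combinations enumerate its
  truth table, and collapsing is stable: re-assessing a collapsed parent
  as a spatially distinct monophyletic group yields a plain ESU.

## Kriging

Ordinary kriging per group with exponential covariance
`C(d) = sill·exp(−d/range) + nugget·1[d=0]`, distances in great-circle km
(continental extents make planar approximations poor). Parameters are
fitted by REML under a constant-mean model with multi-start (3 seeded
starts) Nelder–Mead on log-parameters, tolerance 1e−6, inside a box that
keeps them identifiable: sill and nugget in [1e−6, 4] (probability
surfaces), nugget floor 1e−4 when fitted, and range between 5 km and a
third of the data's maximum pairwise distance — an unbounded range is
unidentifiable from a bounded survey and produces numerically singular
systems. A relative ridge of 1e−8·sill stabilizes the solve; exactly
duplicated coordinates are jittered by 1e−4° with a warning. Predictions
are clamped to [0, 1]; groups are kriged independently and never
renormalized (each surface is that group's own occurrence probability,
not a partition). The default grid is 0.5° over the samples' bounding box
plus a 2° margin; cells farther than `support_km` (default 500 km) from
every sample are outside any mapped range.

## The simulator

The synthetic-data module generates the situation the analysis assumes:
demes with centroids and mtDNA effective sizes, a backward-time split
schedule, optional migration, and an event grammar of extirpations
(year), bottlenecks (year, severity = fraction of the original size,
lasting to the present) and translocations (extant-era samples drawn from
the source gene pool but labelled with the destination population,
country and stock — a 20th-century management action affects sampling,
not deep ancestry). Ancestry comes from the structured coalescent
(msprime) with serial, tip-dated sampling: collection years map to
generations via the **24-year generation time**, the mean of the first
(5.5 y) and last (42.5 y) ages of reproduction. Historic years are drawn
uniformly in 1850–1960 (truncated before a deme's extirpation), extant
years in 1990–2008.

mtDNA mutations fall as infinite sites (each mutation at a fresh column
of an L = 500-site alignment; rate 2e−3 per sequence per generation by
default, giving per-deme θ ≈ 1.6 at N_e = 400), so the number of distinct
haplotypes never exceeds mutations + 1. Microsatellites evolve on
independent diploid genealogies with all sizes scaled ×4 (autosomal vs
maternally inherited effective size) under a single-step stepwise
mutation model bounded to 5–50 repeat units (reflecting boundaries; rate
5e−4 per locus per generation). Everything is deterministic given the
seed, and the emitted ground truth (per-deme status, haplotype origins
and haplogroup labels, translocation records) is computed by independent
set logic over the realized samples, not by the pipeline being tested.

`scenario_rhino` packages a nine-deme configuration echoing a
continental-scale haplogroup structure: two deep isolated extirpated
demes (global extinctions), a recent offshoot extirpated with private
variants (genetic extinction), an offshoot sharing its entire gene pool
with its extant sister (local extinction), five extant demes including a
recently split, bottlenecked pair (MU truth) and an overlapping
monophyletic sister pair (higher-order ESU truth), plus one scripted
extralimital translocation. Sample sizes are 8 historic per deme and 30
extant per surviving deme — museum-scale versus modern-survey-scale.
Because several truth conditions are stochastic (lineage sorting, allele
sharing), the generator deterministically retries derived seeds until the
ground truth exhibits every scripted feature; roughly one seed in three
succeeds, so the retry loop is short and the returned fixture always
honours its contract.

### What the simulations do and do not show

The generator reproduces the *statistical structure* the method assumes:
serial sampling, drift, extirpation, translocation, bounded stepwise
microsatellite evolution. It does not model sequencing or genotyping
error, ancient-DNA damage, within-deme spatial structure, selection or
recombination, and its sampling is geographically unbiased around each
centroid. Passing recovery tests therefore demonstrates correctness of
the inference logic under the stated model — not robustness to the
messiness of real museum data, where fragmentary sequences (handled by the
masking policy) and uneven sampling are the dominant complications.

## Numerical and edge-case choices

* Diversity statistics are undefined for n < 2 and raise rather than
  return silent zeros; empty groups are emitted with n = 0 and flagged.
* All-gap columns are dropped (with a warning) before strict collapsing.
* Monte-Carlo p-values use the add-one rule and compare table
  log-probabilities with a 1e−9 tolerance so that ties (e.g. the observed
  table being the mode) are counted as at-least-as-extreme.
* Empty range unions define Jaccard overlap as 0, with a warning.
* The pipeline is deterministic end to end given config + seed: the seed
  feeds the exact tests, the variogram multi-starts and the jitter, and
  is recorded in the run manifest together with a config hash and library
  versions.

## Known limitations

* Local populations are taken as input labels; the geographic grouping of
  sampling localities into populations is expert judgement and is not
  automated.
* The country-level extralimital rule cannot see within-country
  translocations and can flag natural cross-border sharing (see above).
* Rarefied richness depends on the chosen `g`; comparisons are only valid
  at equal `g`.
* Ordinary kriging of hard 0/1 memberships yields broad plateaus where
  groups co-occur; the range definition is calibrated for presence
  mapping, not for estimating admixture proportions.
* Tree inference, Bayesian clustering and skyline demography are out of
  scope: trees, cluster memberships and their supports are inputs.
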