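# Methods

## The model

Linkage disequilibrium network analysis treats a SNP data set as a
weighted graph: loci are vertices and each pair is joined by an edge
weighted with r², the squared two-locus correlation of allelic state.
Sweeping an LD threshold downwards through the distinct observed r²
values, connected components of the thresholded graph grow and fuse; a
single edge suffices to fuse two components (single linkage).  Recording
every fusion gives a rooted tree over descending thresholds, equivalent
to a single-linkage dendrogram on r² similarity.

Each fusion is scored per participating cluster *i* with

    λ_i = (median_before − median_after) · n_i

where `median_before` is the median of all intracluster r² of cluster *i*
before the merger, `median_after` the median of intracluster r² of the
merged cluster restricted to pairs involving at least one locus of *i*,
and `n_i` the pre-merger locus count of *i*.  λ is large when a big
and/or internally tight cluster is absorbed into a looser surrounding —
the signature of a set of loci bound by a common evolutionary cause
(chromosomal inversion, local adaptation, population structure) embedded
in a background of weaker associations.

Outliers are called relative to the tree's own λ distribution:
`λ_lim = median(λ) + φ · MAD(λ)` with the *unscaled* MAD (no 1.4826
consistency factor), and a cluster must also carry at least `|E|_min`
intracluster edges at its merge threshold.  Outliers with no other
outlier nested below them are single-outlier clusters (SOCs); outliers
containing SOCs are compound outlier clusters (COCs).  SOC names are
`<cluster id>_<formation threshold>` with the threshold printed to two
decimals.

### Numerical and structural choices

* **Event-driven sweep.**  Thresholds are the distinct observed r²
  values, not a decimal grid; a grid would quantise merge order.  Exact
  float ties fuse in one simultaneous multi-way event — any sequential
  order among tied edges would be arbitrary and would create phantom λ
  records.  Components still separate when edges are exhausted are closed
  under a synthetic root at threshold 0 so the tree is always total.
* **λ bookkeeping.**  The event log is replayed with per-cluster caches
  of intracluster r² values; every cross-block between merging clusters
  is computed once and reused, making total λ work linear in the number
  of defined pairs.  Exactness is enforced in tests against a brute-force
  median recomputation.
* **Singletons** carry no intracluster pair and are not scored.  Negative
  λ values (cross-cluster LD above the premerger median) are retained in
  the distribution used for median/MAD.
* **|E| counting.**  Edges are counted at the cluster's merge threshold —
  the last threshold at which it exists as itself, matching the naming
  convention.
* **Outlier comparison** is strict (λ > λ_lim), reading "exceeding"
  literally; the outlier set is therefore monotone non-increasing in both
  φ and |E|_min, which the tests assert over a 10×10 grid.

## r² estimation

Two estimators operate on unphased diploid dosages with pairwise deletion
of missing genotypes:

* `em_haplotype` (default): maximum-likelihood two-locus haplotype
  frequencies under random mating, fitted by EM from the 3×3 genotype
  table (only the double heterozygote is phase-ambiguous), then
  r² = D²/(p_A p_a p_B p_b).  EM is initialised at linkage equilibrium
  and stopped when the log-likelihood moves less than 1e-8 (at most 1000
  iterations); non-convergence is flagged and the last iterate returned.
  The implementation is vectorised across all pairs at once.
* `dosage_correlation`: squared Pearson correlation of dosage vectors.
  It assumes nothing about mating, which is relevant because pooled
  populations and inversion karyotypes violate the EM's random-mating
  assumption; both estimators are exposed and structural invariants
  (symmetry, [0,1] range) hold for either.

SNP filtering keeps biallelic polymorphic loci with minor allele
frequency strictly above `maf_min` (default 0.10, i.e. "above 10%") and
missing fraction at most `max_missing` (default 0.25); optionally one SNP
per RAD tag (highest MAF, ties by input order).  Pairs undefined after
pairwise deletion are absent edges, not zeros.

## SOC diagnostics

The inversion interpretation of a SOC is tested with standard
population-genetic follow-ups on the SOC's loci:

* **Dosage PCA** on the mean-imputed, centred, unit-scaled dosage matrix.
* **Grouping** by k-means on leading principal components (seeded,
  multiple restarts).  For the karyotype test the clustering runs on PC1
  only: the karyotype hypothesis is one-dimensional, and in practice the
  leading axis of SOC loci carries almost all between-group variance.
* **Per-locus F_IS** = 1 − H_obs/H_exp with H_exp = 2p(1−p) from
  within-group allele frequencies.  No small-sample correction is
  applied, preserving the exact closed forms (all-heterozygote → −1,
  HWE → 0, all-homozygote at p=½ → +1); the estimator consequently has a
  bias of about −1/(2n−1) in a group of n individuals, which matters for
  small groups (see sample-size guidance below).
* **Signature verdict**: with three groups, the PC1-intermediate group
  must show median F_IS < 0 (heterokaryotypes are heterozygous at every
  arrangement-diagnostic locus) while the flanking groups stay above a
  small negative tolerance (−0.1, an operationalisation of "centred close
  to zero").  A flanking group monomorphic at every SOC locus has no
  defined F_IS; that is maximal homozygosity — exactly what fixation for
  one arrangement produces — and counts as consistent.

## Synthetic data

The simulators generate the statistical structures the method detects;
they are first-class, tested code.

**Population split** (`simulate_split`): an ancestral population of
`ne` diploids splits into `n_pops` populations that evolve `t_split`
generations by mutation, recombination and drift, optionally with
symmetric migration; `sample_size` diploids per population are pooled
before LD is computed, converting between-population allele-frequency
differences into sample admixture LD.  Defaults are a desk-scale version
of the study design (ne=200, t_split=200 — the same t/2Ne = 0.5 as the
full-scale ne=1000, t=1000 scenario), ~1000 SNPs on 4 chromosomes, 25
diploids per population.  The default backend is the coalescent
(msprime): an exact sample from the neutral equilibrium, with discrete
loci (candidate sites 4× the SNP target, per-site mutation 2e-4,
per-adjacent-site recombination 0.01, thinned to the highest-MAF
segregating sites).  A forward Wright–Fisher backend implements the same
scenario explicitly (log-uniform standing variation, configurable
burn-in, per-meiosis recombination, migrant gametes) and is the basis of
the inversion simulator; it is slower and its burn-in is a truncation of
true equilibrium, so the coalescent backend is preferred for the split
scenario.

**Inversion** (`simulate_inversion`): one panmictic population carries a
biallelic arrangement at frequency `inversion_freq`; crossovers among
loci inside the rearranged segment occur only in homokaryotype meioses,
outside loci assort freely.  Over t generations the two arrangement
classes diverge by drift, so pooled karyotypes show high LD among inside
loci, heterokaryotypes sit between the homokaryotype groups on PC1 and
are heterozygous at diagnosed loci (strongly negative F_IS).  Defaults:
60 inside + 500 outside loci, ne=200, t=400, frequency 0.5, 150 of 200
diploids sampled.  Loci are initialised as an ascertained panel
(frequencies uniform on [0.1, 0.9], linkage equilibrium): the scenario
describes a set of assayed common SNPs, and a rare-skewed spectrum would
leave most inside loci below the MAF filter after drift.  The per-site
mutation rate (2e-4, shared with the split scenario) keeps the
arrangement classes internally polymorphic, as real karyotype classes
are — without it the homokaryotype groups' F_IS distributions collapse
to a handful of rare variants, whose values are structurally negative
(≈ −k/(2n−k)) regardless of mating.  Runs are conditioned
(deterministic retries on seeds derived from the master seed) on the
inversion still segregating, all three karyotypes appearing in the
sample, and the sampled frequency lying within ±0.2 of the target: a
neutral simulation only represents "an inversion observed polymorphic at
frequency f" — in nature typically maintained by balancing selection —
if conditioned, and the karyotype diagnostics are specified for
frequencies in roughly [0.3, 0.7].

**Planted LD blocks** (`generate_planted_ld`): direct r² matrices with
within-block values uniform on [0.7, 0.9] over a uniform background.
These are not realisable correlation structures in general and exercise
only the clustering/λ machinery, never the r² estimators.  The default
background ceiling is 0.05: with a sharp block/background contrast the λ
trigger fires at the block's first external contact, so the pure block is
the outlier; with a background near the within-block values' order of
magnitude, single-linkage accretion attaches a few background loci to a
block before its λ event fires — an intrinsic property of single linkage
worth knowing when interpreting real SOCs (the real data here also show
the occasional stray locus inside a SOC).

### What the simulators do not emulate

No selection, no RAD-seq artefacts (allele dropout, shared-tag SNPs are
only modelled as an optional tag label), no genotyping error or
missingness (real data have all three), no recombination map
heterogeneity.  Passing tests therefore demonstrate that the machinery
detects the targeted statistical structures under clean conditions, not
that any particular empirical cluster is an inversion.

## Analysis parameters

φ and |E|_min default to 7 and 20, the reference analysis values, and are
echoed in every report.  Because λ_lim is a *relative* rule
(median + φ·MAD of the tree's own λ distribution), lax parameters flag
the tail of the noise-λ distribution even in homogeneous data; users
should sweep parameters (`parameter_sweep`) and prefer SOCs stable across
a region of parameter space.  For reduced data sets, smaller clusters
need laxer parameters (the subsampling utility accepts separate
reference and replicate parameters for this reason).

## Problem sizes

The bundled studies run at desk scale, chosen so the full test suite and
the summary script complete in minutes on one core: ten seeds per study;
three-population runs with ~1000 SNPs × 75 pooled diploids; inversion
runs with 560 loci × 150 diploids; planted-block matrices of 100–200
loci.  The full-scale split scenario (ne=1000, t_split=1000) is available
via `SplitScenario` or `ldna simulate split --full-scale`.

## Known limitations

* Single-linkage accretion: SOC membership can include a few background
  loci attached just before the λ event; Jaccard overlap with a planted
  truth is high but not always 1.
* The EM estimator assumes random mating *within the analysed sample*,
  which the pooled designs deliberately violate; this can bias individual
  r² values, which is why the dosage-correlation estimator is offered
  alongside it.
* λ's functional form is linear in the pre-merger locus count; clusters
  merging into very unequal partners are scored on medians, so a large
  homogeneous merger can mask substructure (COCs are reported but not
  interpreted).
* The karyotype signature test assumes exactly three groups; rare
  inversions with substructured homokaryotypes (k=4 patterns) need a
  user-chosen k.
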