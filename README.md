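# ldna — linkage disequilibrium network analysis

`ldna` finds groups of loci bound together by exceptionally high linkage
disequilibrium (LD) in a population-genomic SNP data set, with no need
for a linkage map or reference genome.  Such groups are the footprints of
evolutionary phenomena that correlate alleles across many loci at once:
polymorphic chromosomal inversions (recombination is suppressed in
heterokaryotypes), local adaptation, and population structure or
admixture.  The intended users are population geneticists exploring SNP
data — especially from non-model organisms — who want an unsupervised,
genome-wide view of what is generating LD before committing to
locus-by-locus outlier scans.

## The method

1. **LD matrix.**  Pairwise r² (squared two-locus correlation) between
   all SNPs, estimated from unphased diploid genotypes either by
   maximum-likelihood haplotype frequencies (EM on the 3×3 genotype
   table; default) or as the squared Pearson correlation of dosages.
2. **Merger tree.**  Loci are vertices, r² values are edge weights.
   Sweeping the threshold downward, connected components fuse (single
   linkage: one edge suffices); the fusion order forms a tree over
   descending thresholds.
3. **λ statistic.**  Every merging cluster *i* is scored with
   λ = (median of its intracluster r² before the merger − median of the
   merged cluster's r² over pairs involving *i*) × (loci in *i*).
   High λ marks a large and/or tight cluster absorbed into a looser
   surrounding.
4. **Outlier calling.**  λ_lim = median(λ) + φ·MAD(λ) (unscaled MAD);
   clusters with λ > λ_lim and at least |E|_min intracluster edges are
   outliers.  Outliers with no outlier nested below them are
   single-outlier clusters (**SOCs**, hypothesised to tag one phenomenon
   each); outliers containing SOCs are compound outlier clusters
   (**COCs**).  Defaults: φ = 7, |E|_min = 20.
5. **Diagnostics.**  For each SOC: dosage PCA, k-means grouping, and
   per-locus F_IS per group.  An inversion SOC shows three groups with
   the heterokaryotypes PC1-intermediate and strongly heterozygote-excess
   (median F_IS ≪ 0) while homokaryotype groups sit near zero.

Bundled simulators provide testbeds with known truth: a Wright–Fisher /
coalescent population-split scenario whose pooled samples carry admixture
LD, a forward simulator of a polymorphic inversion with karyotype labels,
and direct LD matrices with planted high-LD blocks.

## Worked example

Simulate an LD matrix with three planted 15-locus blocks (within-block
r² in [0.7, 0.9]) over 55 background loci, then run the analysis:

```bash
$ ldna simulate blocks --n-loci 100 --seed 7 --out sim
wrote sim/
$ ldna run --ldmatrix sim/ld_matrix.tsv --out results
4 outlier clusters: 3 SOCs (134_0.88, 140_0.87, 141_0.87), 1 COCs
$ tail -5 results/outliers.tsv
name	type	lambda	edges	n_loci	merge_threshold
134_0.88	SOC	11.61523886	105	15	0.04996809762
140_0.87	SOC	11.26068189	105	15	0.04997154627
141_0.87	SOC	11.54193265	105	15	0.04997154627
142_0.05	COC	0.5159229974	211	30	0.04996809762
```

Reading the output: each planted block is recovered as one SOC.  The
name `134_0.88` means cluster 134, first complete at LD threshold 0.88;
its 15 loci hold all 105 pairwise edges at its merge threshold, and its
λ ≈ 11.6 — the median intracluster r² (~0.8) collapses toward the
background (~0.025) when the block finally merges at r² ≈ 0.05, scaled by
its 15 loci.  Two blocks happened to fuse with each other before joining
the rest, so their union also scores as an outlier: it is reported as a
COC (a compound containing two SOCs), not as a separate phenomenon.
`results/` also contains the edge list, the tree (newick + event table),
the full λ table, per-locus cluster membership, and `run_info.json` with
parameters, seed and the input checksum.

For genotype input use `--vcf data.vcf` or `--geno table.tsv` (rows =
samples, columns = SNP dosages 0/1/2/NA); SNPs are filtered to minor
allele frequency > 10% by default.  `ldna diagnose --geno table.tsv
--membership results/membership.tsv --soc 134_0.88` runs the PCA /
F_IS karyotype diagnostics for one SOC.  Library users: see
`ldna.analyze_ld`, `ldna.run_pipeline` and the `ldna.simdata` module.

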