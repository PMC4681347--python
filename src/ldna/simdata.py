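"""Synthetic data with the LD structure the network analysis detects.

Three generators:

* :func:`simulate_split` -- an ancestral population splits into ``n_pops``
  populations that drift apart for ``t_split`` generations (optionally
  with symmetric migration); samples are pooled before LD calculation, so
  the between-population allele-frequency differences become sample
  admixture LD.  Backends: ``"coalescent"`` (msprime; samples the
  mutation-drift equilibrium exactly) and ``"forward"`` (explicit diploid
  Wright-Fisher with per-adjacent-locus recombination).
* :func:`simulate_inversion` -- a panmictic population carrying a
  polymorphic inversion; recombination among loci inside the rearranged
  segment happens only in homokaryotype meioses, so the two arrangements
  diverge by drift and pooled karyotypes show high LD among inside loci.
* :func:`generate_planted_ld` -- direct r^2 matrices with planted
  high-LD blocks, for exercising the clustering/lambda machinery with
  known truth (not realizable correlation structures in general; never
  used to test the r^2 estimators).

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ldna.core import GenotypeMatrix, LDMatrix


@dataclass
class SplitScenario:
    """Population-split scenario (drift-only divergence, pooled sampling).

    Defaults are the desk-scale version of the three-population study
    design (full scale: ne=1000, t_split=1000): ne=200 diploids per
    population, 200 generations since the split, ~1000 SNPs on 4
    chromosomes, 25 diploids sampled per population, no migration.
    ``migration_rate`` is the per-generation fraction of migrant gametes,
    symmetric among populations.
    """

    n_pops: int = 3
    ne: int = 200
    t_split: int = 200
    mutation_rate: float = 2e-4
    recombination: float = 0.01
    n_loci: int = 1000
    n_chromosomes: int = 4
    sample_size: int = 25
    migration_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.mutation_rate, self.recombination, self.migration_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if self.sample_size > self.ne:
            raise ValueError("sample_size cannot exceed ne")


@dataclass
class InversionScenario:
    """A polymorphic inversion segregating in one panmictic population."""

    n_loci_inside: int = 60
    n_loci_outside: int = 500
    inversion_freq: float = 0.5
    ne: int = 200
    t: int = 400
    mutation_rate: float = 2e-4
    recombination: float = 0.01
    sample_size: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inversion_freq <= 1.0:
            raise ValueError("inversion_freq must be in [0, 1]")
        if self.n_loci_inside < 2:
            raise ValueError("need at least 2 loci inside the inversion")
        if self.sample_size > self.ne:
            raise ValueError("sample_size cannot exceed ne")


@dataclass
class PlantedBlockSpec:
    """Direct LD matrix with planted high-LD blocks over a low background."""

    n_loci: int
    blocks: list[tuple[int, float, float]]  # (size, within_low, within_high)
    background_r2_high: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(b[0] for b in self.blocks) > self.n_loci:
            raise ValueError("block sizes exceed n_loci")
        for size, low, high in self.blocks:
            if not 0.0 <= self.background_r2_high < low <= high <= 1.0:
                raise ValueError(
                    "need 0 <= background_r2_high < within_low <= within_high <= 1"
                )


# ---------------------------------------------------------------------------
# forward Wright-Fisher machinery
# ---------------------------------------------------------------------------


def _gametes(
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    boundary_p: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Meiosis for a batch of gametes.

    ``haplotypes`` is ``(2*N, L)``; ``parent_idx`` gives the diploid parent
    of each gamete; ``boundary_p[g, b]`` is the crossover probability
    between adjacent loci b and b+1 for gamete g.  Returns the gametes and
    the per-locus source haplotype (0/1), the latter so callers can track
    which parental copy contributed a given segment.
    """
    n_gam, l = len(parent_idx), haplotypes.shape[1]
    start = rng.integers(0, 2, size=n_gam, dtype=np.int32)
    switches = (rng.random((n_gam, l - 1)) < boundary_p).astype(np.int32)
    src = np.empty((n_gam, l), dtype=np.int32)
    src[:, 0] = 0
    np.cumsum(switches, axis=1, out=src[:, 1:])
    src = (src + start[:, None]) % 2
    hap0 = haplotypes[2 * parent_idx]
    hap1 = haplotypes[2 * parent_idx + 1]
    gametes = np.where(src == 0, hap0, hap1)
    return gametes, src


def _mutate(haplotypes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Flip alleles in place at Poisson(#cells * rate) random cells."""
    if rate <= 0:
        return
    n_mut = rng.poisson(haplotypes.size * rate)
    if n_mut == 0:
        return
    rows = rng.integers(0, haplotypes.shape[0], size=n_mut)
    cols = rng.integers(0, haplotypes.shape[1], size=n_mut)
    haplotypes[rows, cols] ^= 1


def _init_standing_variation(
    n_hap: int,
    n_loci: int,
    rng: np.random.Generator,
    spectrum: str = "neutral",
) -> np.ndarray:
    """Haplotypes with standing variation at linkage equilibrium, used to
    seed forward runs in place of an infinite burn-in.

    ``"neutral"``: 1/x-skewed frequencies (log-uniform on [1/n_hap, 0.5],
    random polarity) approximating a neutral site-frequency spectrum.
    ``"panel"``: frequencies uniform on [0.1, 0.9], mimicking a genotyping
    panel ascertained for common variants.
    """
    if spectrum == "neutral":
        u = rng.random(n_loci)
        lo, hi = 1.0 / n_hap, 0.5
        freqs = lo * (hi / lo) ** u
        flip = rng.random(n_loci) < 0.5
        freqs = np.where(flip, 1.0 - freqs, freqs)
    elif spectrum == "panel":
        freqs = rng.uniform(0.1, 0.9, size=n_loci)
    else:
        raise ValueError(f"unknown spectrum {spectrum!r}")
    return (rng.random((n_hap, n_loci)) < freqs).astype(np.int8)


def _thin_by_maf(dosages: np.ndarray, n_target: int) -> np.ndarray:
    """Indices of the ``n_target`` highest-MAF segregating columns, in
    original column order."""
    p = dosages.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    seg = np.flatnonzero(maf > 0)
    if seg.size == 0:
        raise ValueError("no segregating sites to retain")
    if seg.size <= n_target:
        return seg
    top = seg[np.argsort(-maf[seg], kind="stable")[:n_target]]
    return np.sort(top)


# ---------------------------------------------------------------------------
# population split
# ---------------------------------------------------------------------------


def simulate_split(sc: SplitScenario, backend: str = "coalescent", burn_in: int | None = None) -> GenotypeMatrix:
    """Pooled sample from a population-split scenario.

    Returns a :class:`GenotypeMatrix` with ``population_labels`` set
    ("pop0", "pop1", ...), loci thinned to the ``sc.n_loci`` highest-MAF
    segregating sites.  ``burn_in`` applies to the forward backend only
    (default ``2 * ne`` generations from log-uniform standing variation).
    """
    if backend == "coalescent":
        return _split_coalescent(sc)
    if backend == "forward":
        return _split_forward(sc, burn_in)
    raise ValueError(f"unknown backend {backend!r}")


def _split_coalescent(sc: SplitScenario) -> GenotypeMatrix:
    import msprime

    rng = np.random.default_rng(sc.seed)
    demography = msprime.Demography()
    demography.add_population(name="anc", initial_size=sc.ne)
    names = [f"pop{k}" for k in range(sc.n_pops)]
    for name in names:
        demography.add_population(name=name, initial_size=sc.ne)
    if sc.n_pops > 1:
        demography.add_population_split(
            time=sc.t_split, derived=names, ancestral="anc"
        )
        if sc.migration_rate > 0:
            demography.set_symmetric_migration_rate(names, sc.migration_rate)
    # discrete loci: sequence positions are candidate SNP sites
    sites_per_chrom = int(np.ceil(4 * sc.n_loci / sc.n_chromosomes))
    dosage_chunks, id_chunks = [], []
    for chrom in range(sc.n_chromosomes):
        seed_a, seed_m = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples={name: sc.sample_size for name in names},
            demography=demography,
            sequence_length=sites_per_chrom,
            recombination_rate=sc.recombination,
            discrete_genome=True,
            random_seed=int(seed_a),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=sc.mutation_rate,
            random_seed=int(seed_m),
            model=msprime.BinaryMutationModel(),
        )
        geno = mts.genotype_matrix()  # sites x haplotypes, 0/1
        if geno.size == 0:
            continue
        dos = geno[:, 0::2] + geno[:, 1::2]  # sites x diploids
        dosage_chunks.append(dos.T)
        positions = [int(s.position) for s in mts.sites()]
        id_chunks.extend(f"chr{chrom + 1}_{pos}" for pos in positions)
    if not dosage_chunks:
        raise ValueError("no segregating sites in simulation output")
    dosages = np.concatenate(dosage_chunks, axis=1)
    keep = _thin_by_maf(dosages, sc.n_loci)
    labels = np.repeat(names, sc.sample_size)
    return GenotypeMatrix(
        dosages=dosages[:, keep],
        locus_ids=np.array(id_chunks, dtype=object)[keep],
        sample_ids=np.array(
            [f"{pop}_ind{i}" for pop in names for i in range(sc.sample_size)],
            dtype=object,
        ),
        population_labels=labels,
    )


def _split_forward(sc: SplitScenario, burn_in: int | None) -> GenotypeMatrix:
    rng = np.random.default_rng(sc.seed)
    burn_in = 2 * sc.ne if burn_in is None else burn_in
    n_raw = 3 * sc.n_loci
    per_chrom = int(np.ceil(n_raw / sc.n_chromosomes))
    n_raw = per_chrom * sc.n_chromosomes
    boundary = np.full(n_raw - 1, sc.recombination)
    boundary[per_chrom - 1 :: per_chrom] = 0.5  # chromosome boundaries
    n_hap = 2 * sc.ne

    def advance(pop: np.ndarray) -> np.ndarray:
        parents = rng.integers(0, sc.ne, size=n_hap)
        bp = np.broadcast_to(boundary, (n_hap, n_raw - 1))
        gam, _ = _gametes(pop, parents, bp, rng)
        _mutate(gam, sc.mutation_rate, rng)
        return gam

    anc = _init_standing_variation(n_hap, n_raw, rng)
    for _ in range(burn_in):
        anc = advance(anc)
    pops = [anc.copy() for _ in range(sc.n_pops)]
    for _ in range(sc.t_split):
        new_pops = []
        for k in range(sc.n_pops):
            # migrant gametes come from a random other population
            source_pop = np.full(n_hap, k)
            if sc.n_pops > 1 and sc.migration_rate > 0:
                mig = rng.random(n_hap) < sc.migration_rate
                others = rng.integers(0, sc.n_pops - 1, size=n_hap)
                others = np.where(others >= k, others + 1, others)
                source_pop = np.where(mig, others, source_pop)
            gam = np.empty((n_hap, n_raw), dtype=np.int8)
            for src_k in np.unique(source_pop):
                rows = np.flatnonzero(source_pop == src_k)
                parents = rng.integers(0, sc.ne, size=len(rows))
                bp = np.broadcast_to(boundary, (len(rows), n_raw - 1))
                g, _ = _gametes(pops[src_k], parents, bp, rng)
                gam[rows] = g
            _mutate(gam, sc.mutation_rate, rng)
            new_pops.append(gam)
        pops = new_pops
    dosage_rows, labels, sample_ids = [], [], []
    for k, pop in enumerate(pops):
        chosen = rng.choice(sc.ne, size=sc.sample_size, replace=False)
        dosage_rows.append(pop[2 * chosen] + pop[2 * chosen + 1])
        labels.extend([f"pop{k}"] * sc.sample_size)
        sample_ids.extend(f"pop{k}_ind{i}" for i in range(sc.sample_size))
    dosages = np.concatenate(dosage_rows, axis=0)
    keep = _thin_by_maf(dosages, sc.n_loci)
    chroms = keep // per_chrom + 1
    pos = keep % per_chrom
    locus_ids = np.array(
        [f"chr{c}_{p}" for c, p in zip(chroms, pos)], dtype=object
    )
    return GenotypeMatrix(
        dosages=dosages[:, keep],
        locus_ids=locus_ids,
        sample_ids=np.array(sample_ids, dtype=object),
        population_labels=np.array(labels, dtype=object),
    )


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


@dataclass
class InversionSample:
    genotypes: GenotypeMatrix
    karyotypes: np.ndarray  # "AA" / "AB" / "BB" per sampled individual
    inside_loci: np.ndarray  # locus ids inside the inversion


def simulate_inversion(
    sc: InversionScenario, condition: bool = True, max_retries: int = 20
) -> InversionSample:
    """Panmictic population with a polymorphic inversion.

    Recombination among loci inside the rearranged segment occurs only in
    meioses of homokaryotype parents; loci outside assort freely.  The two
    arrangements therefore diverge by drift over ``sc.t`` generations and
    pooled karyotypes show strong LD among the diverged inside loci.

    With ``condition=True`` the run is retried (deterministically, with
    seeds derived from ``sc.seed``) until the inversion is still
    segregating at sampling time, all three karyotypes appear in the
    sample, and the sampled arrangement frequency lies within 0.2 of
    ``sc.inversion_freq`` -- the scenario describes an inversion
    *observed* polymorphic at that frequency (in nature typically held
    there by balancing selection, which the neutral simulation replaces
    by conditioning).  A run that exhausts ``max_retries`` raises.
    """
    polymorphic = 0.0 < sc.inversion_freq < 1.0
    check = condition and polymorphic
    attempts = max_retries if check else 1
    for attempt in range(attempts):
        seed = np.random.default_rng([sc.seed, attempt]).integers(0, 2**31 - 1)
        result = _inversion_once(sc, int(seed), check)
        if result is not None:
            return result
    raise ValueError(f"inversion lost in all {attempts} conditioned attempt(s)")


def _inversion_once(sc: InversionScenario, seed: int, check: bool) -> InversionSample | None:
    rng = np.random.default_rng(seed)
    l_in, l_out = sc.n_loci_inside, sc.n_loci_outside
    l_tot = l_in + l_out
    n_hap = 2 * sc.ne
    # panel-style spectrum: the scenario describes a set of assayed common
    # SNPs, and rare-skewed standing variation would leave most of the
    # inside loci below any MAF filter after drift
    haplos = _init_standing_variation(n_hap, l_tot, rng, spectrum="panel")
    n_b = int(round(sc.inversion_freq * n_hap))
    arr = np.zeros(n_hap, dtype=np.int8)
    arr[rng.choice(n_hap, size=n_b, replace=False)] = 1

    boundary_base = np.full(l_tot - 1, 0.5)  # free recombination outside
    for _ in range(sc.t):
        parents = rng.integers(0, sc.ne, size=n_hap)
        homo = arr[2 * parents] == arr[2 * parents + 1]
        bp = np.broadcast_to(boundary_base, (n_hap, l_tot - 1)).copy()
        if l_in > 1:
            # inside-inside boundaries: crossover only in homokaryotypes
            bp[:, : l_in - 1] = np.where(homo[:, None], sc.recombination, 0.0)
        gam, src = _gametes(haplos, parents, bp, rng)
        new_arr = arr[2 * parents + src[:, 0]]
        _mutate(gam, sc.mutation_rate, rng)
        haplos, arr = gam, new_arr
        f = arr.mean()
        if check and (f == 0.0 or f == 1.0):
            return None
    chosen = rng.choice(sc.ne, size=sc.sample_size, replace=False)
    kary_code = arr[2 * chosen] + arr[2 * chosen + 1]
    if check and len(np.unique(kary_code)) < 3:
        return None
    if check and abs(kary_code.mean() / 2.0 - sc.inversion_freq) > 0.2:
        return None
    karyotypes = np.array(["AA", "AB", "BB"], dtype=object)[kary_code]
    dosages = haplos[2 * chosen] + haplos[2 * chosen + 1]
    locus_ids = np.array(
        [f"inv_{i:04d}" for i in range(l_in)]
        + [f"bg_{i:04d}" for i in range(l_out)],
        dtype=object,
    )
    g = GenotypeMatrix(
        dosages=dosages,
        locus_ids=locus_ids,
        sample_ids=np.array([f"ind{i}" for i in range(sc.sample_size)], dtype=object),
    )
    return InversionSample(
        genotypes=g, karyotypes=karyotypes, inside_loci=locus_ids[:l_in]
    )


# ---------------------------------------------------------------------------
# planted LD blocks
# ---------------------------------------------------------------------------


def generate_planted_ld(spec: PlantedBlockSpec) -> tuple[LDMatrix, np.ndarray]:
    """LD matrix with planted within-block r^2 over a uniform background.

    Returns the matrix and a per-locus block label (-1 for background,
    0..n_blocks-1 for planted blocks, blocks occupying leading columns in
    order).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_loci
    values = rng.uniform(0.0, spec.background_r2_high, size=(p, p))
    labels = np.full(p, -1)
    offset = 0
    for b, (size, low, high) in enumerate(spec.blocks):
        sl = slice(offset, offset + size)
        values[sl, sl] = rng.uniform(low, high, size=(size, size))
        labels[sl] = b
        offset += size
    values = np.triu(values, k=1)
    values = values + values.T
    np.fill_diagonal(values, np.nan)
    locus_ids = np.array([f"L{i:04d}" for i in range(p)], dtype=object)
    ld = LDMatrix(values=values, locus_ids=locus_ids, n_obs=np.full((p, p), 100))
    return ld, labels
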