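"""Core in-memory containers: genotype matrices and pairwise LD matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel for a missing diploid genotype in a dosage matrix.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Unphased diploid biallelic genotypes as ALT-allele dosages.

    Rows are individuals, columns are loci.  Dosages take values 0, 1, 2
    (count of ALT alleles) or :data:`MISSING`.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_loci)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    locus_ids
        Unique locus identifier strings, one per column.
    sample_ids
        Unique sample identifier strings, one per row.
    locus_positions
        Optional ``(chromosome, 1-based position)`` per locus.
    rad_tags
        Optional group label per locus; SNPs from the same sequenced
        fragment share a tag and may be collapsed to one per tag.
    population_labels
        Optional population-of-origin string per individual.
    """

    dosages: np.ndarray
    locus_ids: np.ndarray
    sample_ids: np.ndarray
    locus_positions: list[tuple[str, int]] | None = None
    rad_tags: np.ndarray | None = None
    population_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.rad_tags is not None:
            self.rad_tags = np.asarray(self.rad_tags, dtype=object)
        if self.population_labels is not None:
            self.population_labels = np.asarray(self.population_labels, dtype=object)
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.locus_ids) != p:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {p} columns")
        if len(set(self.locus_ids)) != p:
            raise ValueError("locus ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage {self.dosages[i, j]} at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r} is outside {{0,1,2,missing}}"
            )
        if self.locus_positions is not None:
            seen: set[tuple[str, int]] = set()
            for pos in self.locus_positions:
                if pos in seen:
                    raise ValueError(f"duplicate locus position {pos}")
                seen.add(pos)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def observed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.dosages != MISSING

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-locus MAF over non-missing genotypes (NaN if all missing)."""
        obs = self.observed_mask()
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n_obs)
        p = np.where(n_obs > 0, p, np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return 1.0 - self.observed_mask().mean(axis=0)

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given locus indices (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            locus_ids=self.locus_ids[index],
            sample_ids=self.sample_ids,
            locus_positions=None
            if self.locus_positions is None
            else [self.locus_positions[i] for i in index],
            rad_tags=None if self.rad_tags is None else self.rad_tags[index],
            population_labels=self.population_labels,
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            locus_ids=self.locus_ids,
            sample_ids=self.sample_ids[index],
            locus_positions=self.locus_positions,
            rad_tags=self.rad_tags,
            population_labels=None
            if self.population_labels is None
            else self.population_labels[index],
        )

    def locus_index(self, ids) -> np.ndarray:
        """Column indices of the given locus ids (order of the query)."""
        lookup = {lid: i for i, lid in enumerate(self.locus_ids)}
        return np.array([lookup[i] for i in ids], dtype=int)


@dataclass
class LDMatrix:
    """Symmetric pairwise r^2 between loci.

    ``values`` is an ``(n_loci, n_loci)`` float array; the diagonal and any
    pair for which r^2 is undefined (too few joint observations, or a locus
    monomorphic after pairwise deletion) are NaN.  ``n_obs`` records the
    number of individuals used per pair.
    """

    values: np.ndarray
    locus_ids: np.ndarray
    n_obs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("LD matrix must be square")
        if len(self.locus_ids) != p:
            raise ValueError("locus_ids length mismatch")
        if len(set(self.locus_ids)) != p:
            raise ValueError("locus ids are not unique")
        defined = ~np.isnan(self.values)
        if not np.array_equal(defined, defined.T):
            raise ValueError("definedness pattern is not symmetric")
        if defined.any():
            vals = self.values[defined]
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError("r^2 values outside [0, 1]")
            if not np.allclose(
                self.values[defined], self.values.T[defined], rtol=0, atol=0
            ):
                raise ValueError("LD matrix is not symmetric")
        if self.n_obs is not None:
            self.n_obs = np.asarray(self.n_obs, dtype=int)
            off = defined.copy()
            np.fill_diagonal(off, False)
            if (self.n_obs[off] < 2).any():
                raise ValueError("defined pair with fewer than 2 observations")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    def edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Defined unordered pairs as parallel arrays ``(i, j, r2)``, i < j."""
        iu, ju = np.triu_indices(self.n_loci, k=1)
        w = self.values[iu, ju]
        keep = ~np.isnan(w)
        return iu[keep], ju[keep], w[keep]

    def subset(self, index: np.ndarray) -> "LDMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return LDMatrix(
            values=self.values[np.ix_(index, index)],
            locus_ids=self.locus_ids[index],
            n_obs=None if self.n_obs is None else self.n_obs[np.ix_(index, index)],
        )
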