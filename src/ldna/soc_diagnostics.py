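"""Population-genetic follow-ups for SOCs: PCA, grouping, F_IS, inversion test.

A SOC tagging a polymorphic inversion should split the sample into three
groups on its loci: the two homokaryotypes at the ends of PC1 and the
heterokaryotypes in between, the latter with a strong heterozygote excess
(strongly negative F_IS) because every diverged locus inside the
rearrangement is heterozygous in every heterokaryotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ldna.core import MISSING, GenotypeMatrix


@dataclass
class GroupAssignment:
    k: int
    labels: np.ndarray  # group index per individual, 0..k-1
    method: str = "kmeans_on_pcs"


@dataclass
class InversionSignature:
    is_consistent: bool
    intermediate_group: int | None
    median_fis_by_group: dict[int, float]
    pc1_group_order: list[int]


def pca_dosage(
    g: GenotypeMatrix, loci=None, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the mean-imputed, centred, unit-scaled dosage matrix.

    Missing genotypes are replaced by the locus mean; columns are centred
    and scaled to unit variance (constant columns are left centred only).
    Returns ``(coordinates, variance_fractions)``.  Component signs are
    arbitrary.
    """
    if g.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    idx = np.arange(g.n_loci) if loci is None else _as_locus_index(g, loci)
    if len(idx) < 2:
        raise ValueError("PCA needs at least 2 loci")
    x = g.dosages[:, idx].astype(float)
    miss = x == MISSING
    if miss.all(axis=0).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValueError(f"locus {g.locus_ids[idx[j]]!r} is missing in all individuals")
    x[miss] = np.nan
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean, x)
    x -= mean
    sd = x.std(axis=0)
    x /= np.where(sd > 0, sd, 1.0)
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_


def _as_locus_index(g: GenotypeMatrix, loci) -> np.ndarray:
    loci = np.asarray(loci)
    if loci.dtype.kind in "iub":
        if loci.dtype == bool:
            return np.flatnonzero(loci)
        return loci.astype(int)
    return g.locus_index(loci)


def assign_groups(coords: np.ndarray, k: int, seed: int = 0, n_pcs: int = 10) -> GroupAssignment:
    """k-means on the leading principal components, deterministic per seed."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} individuals")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(coords[:, : min(n_pcs, coords.shape[1])])
    return GroupAssignment(k=k, labels=labels)


def fis_per_locus(g: GenotypeMatrix, loci=None, group=None) -> np.ndarray:
    """Inbreeding coefficient F_IS = 1 - H_obs/H_exp per locus.

    Computed within the given individual subset from non-missing
    genotypes, with H_exp = 2p(1-p) from within-group allele frequencies.
    Monomorphic-within-group or under-observed loci are NaN.
    """
    idx = np.arange(g.n_loci) if loci is None else _as_locus_index(g, loci)
    rows = np.arange(g.n_individuals) if group is None else np.asarray(group)
    if rows.dtype == bool:
        rows = np.flatnonzero(rows)
    if len(rows) == 0:
        raise ValueError("empty group")
    d = g.dosages[np.ix_(rows, idx)]
    obs = d != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n)
        h_obs = np.where(obs, d == 1, False).sum(axis=0) / n
        h_exp = 2.0 * p * (1.0 - p)
        fis = 1.0 - h_obs / h_exp
    return np.where((n >= 2) & (h_exp > 0), fis, np.nan)


def test_inversion_signature(
    g: GenotypeMatrix,
    soc_loci,
    assignment: GroupAssignment,
    flank_tolerance: float = -0.1,
    het_excess_threshold: float = -0.1,
) -> InversionSignature:
    """Test the heterokaryotype signature of an inversion SOC.

    With three groups assigned on the SOC loci, identifies the group whose
    PC1 centroid lies between the other two and checks that its median
    per-locus F_IS shows a material heterozygote excess (below
    ``het_excess_threshold``; heterokaryotypes are heterozygous at every
    arrangement-diagnostic locus, so the genuine signature is strongly
    negative, while ordinary sampling noise sits at about -1/(2n-1))
    and that the flanking (homokaryotype) groups' medians stay above
    ``flank_tolerance``.  A flanking group that is monomorphic at every
    SOC locus has no defined F_IS; this is maximal homozygosity (exactly
    what fixation for one arrangement produces) and counts as consistent,
    reported as NaN.
    """
    if assignment.k != 3:
        raise ValueError("inversion signature test needs exactly 3 groups")
    labels = np.asarray(assignment.labels)
    groups = np.unique(labels)
    if len(groups) < 3:
        raise ValueError("fewer than 3 nonempty groups")
    coords, _ = pca_dosage(g, soc_loci)
    pc1 = coords[:, 0]
    centroids = {int(gr): float(pc1[labels == gr].mean()) for gr in groups}
    order = sorted(centroids, key=centroids.get)
    mid = order[1]
    med_fis = {}
    for gr in groups:
        fis = fis_per_locus(g, soc_loci, labels == gr)
        fis = fis[~np.isnan(fis)]
        med_fis[int(gr)] = float(np.median(fis)) if fis.size else np.nan
    strictly_between = centroids[order[0]] < centroids[mid] < centroids[order[2]]
    flanks_ok = all(
        np.isnan(med_fis[gr]) or med_fis[gr] >= flank_tolerance
        for gr in (order[0], order[2])
    )
    consistent = (
        strictly_between
        and not np.isnan(med_fis[mid])
        and med_fis[mid] < het_excess_threshold
        and flanks_ok
    )
    return InversionSignature(
        is_consistent=bool(consistent),
        intermediate_group=int(mid),
        median_fis_by_group=med_fis,
        pc1_group_order=[int(o) for o in order],
    )
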