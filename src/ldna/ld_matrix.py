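"""SNP filtering and pairwise r^2 estimation from unphased diploid genotypes.

Two estimators are provided.  ``em_haplotype`` fits two-locus haplotype
frequencies by expectation-maximisation from the 3x3 genotype table under
random mating (the classic maximum-likelihood approach for unphased data)
and returns r^2 = D^2 / (p_A p_a p_B p_b).  ``dosage_correlation`` is the
squared Pearson correlation of the 0/1/2 dosage vectors; it makes no
mating-system assumption, which matters when the sample pools diverged
populations or inversion karyotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ldna.core import MISSING, GenotypeMatrix, LDMatrix

_ESTIMATORS = ("em_haplotype", "dosage_correlation")


@dataclass
class LDEstimatorConfig:
    """Settings for SNP filtering and r^2 estimation.

    ``maf_min`` is a strict lower bound: loci are kept when MAF > maf_min
    (so the default 0.10 reads "minor allele frequency above 10%").
    """

    estimator: str = "em_haplotype"
    maf_min: float = 0.10
    max_missing: float = 0.25
    one_snp_per_tag: bool = False
    em_max_iter: int = 1000
    em_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.estimator not in _ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ValueError("em_tol must be > 0 and em_max_iter >= 1")


def filter_snps(g: GenotypeMatrix, cfg: LDEstimatorConfig | None = None) -> GenotypeMatrix:
    """Retain polymorphic biallelic SNPs passing MAF and missingness filters.

    Keeps loci with MAF strictly greater than ``cfg.maf_min`` (computed
    over non-missing genotypes) and missing fraction <= ``cfg.max_missing``.
    With ``one_snp_per_tag``, keeps the highest-MAF SNP per RAD tag (ties
    broken by original column order).  Column order is preserved.
    """
    cfg = cfg or LDEstimatorConfig()
    if g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    maf = g.minor_allele_frequency()
    with np.errstate(invalid="ignore"):
        keep = (maf > cfg.maf_min) & (maf > 0) & (g.missing_fraction() <= cfg.max_missing)
    keep &= ~np.isnan(maf)
    if cfg.one_snp_per_tag and g.rad_tags is not None:
        best: dict[object, int] = {}
        for j in np.flatnonzero(keep):
            tag = g.rad_tags[j]
            if tag not in best or maf[j] > maf[best[tag]]:
                best[tag] = j
        chosen = set(best.values())
        keep = np.array([j in chosen and keep[j] for j in range(g.n_loci)])
    if not keep.any():
        raise ValueError("no loci survive the SNP filters")
    return g.subset_loci(keep)


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimator, vectorised over pairs
# ---------------------------------------------------------------------------


def _genotype_pair_counts(x_block: np.ndarray, y_block: np.ndarray) -> np.ndarray:
    """3x3 genotype-combination counts for every locus pair.

    Returns shape ``(3, 3, Lx, Ly)``: entry ``[a, b]`` counts individuals
    with dosage ``a`` at the row locus and ``b`` at the column locus, both
    observed.  Missing genotypes drop out because they match no indicator.
    """
    ix = [(x_block == a).astype(np.float64) for a in (0, 1, 2)]
    iy = [(y_block == b).astype(np.float64) for b in (0, 1, 2)]
    return np.array([[ixa.T @ iyb for iyb in iy] for ixa in ix])


def _em_r2_flat(
    n: np.ndarray, em_tol: float, em_max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-locus EM on a batch of 3x3 count tables, shape ``(3, 3, M)``.

    Returns ``(r2, converged)`` of length M, with NaN where r^2 is
    undefined (fewer than two joint observations, or a locus monomorphic
    after pairwise deletion).  Haplotypes are coded by ALT content:
    p11 = freq(ALT at both loci).  Only the double-heterozygote cell is
    phase-ambiguous; the EM splits it between coupling (11/00) and
    repulsion (10/01) resolutions.  Convergence: log-likelihood change
    below ``em_tol``.
    """
    n = n.reshape(3, 3, -1)
    nobs = n.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = (2 * n[2].sum(axis=0) + n[1].sum(axis=0)) / (2 * nobs)
        p_b = (2 * n[:, 2].sum(axis=0) + n[:, 1].sum(axis=0)) / (2 * nobs)
    defined = (nobs >= 2) & (p_a > 0) & (p_a < 1) & (p_b > 0) & (p_b < 1)

    def run(nn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # Known haplotype counts (everything except the double het).
        c11 = 2 * nn[2, 2] + nn[2, 1] + nn[1, 2]
        c10 = 2 * nn[2, 0] + nn[2, 1] + nn[1, 0]
        c01 = 2 * nn[0, 2] + nn[0, 1] + nn[1, 2]
        c00 = 2 * nn[0, 0] + nn[0, 1] + nn[1, 0]
        ndh = nn[1, 1]
        tot = nn.sum(axis=(0, 1)) * 2.0
        pa = (2 * nn[2].sum(axis=0) + nn[1].sum(axis=0)) / tot
        pb = (2 * nn[:, 2].sum(axis=0) + nn[:, 1].sum(axis=0)) / tot
        p11 = pa * pb
        p00 = (1 - pa) * (1 - pb)
        p10 = pa * (1 - pb)
        p01 = (1 - pa) * pb

        def loglik(p11, p10, p01, p00, nn):
            probs = np.stack(
                [
                    p00**2, 2 * p00 * p01, p01**2,
                    2 * p00 * p10, 2 * (p11 * p00 + p10 * p01), 2 * p11 * p01,
                    p10**2, 2 * p11 * p10, p11**2,
                ]
            )
            cells = nn.reshape(9, -1)
            with np.errstate(divide="ignore"):
                return np.where(cells > 0, cells * np.log(np.maximum(probs, 1e-300)), 0.0).sum(axis=0)

        ll = loglik(p11, p10, p01, p00, nn)
        conv = np.zeros(ll.shape, dtype=bool)
        active = np.arange(ll.size)
        niter = 0
        while active.size and niter < em_max_iter:
            niter += 1
            coup = p11[active] * p00[active]
            rep = p10[active] * p01[active]
            denom = np.maximum(coup + rep, 1e-300)
            q = np.where(coup + rep > 0, coup / denom, 0.5)
            nd = ndh[active]
            t = tot[active]
            p11[active] = (c11[active] + q * nd) / t
            p10[active] = (c10[active] + (1 - q) * nd) / t
            p01[active] = (c01[active] + (1 - q) * nd) / t
            p00[active] = (c00[active] + q * nd) / t
            ll_new = loglik(
                p11[active], p10[active], p01[active], p00[active], nn[:, :, active]
            )
            done = np.abs(ll_new - ll[active]) < em_tol
            ll[active] = ll_new
            conv[active[done]] = True
            active = active[~done]
        d = p11 - pa * pb
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = d**2 / (pa * (1 - pa) * pb * (1 - pb))
        return np.clip(r2, 0.0, 1.0), conv

    r2 = np.full(nobs.shape, np.nan)
    converged = np.ones(nobs.shape, dtype=bool)
    idx = np.flatnonzero(defined)
    if idx.size:
        r2_d, conv_d = run(n[:, :, idx])
        r2[idx] = r2_d
        converged[idx] = conv_d
    return r2, converged


def _dosage_corr_r2(x_block: np.ndarray, y_block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared Pearson correlation with pairwise deletion, all pairs at once.

    Returns ``(r2, n_obs)`` of shapes (Lx, Ly).
    """
    mx = (x_block != MISSING).astype(np.float64)
    my = (y_block != MISSING).astype(np.float64)
    xz = np.where(x_block != MISSING, x_block, 0).astype(np.float64)
    yz = np.where(y_block != MISSING, y_block, 0).astype(np.float64)
    n = mx.T @ my
    sx = xz.T @ my
    sy = mx.T @ yz
    sxy = xz.T @ yz
    sxx = (xz**2).T @ my
    syy = mx.T @ (yz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx**2
        vary = n * syy - sy**2
        r2 = cov**2 / (varx * vary)
    r2 = np.where((n >= 2) & (varx > 0) & (vary > 0), np.clip(r2, 0.0, 1.0), np.nan)
    return r2, n.astype(int)


def compute_r2_pair(
    x: np.ndarray, y: np.ndarray, cfg: LDEstimatorConfig | None = None
) -> float:
    """r^2 between two dosage columns (pairwise deletion of missing).

    Returns NaN when undefined (fewer than two joint observations, or
    either locus monomorphic among the jointly observed individuals).
    Warns if the EM fails to converge; the last iterate is returned.
    """
    cfg = cfg or LDEstimatorConfig()
    x = np.asarray(x).reshape(-1, 1)
    y = np.asarray(y).reshape(-1, 1)
    if x.shape != y.shape:
        raise ValueError("dosage columns differ in length")
    if cfg.estimator == "dosage_correlation":
        r2, _ = _dosage_corr_r2(x, y)
        return float(r2[0, 0])
    counts = _genotype_pair_counts(x, y)
    r2, converged = _em_r2_flat(counts, cfg.em_tol, cfg.em_max_iter)
    if not converged[0]:
        warnings.warn("EM did not converge within em_max_iter; last iterate returned")
    return float(r2[0])


def compute_r2_matrix(
    g: GenotypeMatrix, cfg: LDEstimatorConfig | None = None
) -> LDMatrix:
    """Pairwise r^2 for all unordered locus pairs.

    Missing genotypes are handled by pairwise deletion; pairs undefined
    after deletion are NaN (absent network edges).  The diagonal is NaN.
    """
    cfg = cfg or LDEstimatorConfig()
    d = g.dosages
    p = g.n_loci
    iu, ju = np.triu_indices(p, k=1)
    if cfg.estimator == "dosage_correlation":
        r2_full, nobs = _dosage_corr_r2(d, d)
        flat = r2_full[iu, ju]
    else:
        counts = _genotype_pair_counts(d, d)
        nobs = counts.sum(axis=(0, 1)).astype(int)
        flat, _ = _em_r2_flat(counts[:, :, iu, ju], cfg.em_tol, cfg.em_max_iter)
    values = np.full((p, p), np.nan)
    values[iu, ju] = flat
    values[ju, iu] = flat
    return LDMatrix(values=values, locus_ids=g.locus_ids, n_obs=nobs)
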