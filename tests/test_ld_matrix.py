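"""SNP filtering and r^2 estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldna.core import MISSING, GenotypeMatrix
from ldna.ld_matrix import (
    LDEstimatorConfig,
    compute_r2_matrix,
    compute_r2_pair,
    filter_snps,
)


def _gm(dosages, tags=None):
    d = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(
        dosages=d,
        locus_ids=np.array([f"l{j}" for j in range(d.shape[1])], dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(d.shape[0])], dtype=object),
        rad_tags=None if tags is None else np.array(tags, dtype=object),
    )


class TestFilterSnps:
    def test_strict_maf_threshold(self):
        # MAFs 0.05, 0.10, 0.15, 0.50, 0.00 over 10 individuals; ">" is strict
        freqs = [0.05, 0.10, 0.15, 0.50, 0.0]
        cols = []
        for p in freqs:
            alt = int(round(p * 20))
            col = np.zeros(10, dtype=np.int8)
            for k in range(alt):  # spread alt alleles over individuals
                col[k % 10] += 1
            cols.append(col)
        g = _gm(np.column_stack(cols))
        kept = filter_snps(g, LDEstimatorConfig(maf_min=0.10))
        assert list(kept.locus_ids) == ["l2", "l3"]

    def test_monomorphic_always_removed(self):
        g = _gm([[0, 0], [0, 1], [0, 1], [0, 1], [0, 1]])
        kept = filter_snps(g, LDEstimatorConfig(maf_min=0.0))
        assert list(kept.locus_ids) == ["l1"]

    def test_one_snp_per_tag_keeps_highest_maf(self):
        g = _gm(
            [[0, 0], [1, 0], [1, 1], [1, 1], [0, 1]],
            tags=["t1", "t1"],
        )
        kept = filter_snps(
            g, LDEstimatorConfig(maf_min=0.0, one_snp_per_tag=True)
        )
        assert kept.n_loci == 1
        assert list(kept.locus_ids) == ["l0"]  # MAF 0.3 beats 0.3 -> tie by order

    def test_all_filtered_raises(self):
        g = _gm([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="no loci survive"):
            filter_snps(g, LDEstimatorConfig())

    def test_max_missing(self):
        col_ok = [0, 1, 1, 0, 1, 0, 1, 1]
        col_gappy = [0, 1, MISSING, MISSING, MISSING, 0, 1, 1]
        g = _gm(np.column_stack([col_ok, col_gappy]))
        kept = filter_snps(g, LDEstimatorConfig(maf_min=0.0, max_missing=0.25))
        assert list(kept.locus_ids) == ["l0"]


class TestR2Pair:
    @pytest.mark.parametrize("estimator", ["em_haplotype", "dosage_correlation"])
    def test_identical_columns_give_one(self, estimator):
        x = np.array([0, 0, 1, 1, 2, 2, 1, 0, 2])
        cfg = LDEstimatorConfig(estimator=estimator)
        assert compute_r2_pair(x, x, cfg) == pytest.approx(1.0)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, (10_000, 2)).sum(axis=1)
        y = rng.integers(0, 2, (10_000, 2)).sum(axis=1)
        assert compute_r2_pair(x, y) < 0.01

    def test_em_matches_counts_when_no_double_het(self):
        # Phased haplotype draws collapsed to dosages, double hets rejected:
        # EM must equal the direct haplotype-count r^2.
        rng = np.random.default_rng(3)
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        probs = np.array([0.4, 0.1, 0.2, 0.3])
        for _ in range(5):
            draw = rng.choice(4, size=(400, 2), p=probs)
            h1, h2 = haps[draw[:, 0]], haps[draw[:, 1]]
            keep = ~((h1[:, 0] != h2[:, 0]) & (h1[:, 1] != h2[:, 1]))
            h1, h2 = h1[keep], h2[keep]
            dos = h1 + h2
            # direct haplotype-count r^2 from the retained gametes
            hap_all = np.concatenate([h1, h2])
            pa, pb = hap_all[:, 0].mean(), hap_all[:, 1].mean()
            p11 = (hap_all[:, 0] & hap_all[:, 1]).mean()
            d = p11 - pa * pb
            expected = d**2 / (pa * (1 - pa) * pb * (1 - pb))
            got = compute_r2_pair(dos[:, 0], dos[:, 1])
            assert got == pytest.approx(min(expected, 1.0), abs=1e-6)

    def test_em_matches_likelihood_grid_oracle(self):
        # Brute-force likelihood grid over D at step 1e-4.
        counts = np.array([[10, 5, 1], [4, 12, 6], [0, 3, 9]])
        n = counts.sum()
        pa = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
        pb = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)

        def loglik(dd):
            p11 = pa * pb + dd
            p10 = pa * (1 - pb) - dd
            p01 = (1 - pa) * pb - dd
            p00 = (1 - pa) * (1 - pb) + dd
            if min(p11, p10, p01, p00) < 0:
                return -np.inf
            probs = {
                (0, 0): p00**2, (0, 1): 2 * p00 * p01, (0, 2): p01**2,
                (1, 0): 2 * p00 * p10, (1, 1): 2 * (p11 * p00 + p10 * p01),
                (1, 2): 2 * p11 * p01, (2, 0): p10**2, (2, 1): 2 * p11 * p10,
                (2, 2): p11**2,
            }
            return sum(
                counts[i, j] * np.log(max(probs[(i, j)], 1e-300))
                for i in range(3)
                for j in range(3)
            )

        grid = np.arange(-0.25, 0.25, 1e-4)
        best_d = grid[np.argmax([loglik(d) for d in grid])]
        expected = best_d**2 / (pa * (1 - pa) * pb * (1 - pb))
        dosages = np.repeat(
            np.arange(9), counts.ravel()
        )
        x, y = dosages // 3, dosages % 3
        assert compute_r2_pair(x, y) == pytest.approx(expected, abs=1e-3)

    def test_monomorphic_after_pairwise_deletion_undefined(self):
        x = np.array([0, 0, 0, 1, 1])
        y = np.array([1, 0, 1, MISSING, MISSING])
        assert np.isnan(compute_r2_pair(x, y))


class TestR2Matrix:
    def test_identical_columns_all_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1])
        g = _gm(np.column_stack([col, col, col]))
        ld = compute_r2_matrix(g)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(ld.values[off], 1.0)

    def test_matches_pairwise_recomputation(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(40, 20)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = MISSING
        g = _gm(d)
        cfg = LDEstimatorConfig()
        ld = compute_r2_matrix(g, cfg)
        for i in range(0, 20, 3):
            for j in range(i + 1, 20, 4):
                expect = compute_r2_pair(d[:, i], d[:, j], cfg)
                got = ld.values[i, j]
                if np.isnan(expect):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-9)

    def test_locus_permutation_permutes_matrix(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        g = _gm(d)
        perm = rng.permutation(8)
        ld = compute_r2_matrix(g)
        ld_p = compute_r2_matrix(g.subset_loci(perm))
        expected = ld.values[np.ix_(perm, perm)]
        assert np.allclose(ld_p.values, expected, equal_nan=True)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.sampled_from(["em_haplotype", "dosage_correlation"]),
    )
    def test_structural_invariants(self, seed, estimator):
        """Symmetry and [0,1] range hold for any genotype input."""
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(15, 6)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        ld = compute_r2_matrix(_gm(d), LDEstimatorConfig(estimator=estimator))
        defined = ~np.isnan(ld.values)
        assert np.array_equal(defined, defined.T)
        assert np.array_equal(
            ld.values[defined], ld.values.T[defined]
        )
        assert ((ld.values[defined] >= 0) & (ld.values[defined] <= 1)).all()
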