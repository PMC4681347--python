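"""Lambda scoring, the MAD outlier limit, SOC/COC typing and robustness."""

import numpy as np
import pytest

from ldna.clustering_tree import build_merge_tree
from ldna.core import LDMatrix
from ldna.lambda_outliers import (
    call_outliers,
    compute_lambda,
    lambda_limit,
    parameter_sweep,
    subsample_robustness,
)
from ldna.simdata import PlantedBlockSpec, generate_planted_ld

from conftest import brute_force_lambda, random_ld_matrix


class TestComputeLambda:
    def test_worked_example(self, worked_example_ld):
        """Medians 0.8 -> 0.5 at the merger of {a,b,c} with {d}: lambda 0.9."""
        tree = build_merge_tree(worked_example_ld)
        records = compute_lambda(tree, worked_example_ld)
        rec = next(r for r in records if r.n_loci_before == 3)
        assert rec.median_before == pytest.approx(0.8)
        assert rec.median_after == pytest.approx(0.5)
        assert rec.lam == pytest.approx(0.9)

    def test_unchanged_median_gives_zero(self):
        # two loci at 0.6 absorb a third whose cross values are also 0.6
        v = np.full((3, 3), 0.6)
        np.fill_diagonal(v, np.nan)
        ld = LDMatrix(values=v, locus_ids=np.array(list("abc"), dtype=object))
        tree = build_merge_tree(ld)
        for rec in compute_lambda(tree, ld):
            assert rec.lam == pytest.approx(0.0)

    def test_symmetric_merger_equal_lambda(self):
        # two identical 2-clusters with symmetric cross values
        v = np.full((4, 4), np.nan)
        v[0, 1] = v[1, 0] = 0.9
        v[2, 3] = v[3, 2] = 0.9
        for i in (0, 1):
            for j in (2, 3):
                v[i, j] = v[j, i] = 0.2
        ld = LDMatrix(values=v, locus_ids=np.array(list("abcd"), dtype=object))
        tree = build_merge_tree(ld)
        recs = [r for r in compute_lambda(tree, ld) if r.n_loci_before == 2]
        assert len(recs) == 2
        assert recs[0].lam == pytest.approx(recs[1].lam)

    def test_brute_force_oracle_random_instances(self):
        """Incremental lambda equals raw-matrix median recomputation on 50
        random instances of <= 15 loci."""
        rng = np.random.default_rng(99)
        for trial in range(50):
            n = int(rng.integers(3, 16))
            ld = random_ld_matrix(rng, n, tie_prob=0.2 if trial % 2 else 0.0)
            tree = build_merge_tree(ld)
            records = compute_lambda(tree, ld)
            by_cluster = {r.cluster_id: r for r in records}
            for ev in tree.event_log:
                merged = tree.nodes[ev.new_cluster_id].members.tolist()
                for cid in ev.merging_clusters:
                    mi = tree.nodes[cid].members.tolist()
                    if len(mi) < 2:
                        assert cid not in by_cluster
                        continue
                    expected = brute_force_lambda(ld, mi, merged)
                    assert by_cluster[cid].lam == pytest.approx(expected, abs=1e-12)

    def test_singletons_skipped(self, worked_example_ld):
        records = compute_lambda(build_merge_tree(worked_example_ld), worked_example_ld)
        assert all(r.n_loci_before >= 2 for r in records)


class TestLambdaLimit:
    def test_zero_mad_case(self):
        lams = [1, 1, 1, 1, 10]
        lim = lambda_limit(lams, phi=2)
        assert lim == pytest.approx(1.0)
        assert sum(l > lim for l in lams) == 1

    def test_phi_zero_gives_median(self):
        assert lambda_limit([0.2, 0.5, 0.9], 0.0) == pytest.approx(0.5)

    def test_all_equal_no_outliers(self):
        lim = lambda_limit([3.0, 3.0, 3.0], 5.0)
        assert lim == pytest.approx(3.0)
        assert not any(l > lim for l in [3.0, 3.0, 3.0])

    def test_unscaled_mad(self):
        lams = [0.0, 1.0, 2.0, 3.0, 100.0]
        # median 2, absolute deviations {2,1,0,1,98} -> MAD 1 (no 1.4826 factor)
        assert lambda_limit(lams, 1.0) == pytest.approx(3.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            lambda_limit([], 2.0)


def _nested_outlier_ld():
    """Tight inner pair inside a tight block over a weak background: the
    inner cluster and the block both get large lambda."""
    rng = np.random.default_rng(12)
    n = 20
    v = rng.uniform(0.0, 0.05, size=(n, n))
    block = slice(0, 8)
    v[block, block] = rng.uniform(0.55, 0.65, size=(8, 8))
    inner = slice(0, 4)
    v[inner, inner] = rng.uniform(0.93, 0.99, size=(4, 4))
    v = np.triu(v, 1)
    v = v + v.T
    np.fill_diagonal(v, np.nan)
    return LDMatrix(values=v, locus_ids=np.array([f"L{i}" for i in range(n)], dtype=object))


class TestCallOutliers:
    def test_nested_outliers_soc_and_coc(self):
        ld = _nested_outlier_ld()
        tree = build_merge_tree(ld)
        records = compute_lambda(tree, ld)
        rep = call_outliers(tree, records, phi=2, min_edges=3)
        assert rep.socs and rep.cocs
        soc_sets = [set(rep.members[c]) for c in rep.socs]
        for coc in rep.cocs:
            # every COC contains at least one SOC in its subtree
            assert any(s <= set(rep.members[coc]) for s in soc_sets)
        # SOC member sets pairwise disjoint
        for i, a in enumerate(soc_sets):
            for b in soc_sets[i + 1 :]:
                assert not (a & b)

    def test_edge_filter_excludes_high_lambda_cluster(self, worked_example_ld):
        tree = build_merge_tree(worked_example_ld)
        records = compute_lambda(tree, worked_example_ld)
        rep_loose = call_outliers(tree, records, phi=0, min_edges=0)
        rec = next(r for r in records if r.n_loci_before == 3)
        assert rec.cluster_id in rep_loose.outliers
        rep_strict = call_outliers(tree, records, phi=0, min_edges=rec.edge_count + 1)
        assert rec.cluster_id not in rep_strict.outliers

    def test_names_follow_id_threshold_convention(self):
        ld = _nested_outlier_ld()
        tree = build_merge_tree(ld)
        rep = call_outliers(tree, compute_lambda(tree, ld), phi=2, min_edges=3)
        for cid, name in rep.names.items():
            ident, thr = name.split("_")
            assert int(ident) == cid
            assert thr == f"{tree.nodes[cid].formation_threshold:.2f}"

    def test_empty_outlier_set_allowed(self, worked_example_ld):
        tree = build_merge_tree(worked_example_ld)
        rep = call_outliers(tree, compute_lambda(tree, worked_example_ld), phi=100, min_edges=0)
        assert rep.outliers == [] and rep.socs == [] and rep.cocs == []


class TestParameterSweep:
    def test_reference_point_zero_losses_gains(self):
        ld = _nested_outlier_ld()
        tree = build_merge_tree(ld)
        records = compute_lambda(tree, ld)
        df = parameter_sweep(tree, records, [2], [3], ref_phi=2, ref_min_edges=3)
        row = df.iloc[0]
        assert row.losses == 0 and row.gains == 0

    def test_outlier_set_monotone_in_phi_and_edges(self):
        ld = _nested_outlier_ld()
        tree = build_merge_tree(ld)
        records = compute_lambda(tree, ld)
        phis = [0, 1, 2, 4, 8]
        for me in [0, 2, 5, 10]:
            counts = [
                len(call_outliers(tree, records, phi, me).outliers) for phi in phis
            ]
            assert counts == sorted(counts, reverse=True)
        for phi in phis:
            counts = [
                len(call_outliers(tree, records, phi, me).outliers)
                for me in [0, 2, 5, 10, 20]
            ]
            assert counts == sorted(counts, reverse=True)

    def test_huge_min_edges_loses_all_socs(self):
        ld = _nested_outlier_ld()
        tree = build_merge_tree(ld)
        records = compute_lambda(tree, ld)
        df = parameter_sweep(tree, records, [2], [10_000], ref_phi=2, ref_min_edges=3)
        assert df.iloc[0].n_socs == 0
        assert df.iloc[0].losses > 0


# blocks sized like real SOCs (tens of loci) so a 50% subsample stays
# above the |E|_min viability floor
@pytest.fixture(scope="module")
def planted():
    return generate_planted_ld(
        PlantedBlockSpec(
            n_loci=200, blocks=[(30, 0.7, 0.9)] * 3, background_r2_high=0.05, seed=5
        )
    )


class TestSubsampleRobustness:

    def test_full_fraction_recovers_everything(self, planted):
        ld, _ = planted
        df = subsample_robustness(ld, 1.0, replicates=2, phi=7, min_edges=20, seed=1)
        assert df.recovered.all()

    def test_half_fraction_recovers_blocks(self, planted):
        # replicates analysed at laxer parameters than the reference, as
        # is standard for reduced data sets
        ld, _ = planted
        df = subsample_robustness(
            ld, 0.5, replicates=10, phi=3, min_edges=16, seed=1,
            ref_phi=7, ref_min_edges=20,
        )
        per_rep = df.groupby("replicate").recovered.all()
        assert per_rep.sum() >= 9

    def test_fixed_seed_is_deterministic(self, planted):
        ld, _ = planted
        a = subsample_robustness(ld, 0.5, replicates=3, phi=7, min_edges=10, seed=2)
        b = subsample_robustness(ld, 0.5, replicates=3, phi=7, min_edges=10, seed=2)
        assert a.equals(b)
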