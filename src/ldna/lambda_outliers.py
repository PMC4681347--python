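"""Merger scoring with lambda, MAD outlier calling, and SOC/COC typing.

For every merge event and every participating cluster i with at least two
loci, lambda = (median_before - median_after) * n_ib, where median_before
is the median of all intracluster r^2 of cluster i before the merger,
median_after the median of intracluster r^2 of the merged cluster over
pairs involving at least one locus of i, and n_ib the pre-merger size of
cluster i.  High lambda marks mergers of large and/or tightly associated
clusters.  A cluster is an outlier when lambda exceeds
median(lambda) + phi * MAD (MAD unscaled) and it carries at least
|E|_min edges at its merge threshold.  Outliers with no outlier nested
below them are single-outlier clusters (SOCs); the rest are compound
outlier clusters (COCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ldna.core import GenotypeMatrix, LDMatrix
from ldna.clustering_tree import MergeTree, build_merge_tree


@dataclass
class LambdaRecord:
    cluster_id: int
    n_loci_before: int
    median_before: float
    median_after: float
    lam: float
    merge_threshold: float
    edge_count: int
    formation_threshold: float


@dataclass
class OutlierReport:
    lambda_records: list[LambdaRecord]
    lambda_lim: float
    phi: float
    min_edges: int
    outliers: list[int]
    socs: list[int]
    cocs: list[int]
    names: dict[int, str]
    members: dict[int, list] = field(default_factory=dict)

    def soc_member_sets(self) -> dict[str, frozenset]:
        return {self.names[c]: frozenset(self.members[c]) for c in self.socs}


def _median(vals: np.ndarray) -> float:
    vals = vals[~np.isnan(vals)]
    return float(np.median(vals)) if vals.size else np.nan


def compute_lambda(tree: MergeTree, ld: LDMatrix | None = None) -> list[LambdaRecord]:
    """Score every merging cluster of >= 2 loci with lambda.

    Medians are taken over *all* defined intracluster pairs, not only the
    pairs above the current threshold.  Singleton participants carry no
    intracluster pair and are skipped.  One record per scored cluster (a
    non-root cluster merges exactly once).
    """
    ld = ld or tree.ld
    if ld is None:
        raise ValueError("no LD matrix attached to the tree or supplied")
    v = ld.values
    records: list[LambdaRecord] = []
    # Replay the event log, carrying each live cluster's defined
    # intracluster r^2 values as a list of chunks.  Every pairwise cross
    # block between merging clusters is computed exactly once and reused
    # both for the participants' post-merger medians and as the merged
    # cluster's new within-chunks, so total work is proportional to the
    # number of defined pairs.
    chunks: dict[int, list[np.ndarray]] = {i: [] for i in range(tree.n_loci)}
    for ev in tree.event_log:
        parts = ev.merging_clusters
        cross: dict[tuple[int, int], np.ndarray] = {}
        for a_i, ca in enumerate(parts):
            for cb in parts[a_i + 1 :]:
                block = v[np.ix_(tree.nodes[ca].members, tree.nodes[cb].members)].ravel()
                cross[(ca, cb)] = block[~np.isnan(block)]
        for cid in parts:
            node = tree.nodes[cid]
            mi = node.members
            if len(mi) < 2:
                continue
            within_chunks = chunks[cid]
            within = (
                np.concatenate(within_chunks) if within_chunks else np.empty(0)
            )
            chunks[cid] = [within]  # consolidate for the merged cluster
            cross_i = [
                blk
                for (ca, cb), blk in cross.items()
                if cid in (ca, cb)
            ]
            mb = _median(within)
            ma = _median(np.concatenate([within, *cross_i]) if cross_i else within)
            if np.isnan(mb) or np.isnan(ma):
                continue
            lam = (mb - ma) * len(mi)
            edge_count = int(np.sum(within >= ev.threshold))
            records.append(
                LambdaRecord(
                    cluster_id=cid,
                    n_loci_before=len(mi),
                    median_before=mb,
                    median_after=ma,
                    lam=lam,
                    merge_threshold=ev.threshold,
                    edge_count=edge_count,
                    formation_threshold=node.formation_threshold,
                )
            )
        merged_chunks: list[np.ndarray] = []
        for cid in parts:
            merged_chunks.extend(chunks.pop(cid, []))
        merged_chunks.extend(cross.values())
        chunks[ev.new_cluster_id] = merged_chunks
    return records


def lambda_limit(lambdas, phi: float) -> float:
    """median(lambda) + phi * unscaled MAD(lambda).

    The MAD carries no consistency scaling factor: it is the plain median
    of absolute deviations from the median.
    """
    lambdas = np.asarray(list(lambdas), dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda list")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    med = np.median(lambdas)
    mad = np.median(np.abs(lambdas - med))
    return float(med + phi * mad)


def call_outliers(
    tree: MergeTree,
    records: list[LambdaRecord],
    phi: float = 7.0,
    min_edges: int = 20,
) -> OutlierReport:
    """Call outlier clusters and partition them into SOCs and COCs.

    Outliers satisfy lambda strictly above the limit and edge count at
    their merge threshold >= ``min_edges``.  A SOC has no other outlier in
    its subtree; names follow the "id_threshold" convention using the
    highest threshold at which the cluster exists (its formation
    threshold), printed with two decimals.
    """
    lam_lim = lambda_limit([r.lam for r in records], phi) if records else np.inf
    by_id = {r.cluster_id: r for r in records}
    outliers = [
        r.cluster_id
        for r in records
        if r.lam > lam_lim and r.edge_count >= min_edges
    ]
    outlier_set = set(outliers)
    socs, cocs = [], []
    for cid in outliers:
        nested = any(d in outlier_set for d in tree.descendants(cid))
        (cocs if nested else socs).append(cid)
    names = {
        cid: f"{cid}_{by_id[cid].formation_threshold:.2f}" for cid in outliers
    }
    members = {
        cid: [tree.locus_ids[i] for i in tree.nodes[cid].members] for cid in outliers
    }
    return OutlierReport(
        lambda_records=records,
        lambda_lim=float(lam_lim) if records else np.nan,
        phi=phi,
        min_edges=min_edges,
        outliers=sorted(outliers),
        socs=sorted(socs),
        cocs=sorted(cocs),
        names=names,
        members=members,
    )


def parameter_sweep(
    tree: MergeTree,
    records: list[LambdaRecord],
    phis,
    min_edges_list,
    ref_phi: float = 7.0,
    ref_min_edges: int = 20,
) -> pd.DataFrame:
    """SOC losses and gains across a phi x |E|_min grid.

    The SOC set at ``(ref_phi, ref_min_edges)`` is the reference; at every
    grid point, SOCs are compared to it by set identity of member loci.
    ``losses`` counts reference SOCs absent from the grid point, ``gains``
    counts grid-point SOCs absent from the reference.  ``n_outliers`` is
    included so monotonicity in phi and |E|_min can be checked directly.
    """
    phis = list(phis)
    min_edges_list = list(min_edges_list)
    if not phis or not min_edges_list:
        raise ValueError("empty parameter grid")
    ref = call_outliers(tree, records, ref_phi, ref_min_edges)
    ref_sets = set(frozenset(m) for m in (ref.members[c] for c in ref.socs))
    rows = []
    for phi in phis:
        for me in min_edges_list:
            rep = call_outliers(tree, records, phi, me)
            soc_sets = set(frozenset(rep.members[c]) for c in rep.socs)
            rows.append(
                {
                    "phi": phi,
                    "min_edges": me,
                    "n_outliers": len(rep.outliers),
                    "n_socs": len(rep.socs),
                    "losses": len(ref_sets - soc_sets),
                    "gains": len(soc_sets - ref_sets),
                }
            )
    return pd.DataFrame(rows)


def subsample_robustness(
    data: GenotypeMatrix | LDMatrix,
    fraction: float,
    replicates: int,
    phi: float,
    min_edges: int,
    seed: int,
    cfg=None,
    ref_phi: float | None = None,
    ref_min_edges: int | None = None,
) -> pd.DataFrame:
    """SOC recovery under random SNP subsampling without replacement.

    Runs the full analysis on the complete data (at ``ref_phi`` /
    ``ref_min_edges``, defaulting to the replicate parameters) to obtain
    reference SOCs, then on ``replicates`` random locus subsets of the
    given fraction.  A reference SOC is recovered in a replicate when some
    subsample SOC corresponds to it: the majority of the subsample SOC's
    members belong to the reference SOC, and they cover at least half of
    the reference SOC's loci present in the subsample.  (Separate,
    typically laxer, replicate parameters mirror how reduced data sets are
    analysed in practice.)  Returns one row per (replicate, reference SOC).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    from ldna.pipeline import analyze_ld  # local import to avoid cycle
    from ldna.ld_matrix import compute_r2_matrix, filter_snps, LDEstimatorConfig

    cfg = cfg or LDEstimatorConfig()

    def run(d, use_phi, use_min_edges) -> OutlierReport:
        if isinstance(d, GenotypeMatrix):
            ld = compute_r2_matrix(filter_snps(d, cfg), cfg)
        else:
            ld = d
        _, _, rep = analyze_ld(ld, phi=use_phi, min_edges=use_min_edges)
        return rep

    ref = run(
        data,
        phi if ref_phi is None else ref_phi,
        min_edges if ref_min_edges is None else ref_min_edges,
    )
    ref_sets = {ref.names[c]: frozenset(ref.members[c]) for c in ref.socs}
    n = data.n_loci
    k = max(2, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(replicates):
        idx = np.sort(rng.choice(n, size=k, replace=False))
        sub = data.subset_loci(idx) if isinstance(data, GenotypeMatrix) else data.subset(idx)
        kept = frozenset(
            sub.locus_ids if isinstance(sub, GenotypeMatrix) else sub.locus_ids
        )
        try:
            rep = run(sub, phi, min_edges)
            sub_sets = [frozenset(rep.members[c]) for c in rep.socs]
        except ValueError:
            sub_sets = []
        for name, ref_set in ref_sets.items():
            present = ref_set & kept
            recovered = any(
                len(s & ref_set) > 0.5 * len(s)
                and len(s & ref_set) >= 0.5 * len(present)
                for s in sub_sets
                if present
            )
            rows.append(
                {"replicate": r, "reference_soc": name, "recovered": recovered}
            )
    return pd.DataFrame(rows)
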