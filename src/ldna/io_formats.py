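"""Readers and writers: VCF and plain genotype tables in, LD matrices,
edge lists, trees and cluster-membership tables out.

The plain genotype-table dialect is a whitespace- or comma-delimited table
with a header row of locus ids, sample ids in the first column, and cells
in {0, 1, 2, NA} (ALT-allele dosage).  LD matrices round-trip as square
TSVs with locus ids on both margins and empty cells for undefined pairs.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from ldna.core import MISSING, GenotypeMatrix, LDMatrix
from ldna.clustering_tree import MergeTree
from ldna.lambda_outliers import LambdaRecord, OutlierReport


def read_vcf(path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Genotype matrix from a VCF (GT fields; dosage = ALT-allele count).

    Phase separators are ignored (0|1 and 1|0 both give dosage 1); missing
    genotypes become :data:`MISSING`.  Multiallelic or non-SNP records are
    dropped when ``biallelic_only`` and rejected otherwise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples, dtype=object)
    columns, locus_ids, positions = [], [], []
    for v in vcf:
        is_snp = len(v.ALT) == 1 and len(v.REF) == 1 and len(v.ALT[0]) == 1
        if not is_snp:
            if biallelic_only:
                continue
            raise ValueError(
                f"non-biallelic-SNP record at {v.CHROM}:{v.POS} with biallelic_only=False"
            )
        dosage = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            dosage[i] = sum(alleles) if len(alleles) == 2 else MISSING
        columns.append(dosage)
        lid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        locus_ids.append(lid)
        positions.append((v.CHROM, v.POS))
    if not columns:
        raise ValueError(f"no biallelic SNPs retained from {path}")
    return GenotypeMatrix(
        dosages=np.column_stack(columns),
        locus_ids=np.array(locus_ids, dtype=object),
        sample_ids=sample_ids,
        locus_positions=positions,
    )


def read_genotype_table(path) -> GenotypeMatrix:
    """Genotype matrix from the plain-text table dialect (see module doc)."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path} is empty")
    sep = "," if "," in lines[0] else None  # None = any whitespace
    header = [c.strip() for c in lines[0].split(sep)]
    # Header may or may not carry a leading label for the sample-id column.
    first_row = [c.strip() for c in lines[1].split(sep)] if len(lines) > 1 else []
    locus_ids = header if len(header) == len(first_row) - 1 else header[1:]
    n_loci = len(locus_ids)
    sample_ids, rows = [], []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(sep)]
        if len(cells) != n_loci + 1:
            raise ValueError(
                f"row {cells[0]!r} has {len(cells) - 1} genotype cells, expected {n_loci}"
            )
        sample_ids.append(cells[0])
        row = np.empty(n_loci, dtype=np.int8)
        for j, c in enumerate(cells[1:]):
            if c == "NA":
                row[j] = MISSING
            elif c in ("0", "1", "2"):
                row[j] = int(c)
            else:
                raise ValueError(
                    f"invalid genotype {c!r} at row {cells[0]!r}, column {locus_ids[j]!r}"
                )
        rows.append(row)
    return GenotypeMatrix(
        dosages=np.array(rows),
        locus_ids=np.array(locus_ids, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
    )


def write_genotype_table(g: GenotypeMatrix, path) -> None:
    """Write the plain-text genotype table (TSV, NA for missing)."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(map(str, g.locus_ids)) + "\n")
        for i, sid in enumerate(g.sample_ids):
            cells = [
                "NA" if d == MISSING else str(int(d)) for d in g.dosages[i]
            ]
            fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")


def read_ld_tsv(path) -> LDMatrix:
    """Square LD matrix from TSV (locus ids on both margins, blank = undefined)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("LD matrix row and column locus ids differ")
    return LDMatrix(values=df.to_numpy(dtype=float), locus_ids=np.array(df.columns, dtype=object))


def write_ld_tsv(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.values, index=ld.locus_ids, columns=ld.locus_ids)
    df.to_csv(path, sep="\t", na_rep="")


def write_edge_list(ld: LDMatrix, path) -> None:
    """TSV of defined pairs: locus_a, locus_b, r2."""
    ii, jj, ww = ld.edges()
    with open(path, "w") as fh:
        fh.write("locus_a\tlocus_b\tr2\n")
        for i, j, w in zip(ii, jj, ww):
            fh.write(f"{ld.locus_ids[i]}\t{ld.locus_ids[j]}\t{w:.10g}\n")


def write_cluster_membership(report: OutlierReport, path) -> None:
    """One row per (locus, outlier cluster), SOCs and COCs both listed.

    Loci inside a SOC nested in a COC appear once under each.  Rows are
    ordered by cluster name then locus id.
    """
    soc_set = set(report.socs)
    rows = []
    for cid in report.outliers:
        ctype = "SOC" if cid in soc_set else "COC"
        rec = next(r for r in report.lambda_records if r.cluster_id == cid)
        for locus in report.members[cid]:
            rows.append((report.names[cid], str(locus), ctype, rec.merge_threshold))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("locus_id\tcluster_name\tcluster_type\tmerge_threshold\n")
        for name, locus, ctype, thr in rows:
            fh.write(f"{locus}\t{name}\t{ctype}\t{thr:.10g}\n")


def write_lambda_table(records: list[LambdaRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tn_loci\tmedian_before\tmedian_after\tlambda\t"
            "merge_threshold\tedge_count\tformation_threshold\n"
        )
        for r in records:
            fh.write(
                f"{r.cluster_id}\t{r.n_loci_before}\t{r.median_before:.10g}\t"
                f"{r.median_after:.10g}\t{r.lam:.10g}\t{r.merge_threshold:.10g}\t"
                f"{r.edge_count}\t{r.formation_threshold:.10g}\n"
            )


def write_outlier_summary(report: OutlierReport, path, header_lines=()) -> None:
    """One row per outlier cluster: name, type, lambda, |E|, size, threshold."""
    by_id = {r.cluster_id: r for r in report.lambda_records}
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# phi={report.phi:g} min_edges={report.min_edges} lambda_lim={report.lambda_lim:.10g}\n")
        fh.write("name\ttype\tlambda\tedges\tn_loci\tmerge_threshold\n")
        soc_set = set(report.socs)
        for cid in report.outliers:
            r = by_id[cid]
            ctype = "SOC" if cid in soc_set else "COC"
            fh.write(
                f"{report.names[cid]}\t{ctype}\t{r.lam:.10g}\t{r.edge_count}\t"
                f"{r.n_loci_before}\t{r.merge_threshold:.10g}\n"
            )


_NEWICK_UNSAFE = re.compile(r"[\s():;,\[\]']")


def _safe_label(label) -> str:
    return _NEWICK_UNSAFE.sub("_", str(label))


def export_tree(tree: MergeTree, path, format: str = "newick") -> None:
    """Serialize the merger tree.

    ``newick``: leaves are locus ids, internal node labels are cluster
    ids, and each branch length is the difference between the cluster's
    formation threshold and its merge threshold (the LD-threshold span
    over which it exists), preserving the threshold-axis drawing of the
    tree.  ``tabular``: one row per merge event.
    """
    if format == "newick":
        from Bio import Phylo
        from Bio.Phylo.BaseTree import Clade, Tree

        def clade(cid: int) -> Clade:
            node = tree.nodes[cid]
            length = None
            if node.merge_threshold is not None:
                length = node.formation_threshold - node.merge_threshold
            if not node.children:
                return Clade(
                    branch_length=length, name=_safe_label(tree.locus_ids[cid])
                )
            return Clade(
                branch_length=length,
                name=str(cid),
                clades=[clade(c) for c in node.children],
            )

        Phylo.write(Tree(root=clade(tree.root_id), rooted=True), str(path), "newick")
    elif format == "tabular":
        with open(path, "w") as fh:
            fh.write(
                "threshold\tnew_cluster_id\tn_members\tmerging_clusters\ttriggering_edges\n"
            )
            for ev in tree.event_log:
                edges = ";".join(
                    f"{tree.locus_ids[a]}-{tree.locus_ids[b]}"
                    for a, b in ev.triggering_edges
                )
                fh.write(
                    f"{ev.threshold:.10g}\t{ev.new_cluster_id}\t"
                    f"{len(tree.nodes[ev.new_cluster_id].members)}\t"
                    f"{','.join(map(str, ev.merging_clusters))}\t{edges}\n"
                )
    else:
        raise ValueError(f"unknown tree format {format!r}")
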