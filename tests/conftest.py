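"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from ldna.core import GenotypeMatrix, LDMatrix


def random_ld_matrix(rng: np.random.Generator, n: int, tie_prob: float = 0.0) -> LDMatrix:
    """Random symmetric r^2 matrix; optional exact ties via value rounding."""
    vals = rng.uniform(0, 1, size=(n, n))
    if tie_prob > 0:
        mask = rng.random((n, n)) < tie_prob
        vals = np.where(mask, np.round(vals, 1), vals)
    vals = np.triu(vals, k=1)
    vals = vals + vals.T
    np.fill_diagonal(vals, np.nan)
    ids = np.array([f"L{i}" for i in range(n)], dtype=object)
    return LDMatrix(values=vals, locus_ids=ids)


def graph_components_at(ld: LDMatrix, t: float) -> set[frozenset[int]]:
    """Oracle: connected components of the graph with edges r^2 >= t."""
    g = nx.Graph()
    g.add_nodes_from(range(ld.n_loci))
    ii, jj, ww = ld.edges()
    for i, j, w in zip(ii, jj, ww):
        if w >= t:
            g.add_edge(int(i), int(j))
    return {frozenset(c) for c in nx.connected_components(g)}


def naive_single_linkage(ld: LDMatrix) -> list[tuple[float, set[frozenset[int]]]]:
    """Oracle: partition after processing each distinct weight, descending.

    Returns (threshold, partition) per distinct edge weight plus the final
    all-in-one partition at threshold 0.
    """
    _, _, ww = ld.edges()
    out = []
    for w in sorted(set(ww.tolist()), reverse=True):
        out.append((w, graph_components_at(ld, w)))
    out.append((0.0, {frozenset(range(ld.n_loci))}))
    return out


def brute_force_lambda(ld: LDMatrix, members_i, members_merged) -> float:
    """Oracle: direct median recomputation from the raw LD matrix."""
    mi = sorted(members_i)
    mm = sorted(members_merged)
    within = [
        ld.values[a, b]
        for k, a in enumerate(mi)
        for b in mi[k + 1 :]
        if not np.isnan(ld.values[a, b])
    ]
    involving = list(within)
    for a in mi:
        for b in mm:
            if b not in set(mi) and not np.isnan(ld.values[a, b]):
                involving.append(ld.values[a, b])
    return (float(np.median(within)) - float(np.median(involving))) * len(mi)


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """5 individuals x 4 loci with one missing call."""
    d = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [2, 0, 2, 1],
            [0, 1, 2, -1],
            [1, 2, 2, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        dosages=d,
        locus_ids=np.array(["a", "b", "c", "d"], dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(5)], dtype=object),
    )


@pytest.fixture
def worked_example_ld() -> LDMatrix:
    """Cluster {a,b,c} (r^2 0.9/0.8/0.7) plus locus d (cross 0.3/0.2/0.1)."""
    v = np.full((4, 4), np.nan)
    pairs = {(0, 1): 0.9, (0, 2): 0.8, (1, 2): 0.7, (0, 3): 0.3, (1, 3): 0.2, (2, 3): 0.1}
    for (i, j), w in pairs.items():
        v[i, j] = v[j, i] = w
    return LDMatrix(values=v, locus_ids=np.array(list("abcd"), dtype=object))
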