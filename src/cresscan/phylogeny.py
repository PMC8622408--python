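"""Distance-based phylogenetics: neighbor-joining, bootstrap, windows.

A desk-scale stand-in for full maximum-likelihood tree inference: the
claims made at this level are coarse-topological (which genomes form
sibling pairs), which distance methods reproduce. Distances derive from
pairwise alignments as (100 - %identity)/100 or as p-distances of an
alignment. Trees are carried as :class:`dendropy.Tree` objects and
serialize to Newick; bootstrap supports (percent of replicates
containing each bipartition) become internal-node labels.

Negative NJ branch lengths are clamped to zero with the deficit moved
to the sibling edge, preserving the joined pair's path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genome_io import CircularGenome
from .identity import AlignScoring, IdentityMatrix, global_align, \
    pairwise_identity


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or v.min() < 0:
            raise ValueError("distances must be symmetric, non-negative, "
                             "zero on the diagonal")
        self.values = v

    @classmethod
    def from_identity(cls, m: IdentityMatrix) -> "DistanceMatrix":
        v = (100.0 - m.values) / 100.0
        np.fill_diagonal(v, 0.0)
        return cls(list(m.labels), v)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; trifurcation at the seed node).

    Deterministic: ties in the Q criterion resolve to the lowest index
    pair. Negative branch lengths are clamped to zero and the deficit
    shifted to the sibling edge.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    tns = dendropy.TaxonNamespace([str(x) for x in dm.labels])
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(str(lab)))
        nodes.append(nd)
    D = dm.values.astype(float).copy()
    active = list(range(n0))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break
        flat = np.argmin(q)
        ai, aj = np.unravel_index(flat, q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node
        newrow = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            newrow[ak] = max(0.0, 0.5 * (D[i, ak] + D[j, ak] - dij))
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three around the seed node (three-point formulas)
    i, j, k = active
    root = dendropy.Node()
    lens = {
        i: 0.5 * (D[i, j] + D[i, k] - D[j, k]),
        j: 0.5 * (D[i, j] + D[j, k] - D[i, k]),
        k: 0.5 * (D[i, k] + D[j, k] - D[i, j]),
    }
    for a in (i, j, k):
        root.add_child(nodes[a])
        nodes[a].edge.length = max(0.0, lens[a])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_path_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    return pdm.patristic_distance(tns.get_taxon(a), tns.get_taxon(b))


def leaf_bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial splits as canonical frozensets of leaf labels."""
    labels = {t.label for t in tree.taxon_namespace}
    anchor = min(labels)
    splits = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(below) <= 1 or len(below) >= len(labels) - 1:
            continue
        side = below if anchor not in below else frozenset(labels - below)
        splits.add(side)
    return splits


def _p_distance_matrix(labels: Sequence[str], arr: np.ndarray
                       ) -> DistanceMatrix:
    n = len(labels)
    gap = arr == "-"
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            tot = int(ok.sum())
            d = float((arr[i, ok] != arr[j, ok]).mean()) if tot else 0.0
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(list(labels), vals)


def bootstrap_support(seqs: Mapping[str, str], replicates: int = 100,
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree from aligned sequences with bootstrap supports.

    Columns are resampled with replacement; each replicate's NJ tree is
    scored for the base tree's bipartitions; supports (percent of
    replicates, 0-100) are written to internal-node labels.
    Deterministic for a given seed; ``replicates=0`` returns the tree
    without supports.
    """
    labels = list(seqs)
    lens = {len(s) for s in seqs.values()}
    if len(lens) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    ncol = lens.pop()
    if ncol < 1:
        raise ValueError("alignment must have >= 1 column")
    arr = np.array([list(seqs[lab]) for lab in labels])
    base = nj_tree(_p_distance_matrix(labels, arr))
    if replicates <= 0:
        return base
    rng = np.random.default_rng(seed)
    counts: dict = {}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_tree(_p_distance_matrix(labels, arr[:, cols]))
        for split in leaf_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    labels_set = {t.label for t in base.taxon_namespace}
    anchor = min(labels_set)
    for nd in base.preorder_node_iter():
        if nd is base.seed_node or nd.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(below) <= 1 or len(below) >= len(labels_set) - 1:
            continue
        side = below if anchor not in below else frozenset(labels_set - below)
        nd.label = f"{100.0 * counts.get(side, 0) / replicates:.0f}"
    return base


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick",
                          suppress_rooting=True).strip() + "\n"


def sliding_window_identity(query: CircularGenome,
                            refs: Mapping[str, CircularGenome],
                            window: int = 300, step: int = 100,
                            scoring: Optional[AlignScoring] = None
                            ) -> pd.DataFrame:
    """Per-window % identity of the query against each reference.

    Genomes must be rotated to the ori so coordinates are comparable;
    windows wrap the circular origin. A lightweight visual screen for
    mosaic (recombinant) genomes; rows are 1-based window starts.
    """
    if window < 50:
        warnings.warn("windows under 50 nt give noisy identity profiles")
    L = len(query)
    if window > L:
        raise ValueError("window exceeds the query genome length")

    def circ(seq: str, start0: int, n: int) -> str:
        d = seq + seq
        return d[start0 % len(seq):start0 % len(seq) + n]

    starts = list(range(0, L, step))
    data: dict[str, list[float]] = {lab: [] for lab in refs}
    for p in starts:
        q = circ(query.seq, p, window)
        for lab, ref in refs.items():
            rwin = circ(ref.seq, p, min(window, len(ref)))
            aln = global_align(q, rwin, scoring)
            data[lab].append(pairwise_identity(aln))
    return pd.DataFrame(data, index=pd.Index([p + 1 for p in starts],
                                             name="window_start"))
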