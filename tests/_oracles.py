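"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by direct enumeration (and via
Biopython's own translator) so they share no code path with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from cresscan.genome_io import ANTISENSE, VIRION_SENSE, revcomp
from cresscan.motifs import scan_rep_motifs


def oracle_nona_hits(seq: str, consensus: str, max_mismatch: int,
                     circular: bool = True):
    """All motif windows on both strands by direct modular indexing."""
    L = len(seq)
    out = []
    for strand, s in ((VIRION_SENSE, seq), (ANTISENSE, revcomp(seq))):
        n_win = L if circular else L - 8
        for i in range(max(0, n_win)):
            win = "".join(s[(i + k) % L] for k in range(9))
            mm = sum(1 for c, g in zip(consensus, win)
                     if c != "N" and c != g)
            if mm <= max_mismatch:
                out.append((strand, i + 1, win, mm))
    return sorted(out)


def _policy_pick(codons, start_codons, eligible):
    order = ([c for c in ("ATG",) if c in start_codons]
             + [c for c in start_codons if c != "ATG"])
    for pref in order:
        for ci in eligible:
            if codons[ci] == pref:
                return ci
    return None


def oracle_linear_orfs(seq: str, table_id: int, start_codons, min_aa: int):
    """Six-frame ORF scan of a linear sequence via direct codon walks.

    Returns a set of (strand, start_nt, end_nt, init_codon, protein)
    tuples using virion-sense 1-based coordinates (antisense descending).
    """
    L = len(seq)
    out = set()
    for strand, s in ((VIRION_SENSE, seq), (ANTISENSE, revcomp(seq))):
        for f in range(3):
            codons = [s[i:i + 3] for i in range(f, L - 2, 3)]
            stops = [ci for ci, c in enumerate(codons)
                     if Seq(c).translate(table=table_id) == "*"]
            prev = -1
            for stop_ci in stops:
                eligible = [ci for ci in range(prev + 1, stop_ci)
                            if codons[ci] in start_codons]
                chosen = _policy_pick(codons, start_codons, eligible)
                prev = stop_ci
                if chosen is None:
                    continue
                aa_len = stop_ci - chosen
                if aa_len < min_aa:
                    continue
                cds = "".join(codons[chosen:stop_ci])
                prot = str(Seq(cds).translate(table=table_id))
                prot = "M" + prot[1:]
                i0 = f + 3 * chosen
                i1 = f + 3 * stop_ci + 2
                if strand == VIRION_SENSE:
                    start_nt, end_nt = i0 + 1, i1 + 1
                else:
                    start_nt, end_nt = L - i0, L - i1
                out.add((strand, start_nt, end_nt, codons[chosen], prot))
    return out


def oracle_spliced_rep(seq: str, table_id: int, start_codons, min_aa: int,
                       max_intron: int, min_intron: int = 4,
                       patterns=None):
    """Direct excision search for the best intron-interrupted antisense ORF.

    Mirrors the contract of find_spliced_rep: start codon wholly
    upstream of the donor, stop at/after the junction, candidate ranked
    by (motif score, aa length, -intron length, -start index).
    """
    C = revcomp(seq)
    L = len(C)
    best = None
    for d in range(L - 1):
        if C[d:d + 2] != "GT":
            continue
        for a in range(d + min_intron - 1, min(L, d + max_intron)):
            if C[a - 1:a + 1] != "AG":
                continue
            ilen = a - d + 1
            sp = C[:d] + C[a + 1:]
            for f in range(3):
                codons = [sp[i:i + 3] for i in range(f, len(sp) - 2, 3)]
                stops = [ci for ci, c in enumerate(codons)
                         if Seq(c).translate(table=table_id) == "*"]
                prev = -1
                for stop_ci in stops:
                    stop_idx = f + 3 * stop_ci
                    eligible = [ci for ci in range(prev + 1, stop_ci)
                                if codons[ci] in start_codons
                                and f + 3 * ci <= d - 3]
                    chosen = _policy_pick(codons, start_codons, eligible)
                    prev = stop_ci
                    if chosen is None:
                        continue
                    s_idx = f + 3 * chosen
                    r = (d - s_idx) % 3
                    need = d - r + (3 if r else 0)
                    if stop_idx < need:
                        continue  # does not cross the junction
                    aa_len = stop_ci - chosen
                    if aa_len < min_aa:
                        continue
                    cds = "".join(codons[chosen:stop_ci])
                    prot = "M" + str(Seq(cds).translate(
                        table=table_id))[1:]
                    score = scan_rep_motifs(prot, patterns).score
                    key = (score, aa_len, -ilen, -s_idx)
                    if best is None or key > best[0]:
                        best = (key, {
                            "intron": (L - d, L - a),
                            "protein": prot,
                            "init_codon": sp[s_idx:s_idx + 3],
                        })
    return best


def oracle_components(labels, values, threshold):
    """Single-linkage clusters via networkx connected components."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if values[i][j] >= threshold:
                g.add_edge(labels[i], labels[j])
    return {frozenset(c) for c in nx.connected_components(g)}


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary tree by sequential merges.

    Returns (labels, distance matrix, true bipartitions as canonical
    frozensets of labels). All branch lengths are >= 0.1 so the tree
    metric determines the topology uniquely.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    # each subtree: dict leaf -> distance to subtree root
    subtrees = [{lab: 0.0} for lab in labels]
    dist = {}
    clades = []
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        ba, bb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for la, da in a.items():
            for lb, db in b.items():
                dist[frozenset((la, lb))] = da + ba + db + bb
        merged = {la: da + ba for la, da in a.items()}
        merged.update({lb: db + bb for lb, db in b.items()})
        clades.append(frozenset(merged))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(merged)
    a, b = subtrees
    bridge = rng.uniform(0.1, 1.0)
    for la, da in a.items():
        for lb, db in b.items():
            dist[frozenset((la, lb))] = da + db + bridge
    clades.append(frozenset(a))
    mat = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            mat[i, j] = mat[j, i] = dist[frozenset((labels[i], labels[j]))]
    anchor = min(labels)
    allset = set(labels)
    splits = set()
    for c in clades:
        if 1 < len(c) < n_leaves - 1:
            side = c if anchor not in c else frozenset(allset - c)
            splits.add(side)
    return labels, mat, splits
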