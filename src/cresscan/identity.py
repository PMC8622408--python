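"""Pairwise global alignment, % identity matrices and ICTV demarcation.

Identities are computed from exact global (Needleman-Wunsch) affine-gap
alignments: nucleotide scoring match +5 / mismatch -4, gap open -10,
extend -0.5 (N against anything is a mismatch); amino acid scoring
BLOSUM62 with the same gap penalties. The default "SDT-like" identity
denominator counts every alignment column except those gapped in both
sequences and terminal-gap columns; an alternative mode excludes all
gap columns.

ICTV demarcation: genomes sharing < 80 % genome-wide pairwise nt
identity belong to distinct species (single-linkage clustering at the
threshold); > 55 % identity with known cycloviruses supports genus
membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from Bio.Align import PairwiseAligner, substitution_matrices

NT_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class AlignScoring:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    aa_matrix: str = "BLOSUM62"


def _nt_matrix(scoring: AlignScoring):
    alph = "ACGTN"
    m = substitution_matrices.Array(alph, dims=2)
    for a in alph:
        for b in alph:
            m[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    return m


def _is_nt(seq: str) -> bool:
    return set(seq) <= NT_ALPHABET


def make_aligner(level: str, scoring: Optional[AlignScoring] = None
                 ) -> PairwiseAligner:
    scoring = scoring or AlignScoring()
    al = PairwiseAligner()
    al.mode = "global"
    if level == "nt":
        al.substitution_matrix = _nt_matrix(scoring)
    else:
        al.substitution_matrix = substitution_matrices.load(scoring.aa_matrix)
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def global_align(a: str, b: str,
                 scoring: Optional[AlignScoring] = None) -> tuple[str, str]:
    """Optimal global alignment; returns the two gapped strings.

    The alphabet class (nt vs aa) is inferred; mixing classes is an
    error. Tie-breaking among co-optimal alignments is deterministic
    (the aligner's first reported optimum).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a_nt, b_nt = _is_nt(a), _is_nt(b)
    if a_nt != b_nt:
        raise ValueError("cannot align nucleotide against amino acid sequence")
    al = make_aligner("nt" if a_nt else "aa", scoring)
    aln = al.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(aln: tuple[str, str], mode: str = "sdt",
                      n_as_mismatch: Optional[bool] = None) -> float:
    """Percent identity of an alignment.

    mode="sdt" (default): denominator = all columns except dual-gap and
    terminal-gap columns; gap-vs-residue internal columns count as
    non-identical. mode="ungapped": all gap columns are excluded from
    the denominator. N never matches for nucleotide alignments.
    """
    s1, s2 = aln
    if len(s1) != len(s2) or not s1:
        raise ValueError("alignment rows must be equal nonzero length")
    if n_as_mismatch is None:
        n_as_mismatch = _is_nt(s1.replace("-", "")) and _is_nt(s2.replace("-", ""))
    n = len(s1)

    def lead(s: str) -> int:
        return n - len(s.lstrip("-"))

    def trail(s: str) -> int:
        return n - len(s.rstrip("-"))

    lo = max(lead(s1), lead(s2))
    hi = n - max(trail(s1), trail(s2))
    ident = denom = 0
    for i in range(lo, hi):
        c1, c2 = s1[i], s2[i]
        if c1 == "-" and c2 == "-":
            continue
        if mode == "ungapped" and ("-" in (c1, c2)):
            continue
        denom += 1
        if c1 == c2 and c1 != "-" and not (n_as_mismatch and c1 == "N"):
            ident += 1
    if denom == 0:
        return 0.0
    return 100.0 * ident / denom


@dataclass
class IdentityMatrix:
    """Symmetric % identity matrix with labels.

    level is one of {"genome-nt", "rep-aa", "cp-aa"} (or any free-form
    tag for ad-hoc matrices).
    """

    labels: list
    values: np.ndarray
    level: str = "genome-nt"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.3f")

    @classmethod
    def from_tsv(cls, path: Union[str, Path],
                 level: str = "genome-nt") -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), level)


@dataclass(frozen=True)
class SpeciesAssignment:
    threshold: float
    clusters: dict   # label -> cluster id (0-based, by first appearance)

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("label\tspecies_cluster\n")
            for lab, c in self.clusters.items():
                fh.write(f"{lab}\t{c}\n")


@dataclass(frozen=True)
class GenusCall:
    call: str          # "cyclovirus-like" | "circovirus-like" | "unclassified"
    evidence: dict     # criterion name -> bool


def identity_matrix(seqs: Union[Mapping[str, str], Sequence[tuple]],
                    level: str = "genome-nt",
                    scoring: Optional[AlignScoring] = None,
                    mode: str = "sdt") -> IdentityMatrix:
    """All-pairs % identity via exact global alignment.

    Genome-level input must already be rotated to the ori so that
    linearization is consistent across genomes.
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if len(items) < 2:
        raise ValueError(">=2 sequences required")
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(items)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(items[i][1], items[j][1], scoring)
            vals[i, j] = vals[j, i] = pairwise_identity(aln, mode)
    return IdentityMatrix(labels, vals, level)


def demarcate_species(m: IdentityMatrix,
                      threshold: float = 80.0) -> SpeciesAssignment:
    """Single-linkage clusters: labels chained by identities >= threshold."""
    adj = (m.values >= threshold).astype(int)
    np.fill_diagonal(adj, 1)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    # renumber by first appearance for stable output
    remap: dict[int, int] = {}
    clusters = {}
    for lab, c in zip(m.labels, comp):
        if c not in remap:
            remap[c] = len(remap)
        clusters[lab] = remap[c]
    return SpeciesAssignment(threshold=threshold, clusters=clusters)


def classify_genus(annotation, refs: Optional[Mapping[str, str]] = None,
                   genus_threshold: float = 55.0,
                   arg_rich_min: float = 0.25,
                   scoring: Optional[AlignScoring] = None) -> GenusCall:
    """Apply the cyclovirus classification criteria to an annotation.

    Evidence flags: ori present; ori on the Cp-encoding strand (the
    motif-bearing virion-sense strand encodes Cp while Rep is antisense);
    genome-wide identity above the genus threshold against any supplied
    cyclovirus reference; motif-complete Rep (all six conserved motifs);
    Arg-rich Cp N-terminus. "cyclovirus-like" requires the ori
    orientation plus at least one other positive criterion;
    "circovirus-like" is called when the ori instead sits on the
    Rep-encoding strand; no ori means "unclassified".
    """
    ev = {
        "ori_present": annotation.ori is not None,
        "ori_on_cp_strand": False,
        "identity_over_genus_threshold": False,
        "motif_complete_rep": False,
        "arg_rich_cp": False,
    }
    if not ev["ori_present"]:
        return GenusCall("unclassified", ev)
    rep, cp = annotation.rep, annotation.cp
    # after rotation the motif strand is virion-sense; the organization is
    # cyclovirus-like when the motif-complete Rep reads antisense
    ori_on_rep_strand = bool(getattr(annotation, "rep_on_sense", False))
    if rep is not None and cp is not None and not ori_on_rep_strand:
        from .genome_io import ANTISENSE, VIRION_SENSE
        ev["ori_on_cp_strand"] = (cp.strand == VIRION_SENSE
                                  and rep.strand == ANTISENSE)
    if annotation.rep_motifs is not None:
        ev["motif_complete_rep"] = annotation.rep_motifs.score == 6
    if annotation.cp_arg_score is not None:
        ev["arg_rich_cp"] = annotation.cp_arg_score >= arg_rich_min
    if refs:
        g = annotation.genome
        best = 0.0
        for seq in refs.values():
            aln = global_align(g.seq, seq, scoring)
            best = max(best, pairwise_identity(aln))
        ev["identity_over_genus_threshold"] = best > genus_threshold
    others = (ev["identity_over_genus_threshold"]
              or ev["motif_complete_rep"] or ev["arg_rich_cp"])
    if ev["ori_on_cp_strand"] and others:
        return GenusCall("cyclovirus-like", ev)
    if ori_on_rep_strand and (ev["motif_complete_rep"] or others):
        return GenusCall("circovirus-like", ev)
    return GenusCall("unclassified", ev)
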