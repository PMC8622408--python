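"""ORF enumeration, alternative genetic codes and splice-aware Rep.

Cyclovirus genomes carry two divergently transcribed major ORFs: the
capsid protein (Cp) on the virion-sense strand and the
replication-associated protein (Rep) on the antisense strand. Some Rep
genes are interrupted by a short intron with canonical GT...AG
boundaries, and some require a non-standard genetic code (e.g. the
invertebrate mitochondrial code, translation table 5) with an
alternative initiation codon to yield a motif-complete Rep.

Start-preference policy: within a stop-anchored reading frame the
5'-most ATG wins; if the frame has no ATG, the 5'-most codon of each
configured alternative start (in list order) is tried. The initiation
codon is always rendered methionine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

from .genome_io import (ANTISENSE, VIRION_SENSE, CircularGenome, GenomeRegion,
                        region_seq, revcomp)
from . import motifs as _motifs

DEFAULT_START_CODONS = ("ATG", "ATA", "TTG", "GTG")


class TranslationError(ValueError):
    pass


@dataclass(frozen=True)
class TranslationTable:
    """An NCBI genetic code: codon->aa map plus stop and start codons."""

    table_id: int
    forward: dict
    stop_codons: frozenset
    start_codons: tuple

    @classmethod
    def from_id(cls, table_id: int) -> "TranslationTable":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id, dict(t.forward_table),
                   frozenset(t.stop_codons), tuple(t.start_codons))

    def aa(self, codon: str) -> Optional[str]:
        """Amino acid for a codon, None for stops, 'X' for ambiguous."""
        if codon in self.stop_codons:
            return None
        return self.forward.get(codon, "X")


def get_table(table_id: int) -> TranslationTable:
    return TranslationTable.from_id(table_id)


@dataclass(frozen=True)
class OrfAnnotation:
    """A (possibly spliced) coding region and its protein product."""

    role: str                       # "rep", "cp" or "other"
    region: GenomeRegion            # start > end allowed for antisense
    segments: tuple                 # 1 segment if unspliced, 2 if one intron
    table_id: int
    init_codon: str
    protein: str
    intron: Optional[GenomeRegion] = None

    @property
    def strand(self) -> str:
        return self.region.strand

    @property
    def aa_length(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class IntergenicRegions:
    ir5: Optional[GenomeRegion]
    ir3: Optional[GenomeRegion]


def translate(cds: str, table_id: int = 1,
              init_as_met: bool = True) -> str:
    """Translate an in-frame CDS (terminal stop included, not emitted).

    Raises :class:`TranslationError` on length violations, a missing
    terminal stop, or any internal stop (identifying the codon index).
    """
    table = get_table(table_id)
    if len(cds) < 6 or len(cds) % 3:
        raise TranslationError(
            f"CDS length {len(cds)} is not >=6 and a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in table.stop_codons:
        raise TranslationError(
            f"terminal codon {codons[-1]} is not a stop under table {table_id}")
    aas = []
    for idx, codon in enumerate(codons[:-1]):
        aa = table.aa(codon)
        if aa is None:
            raise TranslationError(
                f"internal stop codon {codon} at codon index {idx}")
        aas.append(aa)
    if init_as_met and aas:
        aas[0] = "M"
    return "".join(aas)


def _strand_string(genome: CircularGenome, strand: str) -> str:
    return genome.seq if strand == VIRION_SENSE else revcomp(genome.seq)


def _to_virion(strand: str, idx0: int, L: int) -> int:
    """Map a 0-based strand-string index to a 1-based virion position."""
    if strand == VIRION_SENSE:
        return idx0 % L + 1
    return L - (idx0 % L)


def start_preference_order(start_codons: Sequence[str]) -> list[str]:
    """ATG first when configured, then the remaining list in order."""
    return ([c for c in ("ATG",) if c in start_codons]
            + [c for c in start_codons if c != "ATG"])


def _pick_start(cands: list[tuple[int, int]], scan: str,
                start_codons: Sequence[str]) -> Optional[int]:
    """Apply the start-preference policy to candidate starts.

    ``cands`` are (start_index, own_stop_index) pairs sharing one
    circular stop; 5'-most means the largest distance to that stop.
    """
    for codon in start_preference_order(start_codons):
        best = None
        best_dist = -1
        for i, j in cands:
            if scan[i:i + 3] == codon and (j - i) > best_dist:
                best, best_dist = i, j - i
        if best is not None:
            return best
    return None


def enumerate_orfs(genome: CircularGenome, table_id: int = 1,
                   start_codons: Sequence[str] = DEFAULT_START_CODONS,
                   min_aa: int = 100,
                   forbidden_start_span: Optional[tuple] = None
                   ) -> list[OrfAnnotation]:
    """All stop-terminated ORFs of >= ``min_aa`` aa on both strands.

    Circular genomes may carry ORFs wrapping the origin (reported with
    the wrap in the single segment's coordinates). Each stop-anchored
    frame contributes at most one ORF, with its start chosen by the
    start-preference policy. ``forbidden_start_span`` (1-based inclusive
    virion positions) rejects candidate initiation codons overlapping
    that span, e.g. the ori motif.
    """
    table = get_table(table_id)
    L = len(genome)
    out: list[OrfAnnotation] = []
    for strand in (VIRION_SENSE, ANTISENSE):
        s = _strand_string(genome, strand)
        scan = s + s if genome.is_circular else s
        n = len(scan)
        # group candidate starts by their in-frame stop
        next_stop = [None] * (n + 3)
        for i in range(n - 3, -1, -1):
            codon = scan[i:i + 3]
            if len(codon) == 3 and codon in table.stop_codons:
                next_stop[i] = i
            elif i + 3 <= n:
                next_stop[i] = next_stop[i + 3]
        groups: dict[int, list[int]] = {}
        limit = L if genome.is_circular else max(0, n - 2)
        for i in range(limit):
            codon = scan[i:i + 3]
            if len(codon) < 3 or codon not in start_codons:
                continue
            if forbidden_start_span is not None:
                lo, hi = forbidden_start_span
                pos = [_to_virion(strand, i + k, L) for k in range(3)]
                if any(lo <= p <= hi for p in pos):
                    continue
            j = next_stop[i + 3] if i + 3 < len(next_stop) else None
            if j is None:
                continue
            if genome.is_circular and (j + 3 - i) > L:
                continue  # would wrap more than once
            key = j % L if genome.is_circular else j
            groups.setdefault(key, []).append(i)
        for key, cands in sorted(groups.items()):
            pairs = [(i, next_stop[i + 3]) for i in cands]
            chosen = _pick_start(pairs, scan, tuple(start_codons))
            if chosen is None:
                continue
            j = dict(pairs)[chosen]
            aa_len = (j - chosen) // 3
            if aa_len < min_aa:
                continue
            cds = scan[chosen:j + 3]
            protein = translate(cds, table_id, init_as_met=True)
            start_v = _to_virion(strand, chosen, L)
            end_v = _to_virion(strand, j + 2, L)
            region = GenomeRegion(start_v, end_v, strand)
            out.append(OrfAnnotation(
                role="other", region=region, segments=(region,),
                table_id=table_id, init_codon=scan[chosen:chosen + 3],
                protein=protein))
    out.sort(key=lambda o: (-o.aa_length, o.region.start_nt, o.strand))
    return out


def find_spliced_rep(genome: CircularGenome, table_id: int = 1,
                     start_codons: Sequence[str] = DEFAULT_START_CODONS,
                     min_aa: int = 100, max_intron: int = 200,
                     min_intron: int = 4,
                     patterns=None,
                     unspliced_best: Optional[tuple] = None,
                     forbidden_start_span: Optional[tuple] = None
                     ) -> Optional[OrfAnnotation]:
    """Search the antisense strand for an intron-interrupted Rep.

    Every donor GT / acceptor AG pair with intron length in
    [min_intron, max_intron] is tested; excision must yield an in-frame,
    stop-free ORF crossing the splice junction. The candidate maximizing
    (conserved Rep motif score, protein length) is returned, or ``None``
    if no candidate strictly beats the best unspliced antisense
    candidate (pass ``unspliced_best=(motif_score, aa_len)``; it is
    computed via :func:`enumerate_orfs` when omitted).

    The search is linear in antisense coordinates of the ori-rotated
    genome; introns spanning the origin are not considered (the ori sits
    between the genes, not inside Rep).
    """
    C = revcomp(genome.seq)
    L = len(C)
    table = get_table(table_id)

    if unspliced_best is None:
        cand = [o for o in enumerate_orfs(genome, table_id, start_codons,
                                          min_aa, forbidden_start_span)
                if o.strand == ANTISENSE]
        unspliced_best = (0, 0)
        for o in cand:
            prof = _motifs.scan_rep_motifs(o.protein, patterns)
            unspliced_best = max(unspliced_best, (prof.score, o.aa_length))

    # a motif-complete unspliced Rep is never displaced: a spliced
    # candidate can tie but not exceed the maximal motif score, and a
    # longer read-through obtained by excising the genuine stop codon
    # would be a spurious intron
    full_score = len(patterns) if patterns else len(_motifs.MOTIF_ORDER)
    if unspliced_best[0] >= full_score:
        return None

    is_stop = [C[i:i + 3] in table.stop_codons for i in range(L - 2)]
    # next in-frame stop at or after codon index i
    next_stop: list = [None] * (L + 3)
    for i in range(L - 3, -1, -1):
        next_stop[i] = i if is_stop[i] else next_stop[i + 3]
    # policy-chosen start for the stop-anchored run ending at codon i:
    # earliest index of each start codon type since the last stop
    order = start_preference_order(start_codons)
    first_start: dict[str, list] = {c: [None] * L for c in order}
    for i in range(L - 2):
        for c in order:
            fs = first_start[c]
            if is_stop[i]:
                fs[i] = None
            else:
                prev = fs[i - 3] if i >= 3 else None
                if prev is not None:
                    fs[i] = prev
                elif C[i:i + 3] == c:
                    if forbidden_start_span is not None:
                        lo, hi = forbidden_start_span
                        pos = [_to_virion(ANTISENSE, i + k, L)
                               for k in range(3)]
                        if any(lo <= p <= hi for p in pos):
                            continue
                    fs[i] = i

    donors = [d for d in range(L - 1) if C[d:d + 2] == "GT"]
    best = None  # (score, aa_len, -ilen, -s, payload)
    for d in donors:
        a_lo, a_hi = d + min_intron - 1, min(L - 1, d + max_intron - 1)
        for a in range(a_lo, a_hi + 1):
            if C[a - 1:a + 1] != "AG":
                continue
            ilen = a - d + 1
            for r in (0, 1, 2):
                iU = d - r - 3
                if iU < 0:
                    continue
                s_star = None
                for c in order:
                    v = first_start[c][iU]
                    if v is not None:
                        s_star = v
                        break
                if s_star is None:
                    continue
                if r > 0:
                    jc = C[d - r:d] + C[a + 1:a + 1 + (3 - r)]
                    if len(jc) < 3 or jc in table.stop_codons:
                        continue
                    jD = a + 1 + (3 - r)
                else:
                    jD = a + 1
                if jD > L - 3:
                    continue
                t = next_stop[jD]
                if t is None:
                    continue
                aa_len = ((d - r) - s_star) // 3 + (1 if r else 0) \
                    + (t - jD) // 3
                if aa_len < min_aa:
                    continue
                cds = C[s_star:d] + C[a + 1:t + 3]
                protein = translate(cds, table_id, init_as_met=True)
                prof = _motifs.scan_rep_motifs(protein, patterns)
                key = (prof.score, aa_len, -ilen, -s_star)
                if best is None or key > best[0]:
                    seg1 = GenomeRegion(L - s_star, L - d + 1, ANTISENSE)
                    seg2 = GenomeRegion(L - a - 1, L - t - 2, ANTISENSE)
                    intron = GenomeRegion(L - d, L - a, ANTISENSE)
                    ann = OrfAnnotation(
                        role="rep",
                        region=GenomeRegion(L - s_star, L - t - 2, ANTISENSE),
                        segments=(seg1, seg2), table_id=table_id,
                        init_codon=C[s_star:s_star + 3], protein=protein,
                        intron=intron)
                    best = (key, ann)
    if best is None:
        return None
    score, aa_len = best[0][0], best[0][1]
    if (score, aa_len) <= unspliced_best:
        return None
    return best[1]


def assign_roles(orfs: Sequence[OrfAnnotation], genome: CircularGenome,
                 spliced_rep: Optional[OrfAnnotation] = None,
                 patterns=None, arg_window: int = 20
                 ) -> tuple[Optional[OrfAnnotation], Optional[OrfAnnotation],
                            IntergenicRegions]:
    """Pick Rep (antisense, best motif score) and Cp (virion-sense, most
    Arg-rich N-terminus), then derive the intergenic regions.

    The 5'-IR spans between the two initiation codons through position 1;
    the 3'-IR spans between the two stop codons on the far side and is
    absent when the ORFs abut or overlap. A missing strand yields None
    for that role (annotation incomplete, not fatal).
    """
    L = len(genome)
    anti = [o for o in orfs if o.strand == ANTISENSE]
    if spliced_rep is not None:
        anti = anti + [spliced_rep]
    sense = [o for o in orfs if o.strand == VIRION_SENSE]

    rep = None
    if anti:
        scored = [((_motifs.scan_rep_motifs(o.protein, patterns).score,
                    o.aa_length), o) for o in anti]
        scored.sort(key=lambda t: t[0], reverse=True)
        rep = scored[0][1]
    cp = None
    if sense:
        scored = [((_motifs.arg_rich_score(o.protein, arg_window),
                    o.aa_length), o) for o in sense]
        scored.sort(key=lambda t: t[0], reverse=True)
        cp = scored[0][1]

    ir5 = ir3 = None
    if rep is not None and cp is not None:
        # 5'-IR: between initiation codons, containing position 1
        start5 = rep.region.start_nt % L + 1
        end5 = (cp.region.start_nt - 2) % L + 1
        if start5 != cp.region.start_nt:
            ir5 = GenomeRegion(start5, end5, VIRION_SENSE)
        # 3'-IR: between the stop codons on the opposite side
        gap = rep.region.end_nt - cp.region.end_nt - 1
        if gap >= 1 and cp.region.end_nt < rep.region.end_nt:
            ir3 = GenomeRegion(cp.region.end_nt + 1,
                               rep.region.end_nt - 1, VIRION_SENSE)
    rep = None if rep is None else OrfAnnotation(
        "rep", rep.region, rep.segments, rep.table_id, rep.init_codon,
        rep.protein, rep.intron)
    cp = None if cp is None else OrfAnnotation(
        "cp", cp.region, cp.segments, cp.table_id, cp.init_codon,
        cp.protein, cp.intron)
    return rep, cp, IntergenicRegions(ir5=ir5, ir3=ir3)


def compare_code_translations(genome: CircularGenome, region: GenomeRegion,
                              tables: tuple = (1, 5)) -> int:
    """Amino-acid mismatches between two genetic-code readings of a CDS."""
    cds = region_seq(genome, region)
    p1 = translate(cds, tables[0], init_as_met=True)
    p2 = translate(cds, tables[1], init_as_met=True)
    if len(p1) != len(p2):
        raise TranslationError("proteins differ in length between tables")
    return sum(a != b for a, b in zip(p1, p2))
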