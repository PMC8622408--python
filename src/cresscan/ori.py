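"""Origin-of-replication annotation for circular ssDNA virus genomes.

Cycloviruses (and circoviruses) initiate rolling-circle replication at a
conserved nonanucleotide motif, consensus ``NAGTATTAC`` (N = any base),
presented at the apex of a stem-loop in the 5'-intergenic region. By
ICTV convention the first base of the motif is genome position one.

The stem-loop is located by a deterministic complementary-arm search
(maximal arms flanking a loop that contains the motif) rather than by
thermodynamic folding; for these short near-perfect hairpins the two
approaches identify the same structure, and the combinatorial search is
exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .genome_io import (ANTISENSE, VIRION_SENSE, CircularGenome, GenomeRegion,
                        revcomp, rotate, wrap_position)

NONA_CONSENSUS = "NAGTATTAC"

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class NonaHit:
    """A nonanucleotide motif match.

    ``start_nt`` is 1-based on the strand carrying the hit: for
    virion-sense hits it indexes the genome sequence, for antisense hits
    it indexes the reverse complement of the genome sequence.
    """

    motif_seq: str
    start_nt: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class StemLoop:
    arm5: GenomeRegion
    arm3: GenomeRegion
    loop: GenomeRegion
    arm_len: int
    loop_len: int
    arm_mismatches: int = 0


@dataclass(frozen=True)
class OriAnnotation:
    nona: NonaHit
    stem_loop: Optional[StemLoop]
    rotated: bool = False


def _mismatches(window: str, consensus: str) -> int:
    n = 0
    for g, c in zip(window, consensus):
        if c == "N":
            continue
        if g != c:  # N in the genome never matches a specified base
            n += 1
    return n


def find_nonanucleotide(genome: CircularGenome,
                        consensus: str = NONA_CONSENSUS,
                        max_mismatch: int = 1) -> list[NonaHit]:
    """Scan both strands for the nonanucleotide motif.

    Returns every circular window with <= ``max_mismatch`` mismatches to
    the consensus, sorted by (mismatches, strand, position). An N in the
    consensus matches any base; an N in the genome matches nothing.
    """
    if len(consensus) != 9:
        raise ValueError("consensus must be 9 nt")
    if not 0 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be in 0..3")
    L = len(genome)
    hits: list[NonaHit] = []
    for strand, s in ((VIRION_SENSE, genome.seq),
                      (ANTISENSE, revcomp(genome.seq))):
        scan = s + s[:8] if genome.is_circular else s
        for i in range(L if genome.is_circular else max(0, L - 8)):
            window = scan[i:i + 9]
            if len(window) < 9:
                break
            mm = _mismatches(window, consensus)
            if mm <= max_mismatch:
                hits.append(NonaHit(window, i + 1, strand, mm))
    order = {VIRION_SENSE: 0, ANTISENSE: 1}
    hits.sort(key=lambda h: (h.mismatches, order[h.strand], h.start_nt))
    return hits


def predict_stem_loop(genome: CircularGenome, hit: NonaHit,
                      min_arm: int = 5, max_loop: int = 13,
                      max_arm_mismatch: int = 1,
                      max_arm: int = 40) -> Optional[StemLoop]:
    """Best hairpin presenting the motif inside its loop.

    Among all loop placements (loop length 9..max_loop containing the
    9-nt motif) the arms are extended base by base while the mismatch
    budget lasts; the structure maximizing arm length is returned, ties
    broken by smaller loop, then fewer arm mismatches. ``None`` when no
    placement reaches ``min_arm``. Regions are reported in the hit
    strand's coordinates.
    """
    s = genome.seq if hit.strand == VIRION_SENSE else revcomp(genome.seq)
    L = len(s)

    def base(pos0: int) -> str:  # 0-based circular indexing
        return s[pos0 % L] if genome.is_circular else (
            s[pos0] if 0 <= pos0 < L else "")

    m0 = hit.start_nt - 1  # 0-based motif start
    best: Optional[tuple[int, int, int, int]] = None  # arm, loop, mm, loop_start
    for loop_len in range(9, max_loop + 1):
        for loop_start in range(m0 - (loop_len - 9), m0 + 1):
            loop_end = loop_start + loop_len - 1
            # extend arms outward; a mismatch consumes budget but must not
            # terminate the arm (terminal mismatches are trimmed)
            mm = 0
            arm = 0
            good_arm = 0
            good_mm = 0
            while arm < max_arm and arm < (L - loop_len) // 2:
                a5 = base(loop_start - 1 - arm)
                a3 = base(loop_end + 1 + arm)
                if not a5 or not a3:
                    break
                if _PAIR.get(a5) == a3:
                    arm += 1
                    good_arm, good_mm = arm, mm
                else:
                    mm += 1
                    if mm > max_arm_mismatch:
                        break
                    arm += 1
            if good_arm >= min_arm:
                cand = (good_arm, loop_len, good_mm, loop_start)
                if best is None or (-cand[0], cand[1], cand[2]) < \
                        (-best[0], best[1], best[2]):
                    best = cand
    if best is None:
        return None
    arm, loop_len, mm, loop_start = best
    loop_end = loop_start + loop_len - 1
    wp = lambda p0: wrap_position(p0 + 1, L)
    return StemLoop(
        arm5=GenomeRegion(wp(loop_start - arm), wp(loop_start - 1), VIRION_SENSE),
        arm3=GenomeRegion(wp(loop_end + 1), wp(loop_end + arm), VIRION_SENSE),
        loop=GenomeRegion(wp(loop_start), wp(loop_end), VIRION_SENSE),
        arm_len=arm, loop_len=loop_len, arm_mismatches=mm)


def choose_ori_hit(genome: CircularGenome,
                   consensus: str = NONA_CONSENSUS,
                   max_mismatch: int = 1,
                   min_arm: int = 5, max_loop: int = 13,
                   max_arm_mismatch: int = 1
                   ) -> Optional[tuple[NonaHit, Optional[StemLoop]]]:
    """Pick the ori hit: fewest mismatches, then best stem-loop, then
    lowest position (virion-sense before antisense)."""
    hits = find_nonanucleotide(genome, consensus, max_mismatch)
    if not hits:
        return None
    best_mm = hits[0].mismatches
    ties = [h for h in hits if h.mismatches == best_mm]
    if len(ties) == 1:
        h = ties[0]
        return h, predict_stem_loop(genome, h, min_arm, max_loop,
                                    max_arm_mismatch)
    scored = []
    order = {VIRION_SENSE: 0, ANTISENSE: 1}
    for h in ties:
        sl = predict_stem_loop(genome, h, min_arm, max_loop, max_arm_mismatch)
        arm = sl.arm_len if sl else -1
        scored.append((-arm, order[h.strand], h.start_nt, h, sl))
    scored.sort(key=lambda t: t[:3])
    return scored[0][3], scored[0][4]


def orient_and_rotate(genome: CircularGenome, hit: NonaHit,
                      **stem_kwargs) -> tuple[CircularGenome, OriAnnotation]:
    """Put the motif on the virion-sense strand at positions 1-9.

    If the hit lies on the antisense strand the genome is
    reverse-complemented first, then rotated so the first motif base is
    position one (the ICTV convention).
    """
    if hit is None:
        raise ValueError(
            "no nonanucleotide hit; relax max_mismatch and retry")
    g = genome
    if hit.strand == ANTISENSE:
        g = replace(g, seq=revcomp(g.seq))
    g = rotate(g, hit.start_nt)
    new_hit = NonaHit(hit.motif_seq, 1, VIRION_SENSE, hit.mismatches)
    sl = predict_stem_loop(g, new_hit, **stem_kwargs)
    return g, OriAnnotation(nona=new_hit, stem_loop=sl, rotated=True)
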