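"""Cyclovirus-like genome generator with fully known ground truth.

Each generated genome carries, in position-one order: the
nonanucleotide motif opening the stem-loop's loop, the 3' stem arm, a
spacer, the virion-sense Cp ORF with a planted arginine-rich
N-terminus, an optional 3'-intergenic region, the antisense Rep ORF
(optionally interrupted by a canonical GT...AG intron) whose protein
contains all six conserved Rep motifs at known offsets, a spacer, and
the 5' stem arm closing the hairpin across the origin. A random
rotation is then applied and recorded, so the annotation pipeline can
be scored for exact recovery of every planted feature.

Construction rules that keep the truth unambiguous:

* an in-frame stop codon is planted immediately upstream of each major
  ORF's initiation codon, anchoring the start-preference policy;
* internal methionines are excluded when the planted initiation codon
  is not ATG (otherwise an internal ATG would pre-empt it);
* for non-standard genetic codes the Rep carries two tryptophans
  (TGA) flanking the helicase domain, too far apart for any single
  intron to excise, so the standard code cannot yield a motif-complete
  Rep; under table 5 the Walker-A serine is encoded AGA, which reads
  Arg under tables 1/4, so only table 5 is motif-complete;
* the intron interior is G-free, so its only donor/acceptor
  dinucleotides are the planted GT/AG pair, and it opens with an
  in-frame stop so the unspliced read-through never competes;
* assembled genomes are re-drawn when a spurious nonanucleotide hit at
  least as good as the planted one appears elsewhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .genome_io import (ANTISENSE, VIRION_SENSE, CircularGenome,
                        GenomeRegion, revcomp, rotate)
from .motifs import DEFAULT_REP_PATTERNS
from .orfs import get_table
from .ori import NONA_CONSENSUS, find_nonanucleotide, _mismatches

#: concrete instances of the default degenerate Rep motif patterns
MOTIF_INSTANCES = {
    "RCR-I": "FTLNN",
    "RCR-II": "PHLQG",
    "RCR-III": "YCSK",
    "WalkerA": "GPSGTGKS",
    "WalkerB": "LLFDD",
    "MotifC": "LTSN",
}

#: default 1-based aa offsets of the planted motifs in Rep
DEFAULT_MOTIF_OFFSETS = {
    "RCR-I": 15, "RCR-II": 40, "RCR-III": 70,
    "WalkerA": 160, "WalkerB": 190, "MotifC": 220,
}

_TRP_POSITIONS = (55, 175)  # flank the RCR/SF3 domains; 360 nt apart

_AA_POOL = "ACDEFGHIKLNPQRSTVY"  # no M, no W (planted explicitly)


class InfeasibleSpec(ValueError):
    pass


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic cyclovirus-like genome."""

    genome_len: Optional[int] = None   # None: derived from drawn spacers
    motif: str = "TAGTATTAC"
    arm_len: int = 11
    loop_len: int = 13
    rep_len_aa: int = 280
    cp_len_aa: int = 258
    rep_table: int = 1
    rep_start_codon: str = "ATG"
    cp_start_codon: str = "ATG"
    intron_len: Optional[int] = None   # e.g. 56; None = unspliced Rep
    intron_after_codon: int = 20
    cp_arg_frac: float = 0.5
    arg_window: int = 20
    ir3_len: int = 4
    motif_offsets: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_OFFSETS))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif) != 9:
            raise InfeasibleSpec("motif must be 9 nt")
        if self.loop_len < 9:
            raise InfeasibleSpec("loop must hold the 9-nt motif")
        if self.rep_len_aa < 240:
            raise InfeasibleSpec("rep_len_aa must be >= 240 to hold the "
                                 "default motif layout")
        if self.cp_len_aa < self.arg_window + 2:
            raise InfeasibleSpec("cp_len_aa too short for the Arg window")
        if self.intron_len is not None and self.intron_len < 10:
            raise InfeasibleSpec("intron_len must be >= 10")
        if self.rep_table not in (1, 4, 5):
            raise InfeasibleSpec("rep_table must be 1, 4 or 5")
        if not 0.0 <= self.cp_arg_frac <= 1.0:
            raise InfeasibleSpec("cp_arg_frac must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated genome (position-one coordinates)."""

    genome_position_one: str
    rotation_new_start: int          # rotate() argument used on emission
    motif: str
    rep_region: GenomeRegion
    rep_segments: tuple
    rep_intron: Optional[GenomeRegion]
    rep_table: int
    rep_start_codon: str
    rep_protein: str
    cp_region: GenomeRegion
    cp_protein: str
    ir5: GenomeRegion
    ir3: Optional[GenomeRegion]
    motif_aa_positions: dict
    mutation_count: int = 0


def _codon_choices(table_id: int) -> dict[str, list[str]]:
    t = get_table(table_id)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(t.forward.items()):
        by_aa.setdefault(aa, []).append(codon)
    # keep translations stable across tables 1/4/5: encode R as CGN only,
    # S as TCN only, I without ATA, L without TTA (table-3 quirk safety)
    by_aa["R"] = [c for c in by_aa["R"] if c.startswith("CG")]
    by_aa["S"] = [c for c in by_aa["S"] if c.startswith("TC")]
    by_aa["I"] = [c for c in by_aa.get("I", []) if c != "ATA"] or ["ATT"]
    return by_aa


def _reverse_translate(protein: Sequence[str], table_id: int,
                       rng: np.random.Generator,
                       overrides: Optional[dict[int, str]] = None
                       ) -> str:
    """Pick codons for each residue; ``overrides`` maps 0-based residue
    index to a fixed codon."""
    choices = _codon_choices(table_id)
    out = []
    for i, aa in enumerate(protein):
        if overrides and i in overrides:
            out.append(overrides[i])
            continue
        opts = choices[aa]
        out.append(opts[rng.integers(len(opts))])
    return "".join(out)


def _random_nt(rng: np.random.Generator, n: int,
               alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def _build_rep_protein(spec: GenomeSpec, rng: np.random.Generator
                       ) -> tuple[str, dict]:
    n = spec.rep_len_aa
    aa = list("".join(_AA_POOL[i]
                      for i in rng.integers(len(_AA_POOL), size=n)))
    aa[0] = "M"
    positions = {}
    for name, off in spec.motif_offsets.items():
        inst = MOTIF_INSTANCES[name]
        if off + len(inst) - 1 > n:
            raise InfeasibleSpec(f"motif {name} exceeds rep_len_aa")
        aa[off - 1:off - 1 + len(inst)] = list(inst)
        positions[name] = off
    if spec.rep_table in (4, 5):
        for w in _TRP_POSITIONS:
            aa[w - 1] = "W"
    return "".join(aa), positions


def _build_rep_cds(spec: GenomeSpec, protein: str,
                   rng: np.random.Generator) -> str:
    overrides: dict[int, str] = {0: spec.rep_start_codon}
    if spec.rep_table in (4, 5):
        for w in _TRP_POSITIONS:
            overrides[w - 1] = "TGA"
    if spec.rep_table == 5:
        # Walker-A serine as AGA: Ser under table 5, Arg under tables 1/4
        wa = spec.motif_offsets["WalkerA"]
        overrides[wa - 1 + len(MOTIF_INSTANCES["WalkerA"]) - 1] = "AGA"
    body = _reverse_translate(protein, spec.rep_table, rng, overrides)
    return body + "TAA"


def _build_cp(spec: GenomeSpec, rng: np.random.Generator) -> tuple[str, str]:
    n = spec.cp_len_aa
    aa = list("".join(_AA_POOL[i]
                      for i in rng.integers(len(_AA_POOL), size=n)))
    aa[0] = "M"
    w = spec.arg_window
    n_basic = int(round(spec.cp_arg_frac * w))
    # position 1 is Met; distribute basics over positions 2..w
    slots = list(range(1, w))
    rng.shuffle(slots)
    for i in range(min(n_basic, len(slots))):
        aa[slots[i]] = "R" if rng.integers(2) else "K"
    for i in slots[min(n_basic, len(slots)):]:
        if aa[i] in "RK":
            aa[i] = "ACDEFGHILNPQSTVY"[rng.integers(16)]
    protein = "".join(aa)
    cds = _reverse_translate(protein, 1, rng,
                             {0: spec.cp_start_codon}) + "TAA"
    return protein, cds


def _build_intron(spec: GenomeSpec, rng: np.random.Generator) -> str:
    ilen = spec.intron_len
    # GT donor, read-through stop, G-free interior, AG acceptor
    interior = _random_nt(rng, ilen - 8, alphabet="ACT")
    return "GT" + "A" + "TAA" + interior + "AG"


def generate_genome(spec: GenomeSpec,
                    apply_rotation: bool = True,
                    max_attempts: int = 50
                    ) -> tuple[CircularGenome, SyntheticTruth]:
    """Generate one genome and its ground truth.

    Deterministic in ``spec`` (including ``spec.seed``). Raises
    :class:`InfeasibleSpec` when the requested features cannot fit
    ``genome_len``.
    """
    planted_mm = _mismatches(spec.motif, NONA_CONSENSUS)
    for attempt in range(max_attempts):
        rng = np.random.default_rng((spec.seed, attempt))
        g0, truth = _assemble(spec, rng)
        hits = find_nonanucleotide(g0, NONA_CONSENSUS,
                                   max_mismatch=max(planted_mm, 1))
        bad = False
        for h in hits:
            if h.strand == VIRION_SENSE and h.start_nt == 1:
                continue
            if h.mismatches < planted_mm or (planted_mm == 0
                                             and h.mismatches == 0):
                bad = True
                break
        if bad:
            continue
        if apply_rotation:
            L = len(g0)
            k = int(rng.integers(1, L + 1))
            g = rotate(g0, k)
            truth = dataclasses.replace(truth, rotation_new_start=k)
        else:
            g = g0
        return g, truth
    raise RuntimeError("could not generate an unambiguous genome; "
                       "relax the spec")


def _assemble(spec: GenomeSpec, rng: np.random.Generator
              ) -> tuple[CircularGenome, SyntheticTruth]:
    rep_protein, motif_pos = _build_rep_protein(spec, rng)
    rep_cds = _build_rep_cds(spec, rep_protein, rng)
    if spec.intron_len is not None:
        cut = 3 * spec.intron_after_codon
        if not 3 <= cut <= len(rep_cds) - 6:
            raise InfeasibleSpec("intron_after_codon outside the CDS")
        intron = _build_intron(spec, rng)
        rep_genomic = rep_cds[:cut] + intron + rep_cds[cut:]
        ilen = spec.intron_len
    else:
        rep_genomic = rep_cds
        intron = None
        ilen = 0
    cp_protein, cp_cds = _build_cp(spec, rng)

    loop_extra = spec.loop_len - 9
    fixed = (spec.loop_len + 2 * spec.arm_len + len(cp_cds)
             + spec.ir3_len + len(rep_genomic))
    if spec.genome_len is None:
        sc = 3 + int(rng.integers(10, 70))
        sr = 3 + int(rng.integers(10, 70))
        L = fixed + sc + sr
    else:
        rem = spec.genome_len - fixed
        if rem < 8:
            raise InfeasibleSpec(
                f"features need {fixed + 8} nt but genome_len is "
                f"{spec.genome_len}")
        sc = 3 + (rem - 6) // 2
        sr = rem - sc
        L = spec.genome_len

    loop = spec.motif + _random_nt(rng, loop_extra)
    arm3 = _random_nt(rng, spec.arm_len)
    arm5 = revcomp(arm3)
    spacer_cp = _random_nt(rng, sc - 3) + "TAA"     # stop anchoring Cp
    spacer_rep = "TTA" + _random_nt(rng, sr - 3)    # revcomp stop for Rep

    seq = (loop + arm3 + spacer_cp + cp_cds + _random_nt(rng, spec.ir3_len)
           + revcomp(rep_genomic) + spacer_rep + arm5)
    assert len(seq) == L
    g0 = CircularGenome("synthetic", seq, "circular")

    s_cp = spec.loop_len + spec.arm_len + sc + 1
    e_cp = s_cp + len(cp_cds) - 1
    r_lo = e_cp + spec.ir3_len + 1
    r_hi = r_lo + len(rep_genomic) - 1
    if spec.intron_len is not None:
        cut = 3 * spec.intron_after_codon
        seg1 = GenomeRegion(r_hi, r_hi - cut + 1, ANTISENSE)
        seg2 = GenomeRegion(r_hi - cut - ilen, r_lo, ANTISENSE)
        intron_region = GenomeRegion(r_hi - cut, r_hi - cut - ilen + 1,
                                     ANTISENSE)
        segments = (seg1, seg2)
    else:
        segments = (GenomeRegion(r_hi, r_lo, ANTISENSE),)
        intron_region = None
    truth = SyntheticTruth(
        genome_position_one=seq,
        rotation_new_start=1,
        motif=spec.motif,
        rep_region=GenomeRegion(r_hi, r_lo, ANTISENSE),
        rep_segments=segments,
        rep_intron=intron_region,
        rep_table=spec.rep_table,
        rep_start_codon=spec.rep_start_codon,
        rep_protein=rep_protein,
        cp_region=GenomeRegion(s_cp, e_cp, VIRION_SENSE),
        cp_protein=cp_protein,
        ir5=GenomeRegion(r_hi + 1, s_cp - 1, VIRION_SENSE),
        ir3=(GenomeRegion(e_cp + 1, r_lo - 1, VIRION_SENSE)
             if spec.ir3_len else None),
        motif_aa_positions=motif_pos,
    )
    return g0, truth


def mutate(genome: CircularGenome, rate: float,
           seed: Union[int, tuple] = 0) -> CircularGenome:
    """Independent per-site substitutions to a uniformly chosen
    different base; the expected substituted fraction equals ``rate``."""
    if not 0.0 <= rate <= 0.75:
        raise ValueError("rate must be in [0, 0.75]")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = list(genome.seq)
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hit:
        cur = seq[i]
        alts = [b for b in bases if b != cur]
        seq[i] = alts[rng.integers(len(alts))]
    return CircularGenome(genome.id, "".join(seq), genome.topology)


def generate_species_panel(n_species: int = 2,
                           per_species: Union[int, Sequence[int]] = 2,
                           within_rate: float = 0.01,
                           between_rate: float = 0.15,
                           seed: int = 0,
                           spec: Optional[GenomeSpec] = None
                           ) -> tuple[dict, dict]:
    """A labeled panel of genomes with a known species partition.

    Each species descends from an independent mutant of one root genome
    (divergence ``between_rate`` per site); members within a species are
    mutants of their species base at ``within_rate``. With the default
    rates, within-species pairwise identities sit near 98 % and
    between-species identities near 73 %, cleanly straddling the 80 %
    demarcation threshold. Genomes are emitted in the shared
    position-one rotation so identity matrices need no re-rotation.
    """
    if not within_rate < between_rate:
        raise ValueError("within_rate must be < between_rate")
    if isinstance(per_species, int):
        per_species = [per_species] * n_species
    if len(per_species) != n_species:
        raise ValueError("per_species length must equal n_species")
    spec = spec or GenomeSpec(seed=seed)
    root, _ = generate_genome(dataclasses.replace(spec, seed=seed),
                              apply_rotation=False)
    genomes: dict[str, CircularGenome] = {}
    truth: dict[str, int] = {}
    for i in range(n_species):
        # every species base diverges independently from the root, so any
        # cross-species pair is ~2x between_rate apart
        base = mutate(root, between_rate, seed=(seed, 7919, i))
        for j in range(per_species[i]):
            lab = f"sp{i}_g{j}"
            g = mutate(base, within_rate, seed=(seed, 104729, i, j))
            genomes[lab] = CircularGenome(lab, g.seq, g.topology)
            truth[lab] = i
    return genomes, truth
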