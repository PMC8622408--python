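"""Annotation serialization: GFF3 and JSON writers.

GFF3 is emitted 1-based inclusive with ascending start <= end per line;
features wrapping the circular origin are split into two lines sharing
one ID, and a spliced CDS appears as one line per exon sharing the CDS
ID, the standard convention for multi-segment CDS features.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

from .genome_io import ANTISENSE, VIRION_SENSE, GenomeRegion
from .pipeline import GenomeAnnotation


def _region_dict(r: Optional[GenomeRegion]) -> Optional[dict]:
    if r is None:
        return None
    return {"start_nt": r.start_nt, "end_nt": r.end_nt,
            "strand": "virion-sense" if r.strand == VIRION_SENSE
            else "antisense"}


def annotation_to_dict(ann: GenomeAnnotation) -> dict:
    d = {
        "genome": {"id": ann.genome.id, "length_nt": len(ann.genome),
                   "topology": ann.genome.topology},
        "ori": None,
        "rep": None,
        "cp": None,
        "ir5": _region_dict(ann.irs.ir5),
        "ir3": _region_dict(ann.irs.ir3),
        "cp_arg_score": ann.cp_arg_score,
        "rep_motifs": None,
        "genus_call": ann.genus.call if ann.genus else None,
        "genus_evidence": dict(ann.genus.evidence) if ann.genus else None,
        "table_alternatives": ann.table_alternatives,
        "warnings": list(ann.warnings),
    }
    if ann.ori is not None:
        sl = ann.ori.stem_loop
        d["ori"] = {
            "motif_seq": ann.ori.nona.motif_seq,
            "start_nt": ann.ori.nona.start_nt,
            "mismatches": ann.ori.nona.mismatches,
            "stem_loop": None if sl is None else {
                "arm_len": sl.arm_len, "loop_len": sl.loop_len,
                "arm_mismatches": sl.arm_mismatches,
                "arm5": _region_dict(sl.arm5),
                "arm3": _region_dict(sl.arm3),
                "loop": _region_dict(sl.loop),
            },
        }
    for role in ("rep", "cp"):
        orf = getattr(ann, role)
        if orf is None:
            continue
        d[role] = {
            "region": _region_dict(orf.region),
            "segments": [_region_dict(s) for s in orf.segments],
            "intron": _region_dict(orf.intron),
            "table_id": orf.table_id,
            "init_codon": orf.init_codon,
            "protein_length_aa": orf.aa_length,
            "protein": orf.protein,
        }
    if ann.rep_motifs is not None:
        d["rep_motifs"] = {
            "score": ann.rep_motifs.score,
            "ordered": ann.rep_motifs.ordered,
            "hits": [dataclasses.asdict(h) for h in ann.rep_motifs.hits],
        }
    return d


def write_json(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        json.dump(annotation_to_dict(ann), fh, indent=2)
        fh.write("\n")


def _gff_lines(seqid: str, source: str, ftype: str, region: GenomeRegion,
               genome_len: int, attrs: str) -> list[str]:
    """One ascending-coordinate line, or two for origin-wrapping spans."""
    strand = "+" if region.strand == VIRION_SENSE else "-"
    if region.strand == VIRION_SENSE:
        lo, hi = region.start_nt, region.end_nt
    else:
        lo, hi = region.end_nt, region.start_nt
    pieces = []
    if lo <= hi:
        pieces.append((lo, hi))
    else:  # wraps the origin
        pieces.append((lo, genome_len))
        pieces.append((1, hi))
    return [
        "\t".join([seqid, source, ftype, str(a), str(b), ".", strand, ".",
                   attrs])
        for a, b in pieces
    ]


def to_gff3(ann: GenomeAnnotation) -> str:
    g = ann.genome
    L = len(g)
    out = ["##gff-version 3", f"##sequence-region {g.id} 1 {L}"]
    src = "cresscan"
    if ann.ori is not None:
        out += _gff_lines(g.id, src, "origin_of_replication",
                          GenomeRegion(1, 9, VIRION_SENSE), L,
                          f"ID=ori;motif={ann.ori.nona.motif_seq}")
        sl = ann.ori.stem_loop
        if sl is not None:
            for name, r in (("stem_arm5", sl.arm5), ("stem_arm3", sl.arm3),
                            ("stem_loop", sl.loop)):
                out += _gff_lines(g.id, src, "sequence_feature", r, L,
                                  f"ID={name};Parent=ori")
    for role in ("rep", "cp"):
        orf = getattr(ann, role)
        if orf is None:
            continue
        out += _gff_lines(g.id, src, "gene", orf.region, L,
                          f"ID=gene_{role}")
        for seg in orf.segments:
            out += _gff_lines(
                g.id, src, "CDS", seg, L,
                f"ID=cds_{role};Parent=gene_{role};"
                f"transl_table={orf.table_id};init_codon={orf.init_codon}")
        if orf.intron is not None:
            out += _gff_lines(g.id, src, "intron", orf.intron, L,
                              f"ID=intron_{role};Parent=gene_{role}")
    for name, r in (("ir5", ann.irs.ir5), ("ir3", ann.irs.ir3)):
        if r is not None:
            out += _gff_lines(g.id, src, "intergenic_region", r, L,
                              f"ID={name}")
    return "\n".join(out) + "\n"


def write_gff3(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_gff3(ann))


def motif_tsv(ann: GenomeAnnotation) -> str:
    lines = ["name\taa_start\tmatched"]
    if ann.rep_motifs is not None:
        for h in ann.rep_motifs.hits:
            lines.append(f"{h.name}\t{h.aa_start}\t{h.matched}")
    return "\n".join(lines) + "\n"
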