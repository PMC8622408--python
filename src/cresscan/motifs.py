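"""Conserved Rep motif detection and Cp arginine-richness.

CRESS DNA virus replication-associated proteins carry three rolling
circle replication endonuclease motifs (RCR I-III) in the N-terminal
half and three superfamily 3 helicase motifs (Walker A, Walker B,
motif C) in the C-terminal half. The default degenerate consensus
patterns below follow the circovirus/cyclovirus literature; every
pattern is overridable, and the N-half/C-half zone constraint can be
disabled.

The capsid protein of cycloviruses begins with an arginine-rich,
DNA-binding amino-terminal region, quantified here as the (R+K)
fraction of an N-terminal window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

MOTIF_ORDER = ("RCR-I", "RCR-II", "RCR-III", "WalkerA", "WalkerB", "MotifC")

#: Degenerate consensus patterns (regular expressions over amino acids).
DEFAULT_REP_PATTERNS: dict[str, str] = {
    "RCR-I": r"[FW]T[LIV]NN",
    "RCR-II": r".[HPA][LIV][QH]G",
    "RCR-III": r"Y[CLV][SK]K",
    "WalkerA": r"G[PIAK][PST]GTGKS",
    "WalkerB": r"[LIVM][LIVM][FD]DD",
    "MotifC": r"[LIVM]T[SN]N",
}

_N_HALF = {"RCR-I", "RCR-II", "RCR-III"}


@dataclass(frozen=True)
class MotifHit:
    name: str
    aa_start: int        # 1-based position in the protein
    matched: str
    pattern_id: str


@dataclass(frozen=True)
class MotifProfile:
    hits: tuple
    score: int           # distinct motif names found, 0..6
    ordered: bool        # hits occur in canonical N->C order

    def position(self, name: str) -> Optional[int]:
        for h in self.hits:
            if h.name == name:
                return h.aa_start
        return None


def scan_rep_motifs(protein: str,
                    patterns: Optional[Mapping[str, str]] = None,
                    zone_constraint: bool = True) -> MotifProfile:
    """Locate the six conserved Rep motifs in a protein.

    For each motif the leftmost match within its expected zone is
    reported (RCR motifs in the N-terminal half, SF3 motifs in the
    C-terminal half; searched anywhere when ``zone_constraint`` is off).
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    if patterns is None:
        patterns = DEFAULT_REP_PATTERNS
    half = len(protein) // 2
    hits = []
    for name in MOTIF_ORDER:
        if name not in patterns:
            continue
        pat = re.compile(patterns[name])
        for m in pat.finditer(protein):
            start1 = m.start() + 1
            if zone_constraint:
                if name in _N_HALF and start1 > half:
                    continue
                if name not in _N_HALF and start1 <= half:
                    continue
            hits.append(MotifHit(name, start1, m.group(0), patterns[name]))
            break
    starts = [h.aa_start for h in hits]
    ordered = all(a <= b for a, b in zip(starts, starts[1:]))
    return MotifProfile(hits=tuple(hits), score=len({h.name for h in hits}),
                        ordered=ordered)


def arg_rich_score(protein: str, window: int = 20) -> float:
    """(R+K) fraction of the N-terminal window (truncated if shorter)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    w = min(window, len(protein))
    if w == 0:
        return 0.0
    return sum(c in "RK" for c in protein[:w]) / w
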