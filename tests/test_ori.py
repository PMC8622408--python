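import numpy as np
import pytest

from cresscan.genome_io import ANTISENSE, VIRION_SENSE, CircularGenome, \
    revcomp, rotate
from cresscan.ori import (NONA_CONSENSUS, NonaHit, choose_ori_hit,
                          find_nonanucleotide, orient_and_rotate,
                          predict_stem_loop)

from _oracles import oracle_nona_hits


def _random_genome(seed, n=400):
    rng = np.random.default_rng(seed)
    return CircularGenome(f"r{seed}",
                          "".join("ACGT"[i] for i in rng.integers(4, size=n)))


def test_canonical_motif_found_exact():
    g = CircularGenome("g", "C" * 40 + "TAGTATTAC" + "C" * 40)
    hits = find_nonanucleotide(g, max_mismatch=0)
    assert hits[0].strand == VIRION_SENSE
    assert hits[0].start_nt == 41 and hits[0].mismatches == 0


def test_single_mismatch_variant_found():
    g = CircularGenome("g", "C" * 40 + "TACTATTAC" + "C" * 40)
    assert find_nonanucleotide(g, max_mismatch=0) == []
    hits = find_nonanucleotide(g, max_mismatch=1)
    assert hits and hits[0].mismatches == 1 and hits[0].start_nt == 41


def test_no_hit_returns_empty_list():
    g = CircularGenome("g", "C" * 1000)
    assert find_nonanucleotide(g, max_mismatch=1) == []


def test_n_in_genome_counts_as_mismatch():
    g = CircularGenome("g", "C" * 20 + "TAGTATTNC" + "C" * 20)
    assert find_nonanucleotide(g, max_mismatch=0) == []
    assert find_nonanucleotide(g, max_mismatch=1)[0].mismatches == 1


@pytest.mark.parametrize("seed", range(15))
def test_scan_matches_brute_force_oracle(seed):
    g = _random_genome(seed)
    for mm in (1, 2):
        got = {(h.strand, h.start_nt, h.motif_seq, h.mismatches)
               for h in find_nonanucleotide(g, max_mismatch=mm)}
        assert got == set(oracle_nona_hits(g.seq, NONA_CONSENSUS, mm))


@pytest.mark.parametrize("seed", range(8))
def test_scan_is_strand_symmetric(seed):
    g = _random_genome(seed)
    fwd = find_nonanucleotide(g, max_mismatch=2)
    rev = find_nonanucleotide(
        CircularGenome(g.id, revcomp(g.seq)), max_mismatch=2)
    flip = {VIRION_SENSE: ANTISENSE, ANTISENSE: VIRION_SENSE}
    assert {(flip[h.strand], h.motif_seq, h.mismatches) for h in fwd} \
        == {(h.strand, h.motif_seq, h.mismatches) for h in rev}


def test_planted_hairpin_recovered():
    arm = "GCGGAGGCC"
    loop = "TAGTATTACA"  # 10 nt, motif at the loop start
    g = CircularGenome("g", "T" * 30 + arm + loop + revcomp(arm) + "T" * 30)
    hit = find_nonanucleotide(g, max_mismatch=0)[0]
    sl = predict_stem_loop(g, hit, min_arm=5, max_loop=13)
    assert sl is not None and sl.arm_len == 9 and sl.loop_len == 10


def test_motif_without_complementary_flanks_has_no_stem_loop():
    g = CircularGenome("g", "A" * 30 + "TAGTATTAC" + "A" * 30)
    hit = find_nonanucleotide(g, max_mismatch=0)[0]
    assert predict_stem_loop(g, hit, min_arm=5, max_loop=13,
                             max_arm_mismatch=0) is None


def _oracle_stem_loop(seq, motif_start1, min_arm, max_loop, max_mm):
    """Exhaustive enumeration of legal (arm, loop placement) hairpins."""
    L = len(seq)
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best = None
    m0 = motif_start1 - 1
    for loop_len in range(9, max_loop + 1):
        for loop_start in range(m0 - (loop_len - 9), m0 + 1):
            loop_end = loop_start + loop_len - 1
            for arm in range(min_arm, 41):
                if arm >= (L - loop_len) // 2:
                    break
                mm = 0
                ok = True
                for k in range(arm):
                    a5 = seq[(loop_start - 1 - k) % L]
                    a3 = seq[(loop_end + 1 + k) % L]
                    if pair[a5] != a3:
                        mm += 1
                # terminal base must pair (trailing mismatches trimmed)
                if pair[seq[(loop_start - arm) % L]] != \
                        seq[(loop_end + arm) % L]:
                    ok = False
                if ok and mm <= max_mm:
                    cand = (-arm, loop_len, mm)
                    if best is None or cand < best:
                        best = cand
    return None if best is None else (-best[0], best[1], best[2])


@pytest.mark.parametrize("seed", range(10))
def test_stem_loop_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    arm_n = int(rng.integers(6, 14))
    arm = "".join("ACGT"[i] for i in rng.integers(4, size=arm_n))
    pad = lambda n: "".join("ACGT"[i] for i in rng.integers(4, size=n))
    loop_extra = int(rng.integers(0, 4))
    seq = (pad(40) + arm + "TAGTATTAC" + pad(loop_extra) + revcomp(arm)
           + pad(40))
    g = CircularGenome("g", seq)
    hit = [h for h in find_nonanucleotide(g, max_mismatch=0)
           if h.strand == VIRION_SENSE][0]
    sl = predict_stem_loop(g, hit, min_arm=5, max_loop=13,
                           max_arm_mismatch=1)
    expected = _oracle_stem_loop(seq, hit.start_nt, 5, 13, 1)
    if expected is None:
        assert sl is None
    else:
        assert (sl.arm_len, sl.loop_len, sl.arm_mismatches) == expected


def test_orient_identity_when_already_at_position_one():
    g = CircularGenome("g", "TAGTATTAC" + "ACCTTGCAT" * 20)
    hit = find_nonanucleotide(g, max_mismatch=0)[0]
    rotated, ori = orient_and_rotate(g, hit)
    assert rotated.seq == g.seq and ori.nona.start_nt == 1


@pytest.mark.parametrize("seed", range(10))
def test_rotation_recovers_planted_position(seed):
    rng = np.random.default_rng((99, seed))
    while True:  # draw a background without a second exact motif
        body = "".join("ACGT"[i] for i in rng.integers(4, size=400))
        base = "TAGTATTAC" + body
        g0 = CircularGenome("g", base)
        if len(find_nonanucleotide(g0, max_mismatch=0)) == 1:
            break
    k = int(rng.integers(1, len(base) + 1))
    g = rotate(g0, k)
    hit = find_nonanucleotide(g, max_mismatch=0)[0]
    rotated, ori = orient_and_rotate(g, hit)
    assert rotated.seq == base
    assert rotated.seq[:9] == "TAGTATTAC"


def test_antisense_hit_is_reoriented_to_virion_sense():
    base = "TAGTATTAC" + "ACCTTGCAT" * 20
    g = CircularGenome("g", revcomp(base))
    hit = find_nonanucleotide(g, max_mismatch=0)[0]
    assert hit.strand == ANTISENSE
    rotated, ori = orient_and_rotate(g, hit)
    assert rotated.seq[:9] == "TAGTATTAC"
    assert ori.nona.strand == VIRION_SENSE


def test_orient_without_hit_raises_helpfully():
    with pytest.raises(ValueError, match="max_mismatch"):
        orient_and_rotate(CircularGenome("g", "C" * 100), None)


def test_choose_ori_prefers_better_stem_loop_on_tied_mismatches():
    arm = "GCGGAGGCCAT"
    hairpin = arm + "TAGTATTACA" + revcomp(arm)
    # a second exact motif without flanking complementarity
    seq = "T" * 25 + hairpin + "T" * 25 + "TAGTATTAC" + "T" * 25
    g = CircularGenome("g", seq)
    hit, sl = choose_ori_hit(g, max_mismatch=0)
    assert hit.start_nt == 25 + len(arm) + 1
    assert sl is not None and sl.arm_len >= 11
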