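import numpy as np
import pytest

from cresscan.genome_io import (ANTISENSE, VIRION_SENSE, CircularGenome,
                                GenomeRegion, revcomp, rotate)
from cresscan.orfs import (TranslationError, compare_code_translations,
                           enumerate_orfs, find_spliced_rep, translate,
                           assign_roles, get_table)
from cresscan.synthetic import GenomeSpec, generate_genome

from _oracles import oracle_linear_orfs, oracle_spliced_rep

STARTS = ("ATG", "ATA", "TTG", "GTG")


class TestTranslate:
    def test_ttg_initiation_renders_methionine(self):
        assert translate("TTGAAATAA", 1) == "MK"

    def test_table5_ata_initiation(self):
        assert translate("ATAGGATAG", 5) == "MG"

    def test_code_differences_aga_and_tga(self):
        # AGA: Arg (standard) vs Ser (invertebrate mitochondrial)
        assert translate("ATGAGATAA", 1) == "MR"
        assert translate("ATGAGATAA", 5) == "MS"
        # TGA: stop (standard) vs Trp (table 5)
        assert translate("ATGTGATTTTAA", 5) == "MWF"
        with pytest.raises(TranslationError, match="codon index 1"):
            translate("ATGTGATTTTAA", 1)

    def test_length_and_stop_contracts(self):
        with pytest.raises(TranslationError):
            translate("ATGTA", 1)
        with pytest.raises(TranslationError):
            translate("ATGAAAGGG", 1)  # no terminal stop

    def test_table_definitions_differ_where_expected(self):
        t1, t5 = get_table(1), get_table(5)
        assert t1.aa("ATA") == "I" and t5.aa("ATA") == "M"
        assert t1.aa("AGA") == "R" and t5.aa("AGA") == "S"
        assert t1.aa("TGA") is None and t5.aa("TGA") == "W"


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


@pytest.mark.parametrize("seed", range(30))
@pytest.mark.parametrize("table_id", [1, 5])
def test_linear_enumeration_matches_six_frame_oracle(seed, table_id):
    n = 300 + (seed * 57) % 1000
    seq = _random_seq((seed, table_id), n)
    g = CircularGenome("g", seq, topology="linear")
    got = {(o.strand, o.region.start_nt, o.region.end_nt, o.init_codon,
            o.protein)
           for o in enumerate_orfs(g, table_id, STARTS, min_aa=25)}
    assert got == oracle_linear_orfs(seq, table_id, STARTS, min_aa=25)


def test_orf_spanning_the_circular_origin():
    rng = np.random.default_rng(7)
    body = "".join("ACGTACGTACGGACCTACGAGCTCCATAGC"[i % 30]
                   for i in range(150))
    cds = "ATG" + body + "TAA"
    # anchor stop right before the start so the frame is unambiguous
    g0 = CircularGenome("g", "TAA" + cds + "CCCC")
    g = rotate(g0, 80)  # origin now falls inside the CDS
    orfs = enumerate_orfs(g, 1, STARTS, min_aa=40)
    assert any(o.region.start_nt > o.region.end_nt
               and o.strand == VIRION_SENSE
               and o.protein == translate(cds, 1) for o in orfs)


def test_emitted_orfs_satisfy_type_invariants():
    g = CircularGenome("g", _random_seq(123, 1500))
    for o in enumerate_orfs(g, 1, STARTS, min_aa=30):
        assert o.protein.startswith("M")
        assert "*" not in o.protein
        total = sum(s.length(len(g)) for s in o.segments)
        assert total % 3 == 0
        assert o.aa_length == total // 3 - 1


class TestSplicedRep:
    def test_planted_intron_recovered(self, cn9e_style):
        g, truth = cn9e_style
        rotated = rotate(g, (1 - truth.rotation_new_start) % len(g) + 1)
        found = find_spliced_rep(rotated, 5, ("ATG", "ATA"), 100, 200)
        assert found is not None
        assert found.intron == truth.rep_intron
        assert found.protein == truth.rep_protein
        assert found.init_codon == "ATA"
        assert found.intron.length(len(g)) == 56

    @pytest.mark.parametrize("seed", [2, 8])
    def test_matches_excision_oracle(self, seed):
        spec = GenomeSpec(seed=seed, rep_table=5, rep_start_codon="ATA",
                          intron_len=44, ir3_len=0)
        g, truth = generate_genome(spec, apply_rotation=False)
        found = find_spliced_rep(g, 5, ("ATG", "ATA"), 100, 200)
        best = oracle_spliced_rep(g.seq, 5, ("ATG", "ATA"), 100, 200)
        assert found is not None and best is not None
        assert (found.intron.start_nt, found.intron.end_nt) \
            == best[1]["intron"]
        assert found.protein == best[1]["protein"]

    def test_absent_when_no_donor_acceptor_pair(self):
        # all-A/C sequence has no GT dinucleotide on either strand
        g = CircularGenome("g", "AC" * 300)
        assert find_spliced_rep(g, 1, STARTS, 50, 200) is None

    def test_no_spurious_intron_on_motif_complete_unspliced(self):
        g, truth = generate_genome(GenomeSpec(seed=21),
                                   apply_rotation=False)
        prof_len = len(truth.rep_protein)
        found = find_spliced_rep(g, 1, STARTS, 100, 200,
                                 unspliced_best=(6, prof_len))
        assert found is None


class TestRolesAndIRs:
    def test_roles_and_irs_match_generator_truth(self):
        g, truth = generate_genome(GenomeSpec(seed=33),
                                   apply_rotation=False)
        orfs = enumerate_orfs(g, 1, STARTS, min_aa=100)
        rep, cp, irs = assign_roles(orfs, g)
        assert rep.region == truth.rep_region and rep.role == "rep"
        assert cp.region == truth.cp_region and cp.role == "cp"
        assert irs.ir5 == truth.ir5 and irs.ir3 == truth.ir3

    def test_ir3_absent_when_orfs_abut(self):
        g, truth = generate_genome(
            GenomeSpec(seed=4, ir3_len=0), apply_rotation=False)
        orfs = enumerate_orfs(g, 1, STARTS, min_aa=100)
        _, _, irs = assign_roles(orfs, g)
        assert irs.ir3 is None and truth.ir3 is None

    def test_missing_strand_is_flagged_not_fatal(self):
        g = CircularGenome("g", _random_seq(9, 600))
        sense_only = [o for o in enumerate_orfs(g, 1, STARTS, 10)
                      if o.strand == VIRION_SENSE]
        rep, cp, irs = assign_roles(sense_only, g)
        assert rep is None and irs.ir5 is None


class TestCompareCodes:
    def test_constructed_mismatch_count(self):
        # AGA (R/S), ATA (I/M), AGG (R/S) differ; GGG agrees
        g = CircularGenome("g", "ATGAGAATAAGGGGGTAA" + "C" * 30)
        region = GenomeRegion(1, 18, VIRION_SENSE)
        assert compare_code_translations(g, region, (1, 5)) == 3

    def test_zero_when_no_divergent_codons(self):
        g = CircularGenome("g", "ATGGGGCCCTTTTAA" + "C" * 30)
        assert compare_code_translations(
            g, GenomeRegion(1, 15, VIRION_SENSE), (1, 5)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_codon_oracle(self, seed):
        rng = np.random.default_rng((5, seed))
        t1, t5 = get_table(1), get_table(5)
        shared = [c for c in t1.forward
                  if c not in t1.stop_codons and c not in t5.stop_codons]
        codons = [shared[i] for i in
                  rng.integers(len(shared), size=60)]
        cds = "ATG" + "".join(codons) + "TAA"
        g = CircularGenome("g", cds + "CCCC")
        region = GenomeRegion(1, len(cds), VIRION_SENSE)
        got = compare_code_translations(g, region, (1, 5))
        expected = sum(t1.aa(c) != t5.aa(c) for c in codons)
        assert got == expected
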