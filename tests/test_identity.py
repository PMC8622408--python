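import numpy as np
import pytest

from cresscan.genome_io import revcomp
from cresscan.identity import (IdentityMatrix, demarcate_species,
                               global_align, identity_matrix,
                               pairwise_identity)
from cresscan.synthetic import GenomeSpec, generate_genome, mutate

from _oracles import oracle_components


def _rand(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


class TestAlignAndIdentity:
    def test_identical_sequences_align_without_gaps(self):
        a, b = global_align("ACGT", "ACGT")
        assert a == b == "ACGT"
        assert pairwise_identity((a, b)) == 100.0

    def test_single_deletion_example(self):
        # exhaustive check over alignments of these strings gives one
        # gap column and three identities
        a, b = global_align("ACGT", "ACT")
        assert len(a) == 4 and b.count("-") == 1
        assert sum(x == y for x, y in zip(a, b)) == 3
        assert pairwise_identity((a, b)) == 75.0
        assert pairwise_identity((a, b), mode="ungapped") == 100.0

    def test_point_difference_analytic(self):
        a, b = global_align("AAAAAAAAAA", "AAAAACAAAA")
        assert pairwise_identity((a, b)) == 90.0

    def test_terminal_gaps_excluded_from_denominator(self):
        assert pairwise_identity(("--ACGT", "GGACGT")) == 100.0

    def test_n_counts_as_mismatch(self):
        assert pairwise_identity(("AANA", "AANA")) == 75.0

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError):
            global_align("ACGT", "MKLWEF")

    @pytest.mark.parametrize("seed", range(8))
    def test_symmetry_and_revcomp_invariance(self, seed):
        a = _rand((seed, 0), 150)
        b = mutate_seq(a, 0.1, seed)
        id_ab = pairwise_identity(global_align(a, b))
        id_ba = pairwise_identity(global_align(b, a))
        assert id_ab == pytest.approx(id_ba, abs=1e-9)
        id_rc = pairwise_identity(global_align(revcomp(a), revcomp(b)))
        assert id_ab == pytest.approx(id_rc, abs=1e-9)

    def test_optimal_score_beats_sampled_alignments(self):
        from cresscan.identity import make_aligner
        a, b = _rand(3, 60), _rand(4, 55)
        al = make_aligner("nt")
        best = al.align(a, b).score
        rng = np.random.default_rng(0)
        for _ in range(20):
            # random alignment: pad the shorter with gaps at random spots
            bb = list(b)
            while len(bb) < len(a):
                bb.insert(int(rng.integers(len(bb) + 1)), "-")
            score = sum(
                al.substitution_matrix[x, y] if "-" not in (x, y)
                else al.open_gap_score
                for x, y in zip(a, bb))
            assert best >= score


def mutate_seq(seq, rate, seed):
    from cresscan.genome_io import CircularGenome
    return mutate(CircularGenome("t", seq), rate, seed).seq


class TestMatrix:
    def test_matrix_is_symmetric_with_unit_diagonal(self):
        seqs = {f"s{i}": _rand(i, 200) for i in range(4)}
        m = identity_matrix(seqs)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            identity_matrix([("a", "ACGT"), ("a", "ACGT")])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            identity_matrix({"a": "ACGT"})

    def test_tsv_round_trip(self, tmp_path):
        m = identity_matrix({"a": _rand(1, 100), "b": _rand(2, 100),
                             "c": _rand(3, 100)})
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = IdentityMatrix.from_tsv(p)
        assert back.labels == m.labels
        assert np.allclose(back.values, m.values, atol=5e-4)


class TestDemarcation:
    def test_threshold_zero_gives_one_cluster(self):
        m = identity_matrix({"a": _rand(1, 150), "b": _rand(2, 150),
                             "c": _rand(3, 150)})
        assert demarcate_species(m, threshold=1e-9).n_clusters == 1

    def test_threshold_100_separates_non_identical(self):
        m = identity_matrix({"a": _rand(1, 150), "b": _rand(2, 150)})
        assert demarcate_species(m, threshold=100.0).n_clusters == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_graph_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        v = rng.uniform(0, 100, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        labels = [f"g{i}" for i in range(n)]
        thr = float(rng.uniform(20, 95))
        got = demarcate_species(IdentityMatrix(labels, v), thr)
        groups = {}
        for lab, c in got.clusters.items():
            groups.setdefault(c, set()).add(lab)
        assert {frozenset(s) for s in groups.values()} \
            == oracle_components(labels, v, thr)

    @pytest.mark.parametrize("seed", range(8))
    def test_raising_threshold_never_merges(self, seed):
        rng = np.random.default_rng((7, seed))
        n = 6
        v = rng.uniform(0, 100, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        m = IdentityMatrix([f"g{i}" for i in range(n)], v)
        lo = demarcate_species(m, 40.0).clusters
        hi = demarcate_species(m, 75.0).clusters
        # higher-threshold clusters refine lower-threshold ones
        for a in m.labels:
            for b in m.labels:
                if hi[a] == hi[b]:
                    assert lo[a] == lo[b]


def test_mutation_identity_calibration_small():
    """Parent-vs-mutant identity tracks the analytic expectation
    100*(1-r) under the uniform substitution model."""
    g, _ = generate_genome(GenomeSpec(seed=0), apply_rotation=False)
    for rate in (0.02, 0.10):
        ids = []
        for s in range(20):
            m = mutate(g, rate, seed=(s, int(rate * 1000)))
            ids.append(pairwise_identity(global_align(g.seq, m.seq)))
        assert abs(np.mean(ids) - 100 * (1 - rate)) <= 1.5
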