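"""Motif and protein similarity, clustering, networks, k-mer enrichment."""

import numpy as np
import pytest

from selexmotif.io import CycleReads
from selexmotif.pwm import PWM
from selexmotif.similarity import (
    SimilarityMatrix,
    aa_similarity_score,
    cluster_motifs,
    gapped_kmer_score_vector,
    kmer_enrichment_table,
    kmer_log_odds,
    motif_network,
    motif_similarity,
    motif_similarity_matrix,
    tree_leaf_order,
)
from selexmotif.simulate import pwm_from_consensus

from oracle_utils import oracle_local_alignment


def make_pwm(consensus, p=0.9, name="m"):
    f = pwm_from_consensus(consensus, p)
    return PWM(counts=f, frequencies=f, name=name)


class TestScoreVector:
    def test_uniform_pwm_all_entries_equal(self):
        f = np.full((4, 8), 0.25)
        v = gapped_kmer_score_vector(PWM(counts=f, frequencies=f), 6, 3)
        assert np.allclose(v.values, v.values[0])

    def test_revcomp_invariance_exact(self):
        pwm = make_pwm("GGATTAnnC", 0.85)
        v1 = gapped_kmer_score_vector(pwm, 6, 4).values
        v2 = gapped_kmer_score_vector(pwm.reverse_complement(), 6, 4).values
        np.testing.assert_array_equal(v1, v2)

    def test_one_hot_top_kmer_is_consensus(self):
        pwm = make_pwm("GACGTC", 1.0)
        v = gapped_kmer_score_vector(pwm, 6, 2).values
        top = int(np.argmax(v[:4096]))  # ungapped block
        s = ""
        for _ in range(6):
            s = "ACGT"[top % 4] + s
            top //= 4
        # strand-max scoring: consensus or its reverse complement wins
        assert s in ("GACGTC", "GACGTC"[::-1].translate(
            str.maketrans("ACGT", "TGCA")))

    def test_narrow_pwm_rejected(self):
        with pytest.raises(ValueError):
            gapped_kmer_score_vector(make_pwm("ACGT"), 6, 1)


class TestMotifSimilarity:
    def test_self_similarity_is_one(self):
        pwm = make_pwm("TGACGTCA", 0.85)
        assert motif_similarity(pwm, pwm, 6, 3) == pytest.approx(1.0)

    def test_revcomp_similarity_is_one(self):
        pwm = make_pwm("GGATGT", 0.85)
        assert motif_similarity(pwm, pwm.reverse_complement(), 6, 3) == (
            pytest.approx(1.0))

    def test_unrelated_motifs_low_similarity(self):
        a = make_pwm("GACGTCAA", 0.95)
        b = make_pwm("TTTAGGGC", 0.95)
        assert abs(motif_similarity(a, b, 6, 2)) < 0.5

    def test_degenerate_motif_errors(self):
        f = np.full((4, 7), 0.25)
        with pytest.raises(ValueError):
            motif_similarity(PWM(counts=f, frequencies=f), make_pwm("GACGTCA"))

    def test_matrix_symmetric_unit_diagonal(self):
        pwms = [make_pwm(c, 0.9, c) for c in ("GACGTC", "TAATTA", "GGGGCC")]
        m = motif_similarity_matrix(pwms, 6, 2)
        np.testing.assert_allclose(m.matrix, m.matrix.T)
        np.testing.assert_allclose(np.diag(m.matrix), 1.0)


class TestAASimilarity:
    def test_identical_sequences_return_self_score(self):
        # BLOSUM62 diagonal: M5 K5 V4 L4 A4 A4 = 26; L=n, shorter=n -> S
        assert aa_similarity_score("MKVLAA", "MKVLAA") == pytest.approx(26.0)

    def test_formula_arithmetic(self):
        # identical sequences: L = len = shorter, so the formula collapses to
        # the raw self-alignment score (sum of BLOSUM62 diagonal entries)
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        seq = "HEAGAWGHEE"
        self_score = sum(blosum[c, c] for c in seq)
        assert aa_similarity_score(seq, seq) == pytest.approx(self_score)

    def test_against_dp_oracle(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        pairs = [("MKVLAAGICK", "MKVAAGICK"), ("HEAGAWGHEE", "PAWHEAE"),
                 ("ACDEFGHIK", "ACDFGHIK")]
        for a, b in pairs:
            want = oracle_local_alignment(a, b, blosum, 11, 1)
            from selexmotif.similarity import _make_aligner

            got = _make_aligner().align(a, b)[0].score
            assert got == pytest.approx(want)

    def test_multi_domain_modes(self):
        doms1 = ["MKVLAA", "HEAGAWGHEE"]
        doms2 = ["MKVLAA"]
        best = aa_similarity_score(doms1, doms2, mode="max_domain")
        assert best == pytest.approx(26.0)
        concat = aa_similarity_score(doms1, doms2, mode="concatenate")
        assert concat > 0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            aa_similarity_score("", "MKV")


class TestClustering:
    def test_identical_pair_merges_first(self):
        m = SimilarityMatrix(
            ids=["a", "b", "c"],
            matrix=np.array([[1.0, 1.0, 0.1],
                             [1.0, 1.0, 0.1],
                             [0.1, 0.1, 1.0]]),
        )
        newick = cluster_motifs(m)
        order = tree_leaf_order(newick)
        assert set(order) == {"a", "b", "c"}
        ab = {order[i] for i in range(2)} if order[0] != "c" else set(order[1:])
        assert ab == {"a", "b"}

    def test_three_by_three_hand_computed_heights(self):
        """Average linkage on euclidean row distances, checked against a
        hand computation."""
        M = np.array([[1.0, 0.8, 0.0],
                      [0.8, 1.0, 0.0],
                      [0.0, 0.0, 1.0]])
        rows = M
        d_ab = np.linalg.norm(rows[0] - rows[1])          # ~0.2828
        d_ac = np.linalg.norm(rows[0] - rows[2])
        d_bc = np.linalg.norm(rows[1] - rows[2])
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        Z = hierarchy.linkage(pdist(rows), method="average")
        assert Z[0, 2] == pytest.approx(d_ab)
        assert Z[1, 2] == pytest.approx((d_ac + d_bc) / 2)
        # and the tree serialization carries the same topology
        newick = cluster_motifs(SimilarityMatrix(ids=["a", "b", "c"], matrix=M))
        order = tree_leaf_order(newick)
        assert order.index("c") in (0, 2)

    def test_leaf_set_conserved(self):
        ids = ["m1", "m2", "m3", "m4"]
        rng = np.random.default_rng(5)
        A = rng.random((4, 4))
        M = (A + A.T) / 2
        np.fill_diagonal(M, 1.0)
        newick = cluster_motifs(SimilarityMatrix(ids=ids, matrix=M))
        assert sorted(tree_leaf_order(newick)) == sorted(ids)

    def test_nan_rejected(self):
        M = np.eye(2)
        M[0, 1] = M[1, 0] = np.nan
        with pytest.raises(ValueError):
            cluster_motifs(SimilarityMatrix(ids=["a", "b"], matrix=M))

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        A = rng.random((5, 5))
        M = (A + A.T) / 2
        np.fill_diagonal(M, 1.0)
        sm = SimilarityMatrix(ids=list("abcde"), matrix=M)
        assert cluster_motifs(sm) == cluster_motifs(sm)


class TestNetwork:
    def setup_method(self):
        self.m = SimilarityMatrix(
            ids=["a", "b", "c", "d"],
            matrix=np.array([
                [1.0, 0.9, 0.1, 0.1],
                [0.9, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.85],
                [0.1, 0.1, 0.85, 1.0],
            ]),
        )

    def test_high_threshold_no_edges(self):
        g = motif_network(self.m, 0.95)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 4  # isolated nodes retained

    def test_low_threshold_complete_graph(self):
        g = motif_network(self.m, 0.0)
        assert g.number_of_edges() == 4 * 3 // 2

    def test_two_planted_clusters_two_components(self):
        import networkx as nx

        g = motif_network(self.m, 0.5)
        comps = list(nx.connected_components(g))
        assert sorted(map(sorted, comps)) == [["a", "b"], ["c", "d"]]


class TestKmerEnrichment:
    def test_identical_cycles_zero_log_odds(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(200)]
        early = CycleReads("e", 0, reads)
        late = CycleReads("e", 3, list(reads))
        lo = kmer_log_odds(early, late, k=4)
        np.testing.assert_allclose(lo, 0.0, atol=1e-12)

    def test_quadrupled_count_log_odds_two(self):
        """With equal totals and counts >> pseudocounts, a 4x count change
        gives log-odds ~2."""
        n = 4096
        base = ["AAAATTTT"] * n
        early = CycleReads("e", 0, base + ["ACGTACGT"] * 256)
        late = CycleReads("e", 3, base + ["ACGTACGT"] * 1024)
        k = 8
        lo_e = kmer_log_odds(early, late, k=k)
        code = 0
        for c in "ACGTACGT":
            code = code * 4 + "ACGT".index(c)
        # totals differ slightly; correct for them
        ne = len(early.reads)
        nl = len(late.reads)
        expect = np.log2((1024 + 1) / (nl + 4**k)) - np.log2(
            (256 + 1) / (ne + 4**k))
        assert lo_e[code] == pytest.approx(expect)
        assert lo_e[code] == pytest.approx(2.0, abs=0.1)

    def test_table_structure_and_pwm_scores(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(100)]
        expr = (CycleReads("a", 0, reads), CycleReads("a", 3, reads))
        df = kmer_enrichment_table(expr, expr, k=6,
                                   pwm_a=make_pwm("GACGTC", 0.9))
        assert {"kmer", "log_odds_a", "log_odds_b", "pwm_score_a"} <= set(
            df.columns)
        assert (df["log_odds_a"] == df["log_odds_b"]).all()

    def test_k_larger_than_reads_errors(self):
        e = CycleReads("a", 0, ["ACGT"])
        with pytest.raises(ValueError):
            kmer_log_odds(e, e, k=10)
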