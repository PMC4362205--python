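"""Gapped patterns, Huddinge distance, neighbors, and counting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selexmotif.patterns import (
    GappedPattern,
    PatternBounds,
    PatternError,
    canonical_strand,
    count_patterns,
    enumerate_patterns,
    huddinge_distance,
    huddinge_neighbors,
    parse_pattern,
    revcomp,
    revcomp_pattern,
)

from oracle_utils import (
    all_patterns,
    oracle_count,
    oracle_distance,
    strand_canonical,
)

pattern_text = st.text(alphabet="ACGTn", min_size=1, max_size=8).filter(
    lambda s: s.strip("n")
)


class TestParsing:
    @pytest.mark.parametrize(
        "text,symbols,n_def,gap",
        [
            ("ACnGT", "ACnGT", 4, 1),
            ("nACGTn", "ACGT", 4, 0),
            ("AnnC", "AnnC", 2, 2),
            ("A", "A", 1, 0),
        ],
    )
    def test_canonicalization(self, text, symbols, n_def, gap):
        p = parse_pattern(text)
        assert (p.symbols, p.n_defined, p.gap_len) == (symbols, n_def, gap)

    @pytest.mark.parametrize("bad", ["", "nnn", "ACXT", "acgt"])
    def test_rejects_invalid(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad)

    def test_revcomp_examples(self):
        assert revcomp_pattern(parse_pattern("AACG")).symbols == "CGTT"
        assert revcomp_pattern(parse_pattern("ACGT")).symbols == "ACGT"

    @given(pattern_text)
    @settings(deadline=None)
    def test_revcomp_involution(self, text):
        p = parse_pattern(text)
        assert revcomp_pattern(revcomp_pattern(p)) == p


class TestHuddingeDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "ACGA", 1),   # single substitution
            ("ACGT", "ACG", 1),    # one base shorter
            ("ACGTA", "TACGT", 1), # one-position shift sharing 4 bases
            ("ACnGT", "ACnGT", 0),
        ],
    )
    def test_anchors(self, a, b, expected):
        d = huddinge_distance(parse_pattern(a), parse_pattern(b), "forward_only")
        assert d == expected

    def test_gapped_shift_neighbors_are_at_distance_two(self):
        """One-position shifts of a gapped subsequence (gap shape preserved,
        overlap bases copied from the common underlying sequence, exposed
        bases free) sit at distance exactly 2; the ungapped control reaches 1.
        """
        def one_shift_variants(sym):
            span = len(sym)
            for s in (-1, 1):
                tmpl = []
                for i in range(span):
                    j = s + i
                    if sym[i] == "n":
                        tmpl.append("n")
                    elif 0 <= j < span and sym[j] != "n":
                        tmpl.append(sym[j])
                    else:
                        tmpl.append("*")
                stars = tmpl.count("*")
                for combo in itertools.product("ACGT", repeat=stars):
                    it = iter(combo)
                    yield "".join(next(it) if c == "*" else c for c in tmpl)

        p = parse_pattern("ACnGT")
        dists = {
            huddinge_distance(p, parse_pattern(q))
            for q in one_shift_variants(p.symbols)
        }
        assert dists == {2}
        u = parse_pattern("ACGT")
        assert min(
            huddinge_distance(u, parse_pattern(q), "forward_only")
            for q in one_shift_variants(u.symbols)
        ) == 1

    def test_exhaustive_small_bounds_vs_oracle(self):
        """Exact agreement with the sparse-set brute-force oracle on all
        pattern pairs with <=4 defined bases and gap <=1."""
        space = sorted(set(all_patterns(1, 4, 1)))
        pats = [parse_pattern(s) for s in space]
        for i in range(len(space)):
            for j in range(i, len(space)):
                d_impl = huddinge_distance(pats[i], pats[j], "forward_only")
                d_or = oracle_distance(space[i], space[j], merge=False)
                assert d_impl == d_or, (space[i], space[j])

    def test_sampled_pairs_full_bounds_vs_oracle(self, rng):
        """Seeded random pairs from the <=6-defined / gap<=2 space, both
        strand policies, against the oracle."""
        space = all_patterns(1, 6, 2)
        idx = rng.integers(0, len(space), size=(2000, 2))
        for i, j in idx:
            a, b = space[i], space[j]
            pa, pb = parse_pattern(a), parse_pattern(b)
            assert huddinge_distance(pa, pb, "merge") == oracle_distance(a, b, True)
            assert huddinge_distance(pa, pb, "forward_only") == oracle_distance(
                a, b, False
            )

    @given(pattern_text, pattern_text)
    @settings(deadline=None, max_examples=200)
    def test_metric_properties(self, t1, t2):
        p1, p2 = parse_pattern(t1), parse_pattern(t2)
        d12 = huddinge_distance(p1, p2)
        assert d12 == huddinge_distance(p2, p1)
        assert d12 >= 0
        same = canonical_strand(p1) == canonical_strand(p2)
        assert (d12 == 0) == same


class TestNeighbors:
    def test_substitution_class_included(self):
        p = parse_pattern("ACGT")
        nb = huddinge_neighbors(p, max_defined=5, max_gap=1,
                                strand_policy="forward_only")
        subs = {
            p.symbols[:i] + b + p.symbols[i + 1:]
            for i in range(4)
            for b in "ACGT"
            if b != p.symbols[i]
        }
        assert len(subs) == 12
        assert subs <= {q.symbols for q in nb}

    def test_shift_class_included(self):
        nb = {q.symbols for q in huddinge_neighbors(
            parse_pattern("ACGT"), max_defined=5, max_gap=1,
            strand_policy="forward_only")}
        assert "CGTA" in nb and "TACG" in nb  # offset-one, 3 shared bases

    @pytest.mark.parametrize("sym", ["ACGT", "ACnGT", "AnnC", "GCGTG"])
    @pytest.mark.parametrize("policy", ["forward_only", "merge"])
    def test_completeness_vs_enumeration(self, sym, policy):
        """Neighbor sets equal brute-force {q : d(p,q)=1} over the bounded
        pattern space."""
        p = parse_pattern(sym)
        max_def, max_gap = 5, 2
        if p.n_defined >= 5:
            max_def = p.n_defined + 1
        got = {
            q.symbols
            for q in huddinge_neighbors(
                p, max_defined=max_def, max_gap=max_gap, strand_policy=policy
            )
        }
        merge = policy == "merge"
        expected = set()
        for s in all_patterns(1, max_def, max_gap):
            if oracle_distance(p.symbols, s, merge) == 1:
                expected.add(strand_canonical(s) if merge else s)
        assert got == expected

    def test_every_neighbor_at_distance_one(self):
        p = parse_pattern("TAATnnATTA")
        for q in huddinge_neighbors(p, max_defined=12, max_gap=4):
            assert huddinge_distance(p, q) == 1

    def test_bounds_violation_raises(self):
        with pytest.raises(PatternError):
            huddinge_neighbors(parse_pattern("ACGTAC"), max_defined=4, max_gap=0)


class TestCounting:
    def test_spec_examples(self):
        t = count_patterns(["ACGTACGT"], PatternBounds(4, 4, 0),
                           "per_occurrence", "forward_only")
        assert t.count(parse_pattern("ACGT")) == 2
        t = count_patterns(["ACGTACGT"], PatternBounds(4, 4, 0),
                           "per_read", "forward_only")
        assert t.count(parse_pattern("ACGT")) == 1
        t = count_patterns(["CGTT"], PatternBounds(4, 4, 0), "per_read", "merge")
        assert t.count(parse_pattern("AACG")) == 1  # reverse-strand hit

    @pytest.mark.parametrize("mode", ["per_read", "per_occurrence"])
    @pytest.mark.parametrize("policy", ["merge", "forward_only"])
    def test_counts_match_scanning_oracle(self, rng, mode, policy):
        reads = [
            "".join(rng.choice(list("ACGT"), size=12)) for _ in range(60)
        ]
        bounds = PatternBounds(2, 4, 1)
        t = count_patterns(reads, bounds, mode, policy)
        # every counted pattern agrees with the brute-force scan
        for p, c in list(t.counts.items())[::7]:
            assert c == oracle_count(reads, p.symbols, mode == "per_read",
                                     policy == "merge"), p.symbols
        # and patterns absent from the table genuinely never occur
        for s in ["AAnTT", "GGGG", "CnAC"]:
            want = oracle_count(reads, s, mode == "per_read", policy == "merge")
            key = s if policy == "forward_only" else strand_canonical(s)
            got = t.count(parse_pattern(key))
            assert got == want

    def test_containment_monotonicity_per_occurrence(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(80)]
        t = count_patterns(reads, PatternBounds(2, 4, 0), "per_occurrence",
                           "forward_only")
        for p, c in t.counts.items():
            if p.n_defined >= 3 and p.gap_len == 0:
                parent = parse_pattern(p.symbols[:-1])
                assert t.count(parent) >= c

    def test_strand_merge_symmetry(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(50)]
        t = count_patterns(reads, PatternBounds(3, 4, 1), "per_read", "merge")
        for p in list(t.counts)[::11]:
            assert t.count(p) == t.count(revcomp_pattern(p))

    def test_empty_input(self):
        t = count_patterns([], PatternBounds(2, 3, 0))
        assert t.counts == {} and t.total_reads == 0

    def test_enumerate_matches_oracle_space(self):
        b = PatternBounds(2, 3, 1)
        assert {p.symbols for p in enumerate_patterns(b)} == set(
            all_patterns(2, 3, 1)
        )
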