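"""The Huddinge distance on gapped patterns, and why shifts of gapped
subsequences are farther away than shifts of ungapped ones.

d(p, q) = d - a: d is the larger defined-base count, a the best rigid
alignment's number of matching defined bases (no new gaps allowed).
"""

from selexmotif import huddinge_distance, huddinge_neighbors, parse_pattern

pairs = [
    ("ACGT", "ACGT"),    # identity
    ("ACGT", "ACGA"),    # substitution
    ("ACGT", "ACG"),     # truncation
    ("ACGTA", "TACGT"),  # one-position shift, 4 shared bases
    ("ACnGT", "CAnTG"),  # gapped pattern vs its one-position shift
]
for a, b in pairs:
    d = huddinge_distance(parse_pattern(a), parse_pattern(b), "forward_only")
    print(f"d({a}, {b}) = {d}")

p = parse_pattern("ACGT")
nb = huddinge_neighbors(p, max_defined=5, max_gap=1)
by_len = {}
for q in nb:
    by_len.setdefault(q.n_defined, []).append(q.symbols)
print(f"\n{len(nb)} Huddinge-1 neighbors of ACGT within (<=5 defined, gap<=1):")
for k in sorted(by_len):
    print(f"  {k} defined bases: {len(by_len[k])} patterns, "
          f"e.g. {sorted(by_len[k])[:4]}")
# Substitutions, shifts, truncations and extensions are all one step away;
# a shifted *gapped* pattern is two steps away, which is why Autoseed never
# confuses a gapped site with its own shift.
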