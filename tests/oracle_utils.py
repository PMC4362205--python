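"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive: patterns are handled as sparse
(position, base) sets, alignments enumerated literally, and counts tallied
with double loops, so these functions share no code path with the package.
"""

from __future__ import annotations

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "n": "n"}


def rc(sym: str) -> str:
    return "".join(_COMP[c] for c in reversed(sym))


def defined_set(sym: str) -> set[tuple[int, str]]:
    return {(i, c) for i, c in enumerate(sym) if c != "n"}


def oracle_distance(s1: str, s2: str, merge: bool = True) -> int:
    """Huddinge distance via sparse-set alignment enumeration."""

    def best_align(a: str, b: str) -> int:
        sa, sb = defined_set(a), defined_set(b)
        best = 0
        for shift in range(-len(b), len(a) + 1):
            shifted = {(i + shift, c) for i, c in sb}
            best = max(best, len(sa & shifted))
        return best

    d = max(len(defined_set(s1)), len(defined_set(s2)))
    a = best_align(s1, s2)
    if merge:
        a = max(a, best_align(s1, rc(s2)))
    return d - a


def all_patterns(min_defined: int, max_defined: int, max_gap: int) -> list[str]:
    """Every canonical single-gap pattern string within bounds."""
    out = []
    for k in range(min_defined, max_defined + 1):
        for bases in product("ACGT", repeat=k):
            out.append("".join(bases))
            if k >= 2:
                for g in range(1, max_gap + 1):
                    for s in range(1, k):
                        out.append("".join(bases[:s]) + "n" * g + "".join(bases[s:]))
    return out


def strand_canonical(sym: str) -> str:
    """Lexicographically smaller of pattern/revcomp with A<C<G<T<n."""
    rank = {b: i for i, b in enumerate("ACGTn")}
    r = rc(sym)
    for a, b in zip(sym, r):
        if rank[a] != rank[b]:
            return sym if rank[a] < rank[b] else r
    return sym


def oracle_occurrences(read: str, sym: str) -> int:
    """Number of positions where the pattern's defined bases match the read."""
    span = len(sym)
    hits = 0
    for i in range(len(read) - span + 1):
        if all(c == "n" or read[i + j] == c for j, c in enumerate(sym)):
            hits += 1
    return hits


def oracle_count(reads: list[str], sym: str, per_read: bool, merge: bool) -> int:
    """Strand-merged pattern count by direct scanning."""
    syms = [sym]
    if merge and rc(sym) != sym:
        syms.append(rc(sym))
    total = 0
    for read in reads:
        occ = sum(oracle_occurrences(read, s) for s in syms)
        total += min(occ, 1) if per_read else occ
    return total


def oracle_multinomial(
    reads: list[str], seed: str, order: int, flank: int, merge: bool = True
) -> "list[list[float]]":
    """Double-loop multinomial matrix (best window per read, then per-cell rule)."""
    span = len(seed)
    w = span + 2 * flank
    out = [[0.0] * w for _ in range(4)]
    bidx = {b: i for i, b in enumerate("ACGT")}
    for read in reads:
        # best window: max matching defined bases; leftmost, then forward
        best = None
        for pos in range(len(read) - span + 1):
            for strand, s in ((0, seed), (1, rc(seed))):
                m = sum(
                    1
                    for j, c in enumerate(s)
                    if c != "n" and read[pos + j] == c
                )
                key = (-m, pos, strand)
                if best is None or key < best[0]:
                    best = (key, pos, strand)
        _, pos, strand = best
        window = []
        for i in range(-flank, span + flank):
            p = pos + i
            window.append(read[p] if 0 <= p < len(read) else None)
        if strand == 1:
            window = [(_COMP[c] if c else None) for c in reversed(window)]
        seed_full = ["n"] * flank + list(seed) + ["n"] * flank
        mism = [
            int(
                seed_full[i] != "n"
                and window[i] is not None
                and window[i] != seed_full[i]
            )
            for i in range(w)
        ]
        for i in range(w):
            if window[i] is None:
                continue
            others = sum(mism) - mism[i]
            if others <= order - 1:
                out[bidx[window[i]]][i] += 1
    return out


def oracle_pair_tally(windows: list[str]) -> dict:
    """4x4 joint counts for every position pair, by double loop."""
    bidx = {b: i for i, b in enumerate("ACGT")}
    w = len(windows[0])
    tabs = {}
    for i in range(w):
        for j in range(i + 1, w):
            t = [[0] * 4 for _ in range(4)]
            for win in windows:
                t[bidx[win[i]]][bidx[win[j]]] += 1
            tabs[(i, j)] = t
    return tabs


def oracle_local_alignment(a: str, b: str, matrix, gap_open: int, gap_extend: int):
    """Smith-Waterman with affine gaps (Gotoh), returning the best score."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
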