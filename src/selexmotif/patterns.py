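"""Gapped subsequences, the Huddinge distance, and strand-merged pattern counting.

The unit object here is a *gapped pattern*: a short subsequence over ``{A,C,G,T}``
in which some internal positions are undefined (written ``n``).  A pattern such
as ``ACnGT`` has four *defined* bases and a single-position gap.  Patterns are
the substrate for seed discovery: each one is counted in a pool of SELEX reads,
and seeds are patterns whose counts dominate their neighborhood under the
Huddinge distance.

The Huddinge distance between two patterns is ``d - a`` where ``d`` is the
maximum number of defined bases in either pattern and ``a`` is the maximum
number of defined bases that can be aligned as perfect matches when the two
patterns are slid rigidly against each other (no new gaps may be introduced).
It is 0 exactly for identical patterns, 1 for single substitutions, single
extensions/truncations and single-offset shifts of ungapped patterns, and ≥2
for shifts of gapped patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Literal

import numpy as np

BASES = "ACGT"
GAP = "n"
_ALPHABET = set(BASES + GAP)
_COMPLEMENT = str.maketrans("ACGTn", "TGCAn")

# Lexicographic symbol order used for strand-canonical forms: A < C < G < T < n.
_SYM_RANK = {b: i for i, b in enumerate(BASES + GAP)}

StrandPolicy = Literal["merge", "forward_only"]
CountingMode = Literal["per_read", "per_occurrence"]


class PatternError(ValueError):
    """Raised for syntactically invalid gapped patterns."""


@dataclass(frozen=True, order=True)
class GappedPattern:
    """A canonical gapped subsequence over ``{A,C,G,T,n}``.

    Canonical means both ends are defined bases (edge ``n`` carries no
    information and is stripped by :func:`parse_pattern`).
    """

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols
        if not s or not set(s) <= _ALPHABET:
            raise PatternError(f"illegal pattern {s!r}")
        if s[0] == GAP or s[-1] == GAP:
            raise PatternError(f"non-canonical pattern {s!r}: undefined edge position")

    @property
    def span(self) -> int:
        return len(self.symbols)

    @property
    def n_defined(self) -> int:
        return self.span - self.symbols.count(GAP)

    @property
    def gap_len(self) -> int:
        return self.symbols.count(GAP)

    @property
    def gap_runs(self) -> int:
        runs = 0
        prev = ""
        for c in self.symbols:
            if c == GAP and prev != GAP:
                runs += 1
            prev = c
        return runs

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.symbols


def parse_pattern(text: str) -> GappedPattern:
    """Parse ``text`` into a canonical :class:`GappedPattern`.

    Leading/trailing ``n`` symbols are stripped (``nACGTn`` → ``ACGT``); at
    least one defined base is required.
    """
    if not text:
        raise PatternError("empty pattern")
    if not set(text) <= _ALPHABET:
        bad = sorted(set(text) - _ALPHABET)
        raise PatternError(f"illegal symbol(s) {bad} in pattern {text!r}")
    stripped = text.strip(GAP)
    if not stripped:
        raise PatternError(f"pattern {text!r} has no defined bases")
    return GappedPattern(stripped)


def revcomp(seq: str) -> str:
    """Reverse complement of a base string (``n`` maps to ``n``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_pattern(p: GappedPattern) -> GappedPattern:
    return GappedPattern(revcomp(p.symbols))


def canonical_strand(p: GappedPattern) -> GappedPattern:
    """The lexicographically smaller of a pattern and its reverse complement.

    Symbol order is A < C < G < T < n, so e.g. ``AnT`` < ``AnnT`` < ``CA``.
    Used as the representative when forward and reverse occurrences are merged.
    """
    rc = revcomp(p.symbols)
    fwd = p.symbols
    if len(rc) != len(fwd):  # spans always equal; guard anyway
        return p
    for a, b in zip(fwd, rc):
        if _SYM_RANK[a] != _SYM_RANK[b]:
            return p if _SYM_RANK[a] < _SYM_RANK[b] else GappedPattern(rc)
    return p


def _aligned_matches(s1: str, s2: str) -> int:
    """Max number of positions with equal defined bases over all rigid offsets."""
    best = 0
    for off in range(-(len(s2) - 1), len(s1)):
        m = 0
        for j, c2 in enumerate(s2):
            i = off + j
            if 0 <= i < len(s1) and c2 != GAP and s1[i] == c2:
                m += 1
        if m > best:
            best = m
    return best


def huddinge_distance(
    p1: GappedPattern, p2: GappedPattern, strand_policy: StrandPolicy = "merge"
) -> int:
    """Huddinge distance ``d - a`` between two gapped patterns.

    ``d`` is the larger defined-base count; ``a`` the best rigid-alignment
    match count.  With ``strand_policy="merge"`` the minimum over ``p2`` and
    its reverse complement is returned, so the metric agrees with
    strand-merged counting.
    """
    d = max(p1.n_defined, p2.n_defined)
    a = _aligned_matches(p1.symbols, p2.symbols)
    if strand_policy == "merge":
        a = max(a, _aligned_matches(p1.symbols, revcomp(p2.symbols)))
    return d - a


def _canonical_or_none(raw: list[str], max_gap_runs: int) -> GappedPattern | None:
    s = "".join(raw).strip(GAP)
    if not s:
        return None
    p = GappedPattern(s)
    if p.gap_runs > max_gap_runs:
        return None
    return p


def huddinge_neighbors(
    p: GappedPattern,
    max_defined: int = 10,
    max_gap: int = 10,
    min_defined: int = 1,
    strand_policy: StrandPolicy = "merge",
    max_gap_runs: int = 1,
) -> set[GappedPattern]:
    """All patterns at Huddinge distance exactly 1 from ``p`` within bounds.

    Candidates are generated by structural edits — delete one defined base,
    add one defined base (in the gap, at the ends, or beyond the ends creating
    a new edge gap), and delete-one-plus-add-one (substitutions and shifts) —
    then verified against :func:`huddinge_distance`.  With strand merging the
    returned set contains strand-canonical forms only.

    Any pattern ``q`` with ``d(p, q) = 1`` differs from ``p`` by at most one
    defined base once optimally aligned, so this edit family is exhaustive
    (property-checked against brute-force enumeration in the test suite).
    """
    if p.n_defined > max_defined or p.gap_len > max_gap:
        raise PatternError("pattern outside configured bounds")

    span = p.span
    reach = max_gap + 1  # farthest a new base may sit beyond an end
    candidates: set[GappedPattern] = set()

    def push(raw: list[str]) -> None:
        q = _canonical_or_none(raw, max_gap_runs)
        if q is None or q.symbols == p.symbols:
            return
        if not (min_defined <= q.n_defined <= max_defined and q.gap_len <= max_gap):
            return
        candidates.add(q)

    syms = list(p.symbols)
    defined_idx = [i for i, c in enumerate(syms) if c != GAP]

    def additions(base_raw: list[str], offset: int) -> Iterator[list[str]]:
        """Yield base_raw with one defined base added at every legal slot.

        ``offset`` is the index shift of base_raw relative to the extended
        coordinate frame [-reach, span+reach).
        """
        lo, hi = -reach, len(base_raw) - offset + reach
        for j in range(lo, hi):
            i = j + offset
            if 0 <= i < len(base_raw) and base_raw[i] != GAP:
                continue
            for b in BASES:
                if 0 <= i < len(base_raw):
                    raw = base_raw.copy()
                    raw[i] = b
                elif i < 0:
                    raw = [b] + [GAP] * (-i - 1) + base_raw
                else:
                    raw = base_raw + [GAP] * (i - len(base_raw)) + [b]
                yield raw

    # 1 gap run bound keeps the raw-edit space tiny; verification below is exact.
    # Deletions (shorter / shorter-with-gap classes).
    for i in defined_idx:
        raw = syms.copy()
        raw[i] = GAP
        push(raw)
    # Additions (longer class).
    for raw in additions(syms, 0):
        push(raw)
    # Delete one + add one (substitutions, shifts, gap moves).
    for i in defined_idx:
        dele = syms.copy()
        dele[i] = GAP
        for raw in additions(dele, 0):
            push(raw)

    out: set[GappedPattern] = set()
    for q in candidates:
        if huddinge_distance(p, q, strand_policy) != 1:
            continue
        out.add(canonical_strand(q) if strand_policy == "merge" else q)
    out.discard(canonical_strand(p) if strand_policy == "merge" else p)
    return out


# ---------------------------------------------------------------------------
# Pattern counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternBounds:
    """Bounds on the enumerated pattern space.

    Defaults follow desk-scale practice: 4–10 defined bases with a single
    internal gap of up to 10 positions.
    """

    min_defined: int = 4
    max_defined: int = 10
    max_gap: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.min_defined <= self.max_defined):
            raise ValueError("infeasible defined-base bounds")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")

    def shapes(self) -> Iterator[tuple[int, int, int]]:
        """Yield (n_defined, gap_len, gap_start) shapes; gap_start counts
        defined bases before the gap (so gaps are always internal)."""
        for k in range(self.min_defined, self.max_defined + 1):
            yield (k, 0, 0)
            if k >= 2:
                for g in range(1, self.max_gap + 1):
                    for s in range(1, k):
                        yield (k, g, s)


@dataclass
class PatternCountTable:
    """Occurrence counts of every in-bounds gapped pattern in one cycle's reads."""

    cycle: int
    counts: dict[GappedPattern, int]
    total_reads: int
    counting_mode: CountingMode
    strand_policy: StrandPolicy
    bounds: PatternBounds

    def count(self, p: GappedPattern) -> int:
        """Count of ``p`` (strand-adjusted when merging); 0 if never seen."""
        if self.strand_policy == "merge":
            p = canonical_strand(p)
        return self.counts.get(p, 0)

    def items_by_count(self) -> list[tuple[GappedPattern, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0].symbols))


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i

_DEC5 = np.array(list(BASES + GAP))


def encode_reads(reads: list[str]) -> np.ndarray:
    """Encode equal-length reads as an (n, L) uint8 array with A,C,G,T → 0..3."""
    if not reads:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(reads[0])
    if any(len(r) != L for r in reads):
        raise ValueError("reads must have identical length")
    flat = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    enc = _ENC[flat].reshape(len(reads), L)
    if (enc == 255).any():
        raise ValueError("reads contain non-ACGT characters")
    return enc


def _decode_codes(codes: np.ndarray, span: int) -> list[str]:
    digits = np.empty((codes.size, span), dtype=np.int64)
    c = codes.copy()
    for j in range(span - 1, -1, -1):
        digits[:, j] = c % 5
        c //= 5
    chars = _DEC5[digits]
    return ["".join(row) for row in chars]


def count_patterns(
    reads: Iterable[str],
    bounds: PatternBounds = PatternBounds(),
    counting_mode: CountingMode = "per_read",
    strand_policy: StrandPolicy = "merge",
    cycle: int = 0,
) -> PatternCountTable:
    """Count every in-bounds gapped pattern across a set of reads.

    A pattern matches at a read position when all of its defined bases equal
    the read there; gap positions are unconstrained.  With strand merging,
    forward and reverse-complement occurrences accumulate to the
    strand-canonical pattern.  In ``per_read`` mode (default) each read
    contributes at most once per pattern, damping PCR jackpots; in
    ``per_occurrence`` mode every window counts, which makes counts
    containment-monotone (a pattern's count is at least that of any extension).
    """
    reads = list(reads)
    table: dict[GappedPattern, int] = {}
    n_reads = len(reads)
    if n_reads == 0:
        return PatternCountTable(cycle, table, 0, counting_mode, strand_policy, bounds)

    enc = encode_reads(reads).astype(np.int64)
    L = enc.shape[1]
    read_idx = np.arange(n_reads, dtype=np.int64)

    by_span: dict[int, list[tuple[int, int, int]]] = {}
    for k, g, s in bounds.shapes():
        by_span.setdefault(k + g, []).append((k, g, s))

    for span, shapes in by_span.items():
        if span > L:
            continue
        n_pos = L - span + 1
        win = np.lib.stride_tricks.sliding_window_view(enc, span, axis=1)
        W = np.ascontiguousarray(win.reshape(-1, span), dtype=np.float64)
        w5 = 5.0 ** np.arange(span - 1, -1, -1)
        # Base-5 window codes via one BLAS matmul per span (codes < 5^21 are
        # exactly representable in float64); per-shape gap columns are then
        # patched in-place instead of recoding the whole window.
        base_fwd = (W @ w5).astype(np.int64)
        base_rc = ((3.0 - W) @ w5[::-1]).astype(np.int64)
        span_codes: list[np.ndarray] = []
        p5 = 5 ** np.arange(span, dtype=np.int64)  # p5[j] = 5**j
        for _k, g, s in shapes:
            fwd = base_fwd
            rc = base_rc
            for j in range(s, s + g):
                d = W[:, j].astype(np.int64)
                # forward: digit at j (weight 5**(span-1-j)) becomes 4
                fwd = fwd + (4 - d) * p5[span - 1 - j]
                # reverse complement: mirrored digit (3-d at weight 5**j)
                # becomes 4
                rc = rc + (1 + d) * p5[j]
            if strand_policy == "merge":
                span_codes.append(np.minimum(fwd, rc))
            else:
                span_codes.append(fwd)
        codes = np.concatenate(span_codes)
        if counting_mode == "per_read":
            # One contribution per (read, canonical pattern): shapes of equal
            # span can yield the same canonical pattern (forward vs reverse
            # hits), so dedup pools all same-span shapes.  Explicit sort+diff
            # dedup: much faster than np.unique's hash path on this scale.
            ridx = np.tile(np.repeat(read_idx, n_pos), len(shapes))
            keys = ridx * (5**span) + codes
            keys.sort()
            mask = np.empty(keys.size, dtype=bool)
            mask[0] = True
            np.not_equal(keys[1:], keys[:-1], out=mask[1:])
            codes = keys[mask] % (5**span)
        uniq, cnt = np.unique(codes, return_counts=True)
        for sym, c in zip(_decode_codes(uniq, span), cnt):
            gp = GappedPattern(sym)
            table[gp] = table.get(gp, 0) + int(c)

    return PatternCountTable(
        cycle, table, n_reads, counting_mode, strand_policy, bounds
    )


def enumerate_patterns(bounds: PatternBounds) -> Iterator[GappedPattern]:
    """Every canonical single-gap pattern within bounds (test/oracle scale only)."""
    from itertools import product

    for k, g, s in bounds.shapes():
        for bases in product(BASES, repeat=k):
            syms = bases[:s] + (GAP,) * g + bases[s:] if g else bases
            yield GappedPattern("".join(syms))


def write_count_table(table: PatternCountTable, path) -> None:
    """Serialize as two-column TSV (pattern, count), count-descending."""
    with open(path, "w") as fh:
        fh.write("pattern\tcount\n")
        for p, c in table.items_by_count():
            fh.write(f"{p.symbols}\t{c}\n")
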