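"""Autoseed: local-maxima seed discovery in gapped-pattern count space.

A pattern is a seed candidate when no closely related pattern is more
enriched: it must beat every equal-length neighbor at Huddinge distance one
outright, and win the cross-length comparison against neighbors with one
defined base more or fewer.  Because a shorter pattern contained in a longer
one is always at least as frequent, cross-length dominance uses a threshold
theta: the longer pattern wins when count(long) > theta * count(short).
Under a null of no enrichment the expected long/short count ratio is about
1/4 per added defined base and approaches 1 under perfect enrichment;
theta = 0.5 is the log-scale midpoint and the default.

The strongest local maximum is the primary binding mode; the remaining maxima
are secondary modes, classified by how they relate to the primary: same
half-sites with different spacing/orientation, the same site with extended
flanks, a two-adjacent-base (dinucleotide) variant, or unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .patterns import (
    GAP,
    GappedPattern,
    PatternBounds,
    PatternCountTable,
    canonical_strand,
    huddinge_neighbors,
    revcomp,
)

Relation = Literal["dinucleotide", "flank", "spacing_orientation", "unrelated", "none"]


@dataclass(frozen=True)
class AutoseedConfig:
    theta: float = 0.5
    min_count: int = 10
    bounds: PatternBounds = field(default_factory=PatternBounds)
    top: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


@dataclass
class SeedModel:
    pattern: GappedPattern
    count: int
    rank: int
    role: Literal["primary", "secondary"] = "secondary"
    relation_to_primary: Relation = "none"


def is_local_maximum(
    p: GappedPattern, table: PatternCountTable, config: AutoseedConfig
) -> bool:
    """Exact local-maximum predicate for one pattern.

    (i) strictly higher count than every equal-length Huddinge-1 neighbor
    (ties break dominance); (ii) count > theta * count(shorter neighbor);
    (iii) no longer neighbor L with count(L) > theta * count(p);
    (iv) count >= min_count.
    """
    c = table.count(p)
    if c < config.min_count:
        return False
    b = config.bounds
    neighbors = huddinge_neighbors(
        p,
        max_defined=b.max_defined,
        max_gap=b.max_gap,
        min_defined=b.min_defined,
        strand_policy=table.strand_policy,
    )
    k = p.n_defined
    theta = config.theta
    for q in neighbors:
        cq = table.count(q)
        if q.n_defined == k:
            if cq >= c:
                return False
        elif q.n_defined == k - 1:
            if c <= theta * cq:
                return False
        elif q.n_defined == k + 1:
            if cq > theta * c:
                return False
    return True


def _extension_counts_exceed(
    p: GappedPattern, table: PatternCountTable, config: AutoseedConfig
) -> bool:
    """Fast pre-check of rule (iii): does any one-base extension dominate p?

    Direct construction of the longer Huddinge-1 neighbors (add one defined
    base at the ends, beyond the ends, or inside the gap); a superset check
    for counts only, used to discard dominated patterns cheaply before the
    full neighbor enumeration runs.
    """
    b = config.bounds
    if p.n_defined + 1 > b.max_defined:
        return False
    c = table.count(p)
    syms = p.symbols
    cands: list[str] = []
    for base in "ACGT":
        # Adjacent end extensions.
        cands.append(base + syms)
        cands.append(syms + base)
        # End extensions creating a new edge gap (only for ungapped patterns,
        # otherwise the result has two gap runs and leaves the pattern space).
        if p.gap_len == 0:
            for g in range(1, b.max_gap + 1):
                cands.append(base + GAP * g + syms)
                cands.append(syms + GAP * g + base)
        else:
            # Fill one edge position of the existing gap run.
            i = syms.index(GAP)
            j = i + p.gap_len
            cands.append(syms[:i] + base + syms[i + 1 :])
            if j - 1 != i:
                cands.append(syms[: j - 1] + base + syms[j:])
    for s in cands:
        q = GappedPattern(s)
        if q.gap_runs > 1 or q.gap_len > b.max_gap:
            continue
        if table.count(q) > config.theta * c:
            return True
    return False


def find_local_maxima(
    table: PatternCountTable, config: AutoseedConfig = AutoseedConfig()
) -> list[SeedModel]:
    """All local-maxima seed patterns, ranked by count (descending).

    Patterns are visited in count order so the scan can stop once counts fall
    below ``min_count`` (or after ``config.top`` maxima when set); each
    surviving pattern is verified with the exact Huddinge-1 predicate.
    """
    if not table.counts:
        raise ValueError("empty count table")
    results: list[SeedModel] = []
    for p, c in table.items_by_count():
        if c < config.min_count:
            break
        if config.top is not None and len(results) >= config.top:
            break
        if _extension_counts_exceed(p, table, config):
            continue
        if is_local_maximum(p, table, config):
            results.append(SeedModel(pattern=p, count=c, rank=len(results) + 1))
    return results


# ---------------------------------------------------------------------------
# Primary/secondary classification
# ---------------------------------------------------------------------------

def _halves(p: GappedPattern) -> tuple[str, str] | None:
    """Split a single-gap pattern at its gap into (left, right) half-sites."""
    if p.gap_runs != 1:
        return None
    i = p.symbols.index(GAP)
    j = i
    while j < len(p.symbols) and p.symbols[j] == GAP:
        j += 1
    return p.symbols[:i], p.symbols[j:]


def _half_key(h: str) -> str:
    return min(h, revcomp(h))


def _best_alignment(a: str, b: str) -> tuple[int, list[tuple[int, int]]]:
    """(max defined matches, mismatching defined-position pairs at that offset)."""
    best, best_mm = -1, []
    for off in range(-(len(b) - 1), len(a)):
        m, mm = 0, []
        for j, cb in enumerate(b):
            i = off + j
            if not (0 <= i < len(a)):
                continue
            ca = a[i]
            if ca == GAP or cb == GAP:
                continue
            if ca == cb:
                m += 1
            else:
                mm.append((i, j))
        if m > best:
            best, best_mm = m, mm
    return best, best_mm


def classify_model_relation(
    secondary: GappedPattern, primary: GappedPattern
) -> Relation:
    """How a secondary seed relates to the primary seed.

    Precedence: spacing_orientation (same half-sites, different gap length or
    orientation) > flank (one pattern end-extends the other) > dinucleotide
    (best rigid alignment differs at exactly two adjacent defined positions);
    anything else is unrelated.
    """
    if canonical_strand(secondary) == canonical_strand(primary):
        return "unrelated"  # degenerate: same pattern up to strand
    hp = _halves(primary)
    hs = _halves(secondary)
    if hp is not None and hs is not None:
        keys_p = sorted(_half_key(h) for h in hp)
        keys_s = sorted(_half_key(h) for h in hs)
        if keys_p == keys_s:
            return "spacing_orientation"

    shorter, longer = sorted(
        (secondary, primary), key=lambda p: (p.n_defined, p.span)
    )
    if shorter.n_defined < longer.n_defined:
        for lng in (longer.symbols, revcomp(longer.symbols)):
            m, _ = _best_alignment(lng, shorter.symbols)
            if m == shorter.n_defined:
                return "flank"

    if secondary.n_defined == primary.n_defined:
        best_m, best_mm = -1, None
        for s2 in (secondary.symbols, revcomp(secondary.symbols)):
            m, mm = _best_alignment(primary.symbols, s2)
            if m > best_m:
                best_m, best_mm = m, mm
        if best_mm is not None and len(best_mm) == 2:
            (i1, _), (i2, _) = sorted(best_mm)
            if i2 - i1 == 1:
                return "dinucleotide"
    return "unrelated"


def pick_primary_and_secondary(maxima: list[SeedModel]) -> list[SeedModel]:
    """Annotate ranked maxima: rank 1 is the primary binding mode; every other
    maximum is a secondary mode classified against it."""
    if not maxima:
        raise ValueError("no local maxima to annotate")
    out = []
    primary = maxima[0]
    out.append(
        SeedModel(primary.pattern, primary.count, 1, role="primary",
                  relation_to_primary="none")
    )
    for m in maxima[1:]:
        rel = classify_model_relation(m.pattern, primary.pattern)
        out.append(
            SeedModel(m.pattern, m.count, m.rank, role="secondary",
                      relation_to_primary=rel)
        )
    return out


def write_seed_table(models: list[SeedModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tpattern\tcount\trole\trelation\n")
        for m in models:
            fh.write(
                f"{m.rank}\t{m.pattern.symbols}\t{m.count}\t{m.role}\t"
                f"{m.relation_to_primary}\n"
            )
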