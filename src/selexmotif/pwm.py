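"""Background-corrected multinomial PWMs built around a seed pattern.

A binding profile is estimated by aligning reads to a seed (a gapped
consensus): for each read the best-matching window on either strand is chosen,
and a position's base counts accumulate over windows that match the seed's
defined bases at all *other* positions with at most ``order - 1`` mismatches
("multinomial order"; order 1 means the rest of the site must match the seed
exactly).  Counting one queried position at a time while constraining the
others removes most of the signal a raw column-count PWM would leak between
positions.  Counts can then be corrected against the unselected (cycle 0)
library to cancel the synthesis/sequencing composition bias of the library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import CycleReads, read_pwm_matrix, write_pwm_matrix
from .patterns import GAP, GappedPattern, encode_reads

BackgroundMode = Literal["none", "cycle0", "uniform"]

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PWM:
    """4xW position weight matrix with its provenance metadata.

    ``counts`` are raw (possibly corrected) per-position base counts;
    ``frequencies`` are column-normalized and always sum to 1 per column.
    Width is ``seed.span + 2 * flank``.
    """

    counts: np.ndarray
    frequencies: np.ndarray
    seed: GappedPattern | None = None
    cycle_used: int = 0
    multinomial_order: int = 1
    flank: int = 0
    background_mode: BackgroundMode = "none"
    name: str = "motif"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2:
            raise ValueError("counts must be 4xW")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.frequencies.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, **meta) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        col = counts.sum(axis=0)
        freq = np.where(col > 0, counts / np.where(col > 0, col, 1.0), 0.25)
        return cls(counts=counts, frequencies=freq, **meta)

    @classmethod
    def from_file(cls, path, **meta) -> "PWM":
        return cls.from_counts(read_pwm_matrix(path), **meta)

    def to_file(self, path) -> None:
        write_pwm_matrix(self.counts, path)

    def reverse_complement(self) -> "PWM":
        return PWM(
            counts=self.counts[::-1, ::-1].copy(),
            frequencies=self.frequencies[::-1, ::-1].copy(),
            seed=self.seed,
            cycle_used=self.cycle_used,
            multinomial_order=self.multinomial_order,
            flank=self.flank,
            background_mode=self.background_mode,
            name=self.name,
        )

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (0..2)."""
        f = np.clip(self.frequencies, 1e-12, 1.0)
        return 2.0 + (f * np.log2(f)).sum(axis=0)


def _seed_arrays(seed: GappedPattern) -> tuple[np.ndarray, np.ndarray]:
    """(defined mask, base indices with -1 at gaps) for a seed pattern."""
    mask = np.array([c != GAP for c in seed.symbols])
    idx = np.array([_BASE_IDX.get(c, -1) for c in seed.symbols])
    return mask, idx


def _best_windows(
    enc: np.ndarray, seed: GappedPattern, merge_strands: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best seed-matching window per read.

    Returns (position, strand, n_matches) arrays; strand 0 = forward.
    Score is the number of matching defined bases; ties go to the leftmost
    position, then the forward strand, making output deterministic.
    """
    n, L = enc.shape
    span = seed.span
    if span > L:
        raise ValueError("seed wider than reads")
    mask, sidx = _seed_arrays(seed)
    win = np.lib.stride_tricks.sliding_window_view(enc, span, axis=1)
    n_pos = L - span + 1
    fwd = (win == sidx[None, None, :])[:, :, mask].sum(axis=2)
    if merge_strands:
        rc_idx = np.where(sidx >= 0, 3 - sidx, -1)[::-1]
        rc_mask = mask[::-1]
        rev = (win == rc_idx[None, None, :])[:, :, rc_mask].sum(axis=2)
        both = np.stack([fwd, rev], axis=2).reshape(n, 2 * n_pos)
        # Column order (pos0 fwd, pos0 rev, pos1 fwd, ...) encodes the
        # leftmost-then-forward tie-break directly in argmax.
        best = both.argmax(axis=1)
        pos, strand = best // 2, best % 2
        score = both[np.arange(n), best]
    else:
        pos = fwd.argmax(axis=1)
        strand = np.zeros(n, dtype=int)
        score = fwd[np.arange(n), pos]
    return pos, strand, score


def multinomial_matrix(
    reads: CycleReads | list[str],
    seed: GappedPattern,
    order: int = 1,
    flank: int = 0,
    merge_strands: bool = True,
) -> np.ndarray:
    """Multinomial base-count matrix of width ``seed.span + 2*flank``.

    Each read contributes via its single best-matching window.  Cell (b, i)
    counts windows whose base at position i is b and which mismatch the seed's
    defined bases at positions other than i in at most ``order - 1`` places.
    Gap and flank positions impose no constraint; flank positions that fall
    outside the read are skipped.
    """
    if order < 1:
        raise ValueError("multinomial order must be >= 1")
    rlist = reads.reads if isinstance(reads, CycleReads) else list(reads)
    span = seed.span
    w = span + 2 * flank
    out = np.zeros((4, w))
    if not rlist:
        return out
    enc = encode_reads(rlist).astype(np.int8)
    L = enc.shape[1]
    if span > L:
        raise ValueError("seed wider than reads")
    pos, strand, _ = _best_windows(enc, seed, merge_strands)

    mask, sidx = _seed_arrays(seed)
    rc_mask, rc_sidx = mask[::-1], np.where(sidx >= 0, 3 - sidx, -1)[::-1]

    n = enc.shape[0]
    cols = pos[:, None] + np.arange(-flank, span + flank)[None, :]
    valid = (cols >= 0) & (cols < L)
    window = np.where(valid, enc[np.arange(n)[:, None], np.clip(cols, 0, L - 1)], -1)
    # Reverse-strand windows are read as their reverse complement so that all
    # windows live in seed orientation.
    rev = strand == 1
    if rev.any():
        wr = window[rev][:, ::-1]
        window[rev] = np.where(wr >= 0, 3 - wr, -1)
        valid[rev] = valid[rev][:, ::-1]

    seed_full = np.full(w, -1)
    seed_full[flank : flank + span] = sidx
    is_def = seed_full >= 0
    mm = ((window != seed_full[None, :]) & is_def[None, :] & valid).astype(np.int16)
    total_mm = mm.sum(axis=1)

    for i in range(w):
        # Mismatches at positions other than i must stay within order-1.
        other = total_mm - mm[:, i]
        ok = (other <= order - 1) & valid[:, i]
        b = window[ok, i]
        np.add.at(out, (b[b >= 0], i), 1)
    return out


def background_correct(
    observed: np.ndarray,
    background: np.ndarray | None = None,
    mode: BackgroundMode = "cycle0",
    subtract: bool = False,
    **meta,
) -> PWM:
    """Turn an observed multinomial count matrix into a corrected PWM.

    ``cycle0`` divides each cell by the matched-rule expectation computed from
    unselected-library reads (scaled to the observed total, +1 on both sides
    so identical observed/background gives exactly uniform columns);
    ``uniform`` divides by 0.25 (a no-op after renormalization); ``none``
    takes plain column proportions.  ``subtract=True`` switches the cycle0
    correction from a ratio to a (floored) difference.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.sum() == 0:
        raise ValueError("observed matrix is empty")
    if mode == "cycle0":
        if background is None:
            raise ValueError("cycle0 correction needs a background matrix")
        bg = np.asarray(background, dtype=float)
        if bg.shape != observed.shape:
            raise ValueError("background shape mismatch")
        col_obs = observed.sum(axis=0)
        col_bg = bg.sum(axis=0)
        scale = np.where(col_bg > 0, col_obs / np.where(col_bg > 0, col_bg, 1.0), 0.0)
        expected = bg * scale[None, :]
        if subtract:
            corrected = np.maximum(observed - expected, 0.0)
        else:
            corrected = (observed + 1.0) / (expected + 1.0)
    elif mode == "uniform":
        corrected = observed / 0.25
    elif mode == "none":
        corrected = observed.copy()
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    meta.setdefault("background_mode", mode)
    return PWM.from_counts(corrected, **meta)


def build_pwm(
    reads: CycleReads | list[str],
    seed: GappedPattern,
    order: int = 1,
    flank: int = 0,
    background_reads: CycleReads | list[str] | None = None,
    background_mode: BackgroundMode = "cycle0",
    subtract: bool = False,
    name: str = "motif",
) -> PWM:
    """Multinomial matrix + background correction in one call."""
    observed = multinomial_matrix(reads, seed, order=order, flank=flank)
    bg = None
    if background_mode == "cycle0":
        if background_reads is None:
            raise ValueError("cycle0 background requires background_reads")
        bg = multinomial_matrix(background_reads, seed, order=order, flank=flank)
    cycle = reads.cycle if isinstance(reads, CycleReads) else 0
    return background_correct(
        observed,
        background=bg,
        mode=background_mode,
        subtract=subtract,
        seed=seed,
        cycle_used=cycle,
        multinomial_order=order,
        flank=flank,
        name=name,
    )


def classify_site_structure(
    pwm: PWM,
    core_len: int = 5,
    similarity_threshold: float = 0.85,
) -> str:
    """Heuristic repeat-structure call: monomer / dimer / trimer / dimer_of_dimers.

    The PWM's highest-information contiguous window (the putative half-site)
    is slid against the full PWM on both strands; non-overlapping placements
    whose mean per-column Pearson correlation with the core exceeds the
    threshold are counted as half-site copies.
    """
    w = pwm.width
    if w < 4:
        raise ValueError("PWM too narrow to classify")
    core_len = min(core_len, w)
    ic = pwm.information_content()
    starts = range(w - core_len + 1)
    core_start = max(starts, key=lambda s: ic[s : s + core_len].sum())
    core = pwm.frequencies[:, core_start : core_start + core_len]

    def placement_scores(target: np.ndarray) -> list[tuple[float, int]]:
        out = []
        for s in range(target.shape[1] - core_len + 1):
            sub = target[:, s : s + core_len]
            cors = []
            for j in range(core_len):
                a, b = core[:, j], sub[:, j]
                sa, sb = a.std(), b.std()
                cors.append(
                    1.0 if sa < 1e-12 and sb < 1e-12
                    else 0.0 if sa < 1e-12 or sb < 1e-12
                    else float(np.corrcoef(a, b)[0, 1])
                )
            out.append((float(np.mean(cors)), s))
        return out

    # Collect above-threshold placements on forward coordinates (a
    # reverse-strand start s maps to forward start w - core_len - s), then
    # greedily keep non-overlapping ones best-first.
    all_hits: list[tuple[float, int]] = []
    for strand, target in enumerate((pwm.frequencies, pwm.frequencies[::-1, ::-1])):
        for score, s in placement_scores(target):
            if score >= similarity_threshold:
                fwd = s if strand == 0 else w - core_len - s
                all_hits.append((score, fwd))
    placed: list[int] = []
    for score, fwd in sorted(all_hits, key=lambda t: (-t[0], t[1])):
        if all(abs(fwd - q) >= core_len for q in placed):
            placed.append(fwd)
    count = len(placed)
    if count <= 1:
        return "monomer"
    if count == 2:
        return "dimer"
    if count == 3:
        return "trimer"
    return "dimer_of_dimers"
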