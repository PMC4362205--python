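"""Pairwise base interdependency within bound sites.

A mononucleotide PWM assumes positions bind independently.  For every pair of
positions in the aligned site windows, the observed joint 4x4 dinucleotide
distribution is compared with the product of its marginals; the score is the
fraction of counts the independence model mispredicts (total variation
distance), scaled so that 0% means independent bases and 100% means half of
all counts mispredicted — the extreme reached when only two complementary
dinucleotides (e.g. AA and TT) occur, each half the time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CycleReads
from .patterns import GappedPattern, encode_reads
from .pwm import _best_windows

SIGN_EPS = 1e-6


def dependency_score(joint: np.ndarray) -> float:
    """Scaled mispredict score (percent) for one 4x4 joint distribution.

    mispredicted fraction = (1/2) * sum |joint - marginal product| (total
    variation); score = 200 * fraction, mapping the half-mispredicted case
    to 100%.  Not clipped: pathological joints (e.g. a 4-state diagonal) can
    exceed 100.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.shape != (4, 4):
        raise ValueError("joint must be 4x4")
    total = joint.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("joint distribution must sum to 1")
    mi = joint.sum(axis=1)
    mj = joint.sum(axis=0)
    predicted = np.outer(mi, mj)
    fraction = 0.5 * np.abs(joint - predicted).sum()
    return float(200.0 * fraction)


@dataclass
class PairDependencyTable:
    """Per position-pair joint distributions and mispredict scores.

    ``joint[(i, j)]`` (i < j) is the observed 4x4 frequency table,
    ``predicted`` its product-of-marginals counterpart, ``score_pct`` the
    scaled score, and ``sign`` a 4x4 array of {"over", "under", "neutral"}
    marking dinucleotides over-/under-represented vs the mononucleotide
    prediction.
    """

    width: int
    n_sites: int
    joint: dict[tuple[int, int], np.ndarray]
    predicted: dict[tuple[int, int], np.ndarray]
    score_pct: dict[tuple[int, int], float]
    sign: dict[tuple[int, int], np.ndarray]

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.joint)

    def score_matrix(self) -> np.ndarray:
        m = np.zeros((self.width, self.width))
        for (i, j), s in self.score_pct.items():
            m[i, j] = m[j, i] = s
        return m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tscore_pct\n")
            for (i, j) in self.pairs():
                fh.write(f"{i + 1}\t{j + 1}\t{self.score_pct[(i, j)]:.6f}\n")


def joint_pair_counts(
    reads: CycleReads | list[str],
    seed: GappedPattern,
    flank: int = 0,
    max_mismatch: int = 1,
) -> tuple[dict[tuple[int, int], np.ndarray], int]:
    """Joint 4x4 base-pair counts for every position pair in the site window.

    Site windows are selected as in PWM building (best-matching window per
    read, both strands, leftmost/forward tie-break); reads whose best window
    mismatches the seed's defined bases in more than ``max_mismatch`` places
    are excluded.  Window positions outside the read are skipped pairwise.
    """
    rlist = reads.reads if isinstance(reads, CycleReads) else list(reads)
    if not rlist:
        raise ValueError("empty site set")
    enc = encode_reads(rlist).astype(np.int8)
    n, L = enc.shape
    span = seed.span
    w = span + 2 * flank
    if span > L:
        raise ValueError("seed wider than reads")
    pos, strand, score = _best_windows(enc, seed, merge_strands=True)
    ok = score >= seed.n_defined - max_mismatch
    if not ok.any():
        raise ValueError("empty site set")
    pos, strand = pos[ok], strand[ok]
    enc = enc[ok]
    n = enc.shape[0]

    cols = pos[:, None] + np.arange(-flank, span + flank)[None, :]
    valid = (cols >= 0) & (cols < L)
    window = np.where(valid, enc[np.arange(n)[:, None], np.clip(cols, 0, L - 1)], -1)
    rev = strand == 1
    if rev.any():
        wr = window[rev][:, ::-1]
        window[rev] = np.where(wr >= 0, 3 - wr, -1)

    counts: dict[tuple[int, int], np.ndarray] = {}
    for i in range(w):
        for j in range(i + 1, w):
            both = (window[:, i] >= 0) & (window[:, j] >= 0)
            tab = np.zeros((4, 4))
            np.add.at(tab, (window[both, i], window[both, j]), 1)
            counts[(i, j)] = tab
    return counts, n


def dependency_table(
    reads: CycleReads | list[str],
    seed: GappedPattern,
    flank: int = 0,
    max_mismatch: int = 1,
    clip: bool = False,
) -> PairDependencyTable:
    """Full dependency table over the site window: scores plus over/under signs."""
    counts, n_sites = joint_pair_counts(reads, seed, flank, max_mismatch)
    w = seed.span + 2 * flank
    joint_d, pred_d, score_d, sign_d = {}, {}, {}, {}
    for pair, tab in counts.items():
        tot = tab.sum()
        if tot == 0:
            joint = np.full((4, 4), 1 / 16)
        else:
            joint = tab / tot
        mi, mj = joint.sum(axis=1), joint.sum(axis=0)
        predicted = np.outer(mi, mj)
        score = dependency_score(joint)
        if clip:
            score = min(score, 100.0)
        sign = np.where(
            joint > predicted + SIGN_EPS, "over",
            np.where(joint < predicted - SIGN_EPS, "under", "neutral"),
        )
        joint_d[pair] = joint
        pred_d[pair] = predicted
        score_d[pair] = score
        sign_d[pair] = sign
    return PairDependencyTable(
        width=w, n_sites=n_sites, joint=joint_d, predicted=pred_d,
        score_pct=score_d, sign=sign_d,
    )
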