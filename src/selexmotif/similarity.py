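"""Motif-motif and protein-protein similarity, clustering, and k-mer enrichment.

Motif similarity is the Pearson correlation between *gapped 6-mer score
vectors*: every pattern of 3 defined bases + a middle gap of 0..G + 3 defined
bases is scored against each PWM (best placement over positions and strands,
log-probability with a small pseudocount), giving each motif a fixed-length
fingerprint that is insensitive to motif width, alignment and strand.

Protein (DBD) similarity follows the blastp-score convention: local
alignment score x alignment length / length of the shorter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.stats import pearsonr, spearmanr

from .io import CycleReads
from .patterns import encode_reads
from .pwm import PWM

DEFAULT_PSEUDOCOUNT = 0.01


# ---------------------------------------------------------------------------
# Gapped 6-mer fingerprints
# ---------------------------------------------------------------------------

@dataclass
class ScoreVector:
    motif_id: str
    values: np.ndarray  # shared enumeration order: gap ascending, then base-4 code


def _kmer_index_array(half: int) -> np.ndarray:
    """(4^(2*half), 2*half) array of base indices in base-4 enumeration order."""
    k = 2 * half
    codes = np.arange(4**k)
    digits = np.empty((4**k, k), dtype=np.int64)
    c = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[:, j] = c % 4
        c //= 4
    return digits


def gapped_kmer_score_vector(
    pwm: PWM,
    k: int = 6,
    max_gap: int = 10,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ScoreVector:
    """Score every gapped k-mer (k/2 + gap + k/2) against a PWM.

    A pattern's score is the maximum over all rigid placements inside the PWM
    on both strands of the summed log frequencies at its defined positions.
    Placements that do not fit score the flat background value
    ``k * log(0.25 + pseudocount)``, so narrow PWMs still yield finite,
    comparable vectors.
    """
    if k % 2:
        raise ValueError("k must be even (half-sites flank the gap)")
    if pwm.width < k:
        raise ValueError(f"PWM width {pwm.width} < k = {k}")
    half = k // 2
    digits = _kmer_index_array(half)  # (4^k, k)
    background = k * np.log(0.25 + pseudocount)

    logmats = [
        np.log(pwm.frequencies + pseudocount),
        np.log(pwm.frequencies[::-1, ::-1] + pseudocount),
    ]
    blocks = []
    for g in range(max_gap + 1):
        offsets = np.concatenate([np.arange(half), half + g + np.arange(half)])
        span = k + g
        best = np.full(digits.shape[0], background)
        for L in logmats:
            for start in range(pwm.width - span + 1):
                cols = start + offsets
                s = L[digits, cols[None, :]].sum(axis=1)
                np.maximum(best, s, out=best)
        blocks.append(best)
    return ScoreVector(pwm.name, np.concatenate(blocks))


def motif_similarity(
    pwm1: PWM,
    pwm2: PWM,
    k: int = 6,
    max_gap: int = 10,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Correlation of the two motifs' gapped k-mer score vectors, in [-1, 1]."""
    v1 = gapped_kmer_score_vector(pwm1, k, max_gap).values
    v2 = gapped_kmer_score_vector(pwm2, k, max_gap).values
    if np.std(v1) < 1e-12 or np.std(v2) < 1e-12:
        raise ValueError("degenerate motif: zero-variance score vector")
    if method == "pearson":
        return float(pearsonr(v1, v2)[0])
    return float(spearmanr(v1, v2)[0])


@dataclass
class SimilarityMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], matrix=df.to_numpy(dtype=float))


def motif_similarity_matrix(
    pwms: list[PWM], k: int = 6, max_gap: int = 10,
    method: Literal["pearson", "spearman"] = "pearson",
) -> SimilarityMatrix:
    vecs = [gapped_kmer_score_vector(p, k, max_gap).values for p in pwms]
    n = len(pwms)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.std(vecs[i]) < 1e-12 or np.std(vecs[j]) < 1e-12:
                raise ValueError("degenerate motif: zero-variance score vector")
            if method == "pearson":
                r = pearsonr(vecs[i], vecs[j])[0]
            else:
                r = spearmanr(vecs[i], vecs[j])[0]
            m[i, j] = m[j, i] = r
    return SimilarityMatrix(ids=[p.name for p in pwms], matrix=m)


# ---------------------------------------------------------------------------
# Amino-acid (DBD) similarity
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def aa_similarity_score(
    seq1: str | list[str],
    seq2: str | list[str],
    mode: Literal["max_domain", "concatenate"] = "max_domain",
) -> float:
    """Protein similarity: alignment score x aligned length / shorter length.

    Local alignment with BLOSUM62 and affine gaps (open 11, extend 1).
    Multi-domain proteins (lists of domain sequences) are combined either by
    taking the best-scoring domain pair (``max_domain``) or by concatenating
    all domains into one sequence (``concatenate``).
    """
    l1 = [seq1] if isinstance(seq1, str) else list(seq1)
    l2 = [seq2] if isinstance(seq2, str) else list(seq2)
    if not l1 or not l2 or any(not s for s in l1 + l2):
        raise ValueError("empty protein sequence")
    if mode == "concatenate":
        l1, l2 = ["".join(l1)], ["".join(l2)]
    aligner = _make_aligner()
    best = 0.0
    for a in l1:
        for b in l2:
            alns = aligner.align(a, b)
            if len(alns) == 0:
                continue
            aln = alns[0]
            score = float(aln.score)
            length = int(aln.length)
            val = score * length / min(len(a), len(b))
            best = max(best, val)
    return best


# ---------------------------------------------------------------------------
# Clustering and networks
# ---------------------------------------------------------------------------

def cluster_motifs(matrix: SimilarityMatrix) -> str:
    """Average-linkage tree over similarity-matrix rows, as a Newick string.

    Each motif is represented by its row of similarities; euclidean distances
    between rows feed agglomerative (UPGMA/average) clustering.  Branch
    lengths follow the linkage heights, so identical rows merge at height 0.
    """
    if len(matrix.ids) < 2:
        raise ValueError("need at least 2 motifs to cluster")
    if np.isnan(matrix.matrix).any():
        raise ValueError("similarity matrix contains NaN")
    from scipy.spatial.distance import pdist

    d = pdist(matrix.matrix, metric="euclidean")
    Z = hierarchy.linkage(d, method="average")
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, matrix.ids)
    return str(tree).strip()


def tree_leaf_order(newick: str) -> list[str]:
    from io import StringIO

    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    return [t.name for t in tree.tips()]


def motif_network(matrix: SimilarityMatrix, threshold: float):
    """Undirected similarity network: edge (i, j) iff similarity >= threshold.

    Isolated nodes are retained so the node set always equals the motif set.
    Returns a networkx Graph with 'weight' edge attributes.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.matrix[i, j] >= threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j],
                           weight=float(matrix.matrix[i, j]))
    return g


def write_network(g, edge_tsv=None, graphml=None) -> None:
    import networkx as nx

    if edge_tsv is not None:
        with open(edge_tsv, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.6f}\n")
    if graphml is not None:
        nx.write_graphml(g, graphml)


# ---------------------------------------------------------------------------
# k-mer enrichment scatter tables
# ---------------------------------------------------------------------------

def _kmer_counts(reads: list[str], k: int) -> np.ndarray:
    """Counts of all 4^k ungapped k-mers (forward occurrences)."""
    if not reads:
        return np.zeros(4**k, dtype=np.int64)
    enc = encode_reads(reads).astype(np.int64)
    L = enc.shape[1]
    if k > L:
        raise ValueError(f"k = {k} exceeds read length {L}")
    win = np.lib.stride_tricks.sliding_window_view(enc, k, axis=1)
    w4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = (win.reshape(-1, k) @ w4)
    return np.bincount(codes, minlength=4**k)


def _decode4(codes: np.ndarray, k: int) -> list[str]:
    letters = np.array(list("ACGT"))
    out = np.empty((codes.size, k), dtype="U1")
    c = codes.copy()
    for j in range(k - 1, -1, -1):
        out[:, j] = letters[c % 4]
        c //= 4
    return ["".join(r) for r in out]


def kmer_log_odds(early: CycleReads, late: CycleReads, k: int = 10) -> np.ndarray:
    """Per-k-mer log2 enrichment between an early and a late cycle.

    log-odds = log2[(c_late + 1) / (N_late + 4^k)]
             - log2[(c_early + 1) / (N_early + 4^k)]
    """
    ce = _kmer_counts(early.reads, k).astype(float)
    cl = _kmer_counts(late.reads, k).astype(float)
    ne, nl = ce.sum(), cl.sum()
    return np.log2((cl + 1) / (nl + 4.0**k)) - np.log2((ce + 1) / (ne + 4.0**k))


def _pwm_best_match_scores(kmers_digits: np.ndarray, pwm: PWM) -> np.ndarray:
    k = kmers_digits.shape[1]
    logmats = [
        np.log(pwm.frequencies + DEFAULT_PSEUDOCOUNT),
        np.log(pwm.frequencies[::-1, ::-1] + DEFAULT_PSEUDOCOUNT),
    ]
    best = np.full(kmers_digits.shape[0], -np.inf)
    for L in logmats:
        w = L.shape[1]
        if w >= k:
            for start in range(w - k + 1):
                cols = start + np.arange(k)
                s = L[kmers_digits, cols[None, :]].sum(axis=1)
                np.maximum(best, s, out=best)
        else:
            # PWM narrower than the k-mer: slide the PWM inside the k-mer.
            for start in range(k - w + 1):
                cols = np.arange(w)
                s = L[kmers_digits[:, start : start + w], cols[None, :]].sum(axis=1)
                np.maximum(best, s, out=best)
    return best


def kmer_enrichment_table(
    expr_a: tuple[CycleReads, CycleReads],
    expr_b: tuple[CycleReads, CycleReads],
    k: int = 10,
    pwm_a: PWM | None = None,
    pwm_b: PWM | None = None,
    min_count: int = 1,
) -> pd.DataFrame:
    """Log-odds enrichment of every k-mer in two experiments, for scatter plots.

    Rows are k-mers seen at least ``min_count`` times in some late cycle;
    columns ``log_odds_a`` / ``log_odds_b`` give per-experiment enrichment
    (early vs late), plus optional PWM match scores for 2D coloring.
    """
    lo_a = kmer_log_odds(expr_a[0], expr_a[1], k)
    lo_b = kmer_log_odds(expr_b[0], expr_b[1], k)
    cl_a = _kmer_counts(expr_a[1].reads, k)
    cl_b = _kmer_counts(expr_b[1].reads, k)
    keep = (cl_a >= min_count) | (cl_b >= min_count)
    codes = np.nonzero(keep)[0]
    df = pd.DataFrame(
        {
            "kmer": _decode4(codes, k),
            "log_odds_a": lo_a[codes],
            "log_odds_b": lo_b[codes],
            "count_late_a": cl_a[codes],
            "count_late_b": cl_b[codes],
        }
    )
    if pwm_a is not None or pwm_b is not None:
        digits = np.empty((codes.size, k), dtype=np.int64)
        c = codes.copy()
        for j in range(k - 1, -1, -1):
            digits[:, j] = c % 4
            c //= 4
        if pwm_a is not None:
            df["pwm_score_a"] = _pwm_best_match_scores(digits, pwm_a)
        if pwm_b is not None:
            df["pwm_score_b"] = _pwm_best_match_scores(digits, pwm_b)
    return df
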