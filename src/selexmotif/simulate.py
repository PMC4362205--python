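"""Synthetic HT-SELEX experiments with known ground truth.

Each simulated experiment starts from a uniform random oligo library and
iterates rounds of selection and amplification: a read's binding affinity is
the best site it contains under a planted binding model (a PWM, optionally
with dinucleotide coupling between chosen position pairs, optionally a
mixture of motifs for secondary modes or spacing variants), reads survive a
round with probability proportional to ``1 + strength * affinity``, and the
survivors are resampled with replacement (PCR amplification; duplicates are
intentional, they exercise per-read counting downstream).

Defaults are desk scale: 50,000 reads per cycle and 3 selection cycles, with
the ligand design of a typical HT-SELEX library (6 bp 5' barcode, 20 or 40 bp
randomized region, 2-3 bp 3' barcode).  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import CycleReads, LigandDesign
from .patterns import GAP, encode_reads

DEFAULT_DESIGN = LigandDesign("ACGTAC", 20, "GT")

_LETTERS = np.array(list("ACGT"))


def pwm_from_consensus(consensus: str, match_prob: float = 0.8) -> np.ndarray:
    """4xW frequency matrix spelling a (possibly gapped) consensus.

    Defined positions put ``match_prob`` on the consensus base and the rest
    uniformly on the other three; gap positions (``n``) are uniform.
    """
    if not 0.25 <= match_prob <= 1.0:
        raise ValueError("match_prob must lie in [0.25, 1]")
    w = len(consensus)
    freq = np.full((4, w), 0.25)
    other = (1.0 - match_prob) / 3.0
    for i, c in enumerate(consensus.upper()):
        if c in (GAP.upper(), GAP):
            continue
        bi = "ACGT".index(c)
        freq[:, i] = other
        freq[bi, i] = match_prob
    return freq


@dataclass
class SiteModel:
    """One planted binding mode: a PWM plus optional pair couplings.

    ``couplings`` maps a position pair (i, j) to a 4x4 joint distribution
    that replaces the independent product at those two positions; sampling
    draws the pair jointly, and affinity scoring multiplies in the ratio
    joint / product-of-marginals.
    """

    frequencies: np.ndarray
    couplings: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    name: str = "site"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape[0] != 4:
            raise ValueError("site frequencies must be 4xW")
        if not np.allclose(self.frequencies.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("site frequency columns must sum to 1")
        for (i, j), joint in self.couplings.items():
            joint = np.asarray(joint, dtype=float)
            if joint.shape != (4, 4) or not np.isclose(joint.sum(), 1.0, atol=1e-6):
                raise ValueError("coupling joints must be 4x4 distributions")
            self.couplings[(i, j)] = joint

    @property
    def width(self) -> int:
        return self.frequencies.shape[1]

    def consensus(self) -> str:
        return "".join(
            _LETTERS[c] if self.frequencies[:, i].max() > 0.3 else GAP
            for i, c in enumerate(self.frequencies.argmax(axis=0))
        )


@dataclass
class GroundTruthModel:
    """Full specification of one simulated experiment."""

    components: list[tuple[float, SiteModel]]
    selection_strength: float = 5.0
    cycles: int = 3
    reads_per_cycle: int = 50_000
    design: LigandDesign = field(default_factory=lambda: DEFAULT_DESIGN)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        wsum = sum(w for w, _ in self.components)
        if self.components and not np.isclose(wsum, 1.0, atol=1e-6):
            raise ValueError("component weights must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "GroundTruthModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        comps = []
        for c in d["components"]:
            if "frequencies" in c:
                freq = np.asarray(c["frequencies"], dtype=float)
            else:
                freq = pwm_from_consensus(c["consensus"], c.get("match_prob", 0.8))
            couplings = {}
            for k, v in (c.get("couplings") or {}).items():
                i, j = (int(x) for x in str(k).split(","))
                couplings[(i, j)] = np.asarray(v, dtype=float)
            site = SiteModel(
                frequencies=freq,
                couplings=couplings,
                name=c.get("name", c.get("consensus", "site")),
            )
            comps.append((float(c.get("weight", 1.0)), site))
        total = sum(w for w, _ in comps)
        comps = [(w / total, s) for w, s in comps]
        design = d.get("design")
        design = (
            LigandDesign(
                design["five_prime_barcode"],
                int(design["random_len"]),
                design["three_prime_barcode"],
            )
            if design
            else DEFAULT_DESIGN
        )
        return cls(
            components=comps,
            selection_strength=float(d.get("selection_strength", 5.0)),
            cycles=int(d.get("cycles", 3)),
            reads_per_cycle=int(d.get("reads_per_cycle", 50_000)),
            design=design,
            rng_seed=int(d.get("rng_seed", 0)),
        )

    def to_yaml(self, path) -> None:
        d = {
            "components": [
                {
                    "name": s.name,
                    "consensus": s.consensus(),
                    "weight": float(w),
                    "frequencies": s.frequencies.tolist(),
                    "couplings": {
                        f"{i},{j}": joint.tolist()
                        for (i, j), joint in s.couplings.items()
                    },
                }
                for w, s in self.components
            ],
            "selection_strength": self.selection_strength,
            "cycles": self.cycles,
            "reads_per_cycle": self.reads_per_cycle,
            "design": {
                "five_prime_barcode": self.design.five_prime_barcode,
                "random_len": self.design.random_len,
                "three_prime_barcode": self.design.three_prime_barcode,
            },
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def sample_initial_library(
    n: int, design: LigandDesign = DEFAULT_DESIGN, rng_seed: int = 0,
    experiment_id: str = "sim",
) -> CycleReads:
    """Cycle-0 library: n i.i.d. uniform reads of the randomized-region length."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(rng_seed)
    mat = rng.integers(0, 4, size=(n, design.random_len))
    reads = ["".join(row) for row in _LETTERS[mat]]
    return CycleReads(experiment_id=experiment_id, cycle=0, reads=reads)


def _affinities(enc: np.ndarray, model: GroundTruthModel) -> np.ndarray:
    """Max site probability-ratio vs background, per read (winner-take-all)."""
    n, L = enc.shape
    best_log = np.full(n, -np.inf)
    for weight, site in model.components:
        w = site.width
        if w > L:
            continue
        logratio = np.log(np.clip(site.frequencies, 1e-9, 1.0) / 0.25)
        mats = [logratio]
        mats.append(logratio[::-1, ::-1])
        win = np.lib.stride_tricks.sliding_window_view(enc, w, axis=1)
        for mat_i, LR in enumerate(mats):
            coup_terms = []
            for (i, j), joint in site.couplings.items():
                mi, mj = joint.sum(axis=1), joint.sum(axis=0)
                ratio = np.log(
                    np.clip(joint, 1e-9, 1.0)
                    / np.clip(np.outer(mi, mj), 1e-9, None)
                )
                if mat_i == 1:  # reverse strand: mirrored, complemented pair
                    ii, jj = w - 1 - j, w - 1 - i
                    ratio = ratio[::-1, ::-1].T
                    coup_terms.append((ii, jj, ratio))
                else:
                    coup_terms.append((i, j, ratio))
            for start in range(L - w + 1):
                sub = win[:, start, :]
                s = LR[sub, np.arange(w)[None, :]].sum(axis=1)
                for (i, j, ratio) in coup_terms:
                    s = s + ratio[sub[:, i], sub[:, j]]
                s = s + np.log(weight)
                np.maximum(best_log, s, out=best_log)
    return np.exp(np.clip(best_log, -700, 700))


def sample_site_reads(
    site: SiteModel, n: int, read_len: int, rng: np.random.Generator
) -> list[str]:
    """Reads with one planted site each at a random position (test helper)."""
    w = site.width
    if w > read_len:
        raise ValueError("site wider than read")
    enc = rng.integers(0, 4, size=(n, read_len))
    cum = site.frequencies.cumsum(axis=0)
    u = rng.random((n, w))
    sites = (u[:, None, :] > cum[None, :, :]).sum(axis=1)
    for (i, j), joint in site.couplings.items():
        flat = joint.ravel().cumsum()
        pick = (rng.random(n)[:, None] > flat[None, :]).sum(axis=1)
        sites[:, i], sites[:, j] = pick // 4, pick % 4
    starts = rng.integers(0, read_len - w + 1, size=n)
    for r in range(n):
        enc[r, starts[r] : starts[r] + w] = sites[r]
    return ["".join(row) for row in _LETTERS[enc]]


def select_round(
    reads: CycleReads, model: GroundTruthModel, rng: np.random.Generator
) -> CycleReads:
    """One selection + amplification round.

    Each read is retained with probability proportional to
    ``1 + selection_strength * affinity`` (normalized by the round maximum),
    then the retained pool is resampled with replacement back to
    ``reads_per_cycle``.
    """
    if not reads.reads:
        raise ValueError("cannot select from an empty pool")
    enc = encode_reads(reads.reads).astype(np.int64)
    aff = _affinities(enc, model)
    w = 1.0 + model.selection_strength * aff
    keep = rng.random(len(w)) < (w / w.max())
    kept = [r for r, k in zip(reads.reads, keep) if k]
    if not kept:
        import logging

        logging.getLogger(__name__).warning(
            "selection retained no reads; resampling uniformly"
        )
        kept = reads.reads
    idx = rng.integers(0, len(kept), size=model.reads_per_cycle)
    return CycleReads(
        experiment_id=reads.experiment_id,
        cycle=reads.cycle + 1,
        reads=[kept[i] for i in idx],
    )


def simulate_experiment(
    model: GroundTruthModel, experiment_id: str = "sim"
) -> list[CycleReads]:
    """Full experiment: cycle-0 library plus ``model.cycles`` selection rounds."""
    rng = np.random.default_rng(model.rng_seed)
    lib_seed = int(rng.integers(0, 2**31 - 1))
    cycles = [
        sample_initial_library(
            model.reads_per_cycle, model.design, lib_seed, experiment_id
        )
    ]
    for _ in range(model.cycles):
        cycles.append(select_round(cycles[-1], model, rng))
    return cycles
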