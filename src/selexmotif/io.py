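"""Reading and writing the on-disk formats the toolkit touches.

SELEX ligands are fixed-design oligos: a 6 bp 5' barcode, a randomized region
of 20 or 40 bp, and a 2-3 bp 3' barcode.  Raw reads are binned by exact
barcode match and reduced to their randomized regions before any counting.
PWMs travel as labeled 4xW TSV (rows A,C,G,T) or MEME minimal format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

ROW_ORDER = "ACGT"


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class LigandDesign:
    """Fixed layout of a SELEX selection ligand."""

    five_prime_barcode: str
    random_len: int
    three_prime_barcode: str

    def __post_init__(self) -> None:
        if len(self.five_prime_barcode) != 6:
            raise ValueError("5' barcode must be 6 bp")
        if not 2 <= len(self.three_prime_barcode) <= 3:
            raise ValueError("3' barcode must be 2-3 bp")
        if self.random_len <= 0:
            raise ValueError("random_len must be positive")
        for bc in (self.five_prime_barcode, self.three_prime_barcode):
            if not set(bc) <= set("ACGT"):
                raise ValueError(f"barcode {bc!r} contains non-ACGT characters")

    @classmethod
    def from_yaml(cls, path) -> "LigandDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            five_prime_barcode=d["five_prime_barcode"],
            random_len=int(d["random_len"]),
            three_prime_barcode=d["three_prime_barcode"],
        )


@dataclass
class CycleReads:
    """Randomized-region reads of one SELEX cycle (cycle 0 = initial library)."""

    experiment_id: str
    cycle: int
    reads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cycle < 0:
            raise ValueError("cycle must be >= 0")

    def __len__(self) -> int:
        return len(self.reads)


def read_sequences(path, format: Literal["fastq", "fasta"] | None = None) -> list[str]:
    """Read sequences (uppercased) from FASTA or FASTQ, in file order.

    Format is inferred from the suffix when not given.  Malformed records
    raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    try:
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), format)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed {format} file: {exc}") from exc


def write_fasta(reads: list[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f">{prefix}{i}\n{r}\n")


def demultiplex_cycles(
    raw_reads: list[str],
    design: LigandDesign,
    experiment_id: str = "exp",
    cycle: int = 0,
) -> CycleReads:
    """Extract randomized regions from reads matching the ligand design.

    Barcode matching is exact (barcodes are short; no error correction), the
    extracted region must have exactly ``random_len`` bases, and reads with
    any N in the randomized region are dropped.  The retention fraction is
    logged.  Reads are kept in sequenced orientation; reverse-strand handling
    belongs to counting, not demultiplexing.
    """
    bc5, bc3 = design.five_prime_barcode, design.three_prime_barcode
    n5, nr, n3 = len(bc5), design.random_len, len(bc3)
    kept: list[str] = []
    for read in raw_reads:
        read = read.upper()
        if len(read) < n5 + nr + n3:
            continue
        if read[:n5] != bc5 or read[n5 + nr : n5 + nr + n3] != bc3:
            continue
        region = read[n5 : n5 + nr]
        if set(region) <= set("ACGT"):
            kept.append(region)
    frac = len(kept) / len(raw_reads) if raw_reads else 0.0
    logger.info(
        "demultiplex: retained %d/%d reads (%.1f%%)",
        len(kept), len(raw_reads), 100 * frac,
    )
    return CycleReads(experiment_id=experiment_id, cycle=cycle, reads=kept)


# ---------------------------------------------------------------------------
# PWM serialization
# ---------------------------------------------------------------------------

def read_pwm_matrix(path) -> np.ndarray:
    """Read a labeled 4xW TSV (rows A,C,G,T in order; 1-based column header)."""
    rows: dict[str, list[float]] = {}
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in ("pos", ""):  # header row
                continue
            label = fields[0]
            if label not in ROW_ORDER:
                raise FormatError(f"{path}:{lineno}: unexpected row label {label!r}")
            try:
                vals = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise FormatError(f"{path}:{lineno}: ragged row (expected {width} columns)")
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative matrix entry")
            rows[label] = vals
    if set(rows) != set(ROW_ORDER):
        raise FormatError(f"{path}: expected exactly rows {ROW_ORDER}, got {sorted(rows)}")
    if not width:
        raise FormatError(f"{path}: matrix has no columns")
    return np.array([rows[b] for b in ROW_ORDER], dtype=float)


def write_pwm_matrix(matrix: np.ndarray, path) -> None:
    """Write a 4xW matrix as labeled TSV with 1-based column indices."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != 4 or matrix.ndim != 2:
        raise ValueError("matrix must be 4xW")
    if (matrix < 0).any():
        raise ValueError("matrix entries must be non-negative")
    w = matrix.shape[1]
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(str(i) for i in range(1, w + 1)) + "\n")
        for b, row in zip(ROW_ORDER, matrix):
            fh.write(b + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_pwm_meme(frequencies: np.ndarray, path, name: str = "motif") -> None:
    """Write column frequencies in MEME minimal format (columns sum to 1)."""
    freq = np.asarray(frequencies, dtype=float)
    if freq.shape[0] != 4:
        raise ValueError("frequency matrix must be 4xW")
    sums = freq.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-9):
        freq = freq / sums
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {freq.shape[1]}\n")
        for col in freq.T:
            fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
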