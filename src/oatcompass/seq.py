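"""Small sequence utilities: complements, rotations, FASTA round-trips.

Internal coordinates throughout the package are 0-based half-open; GFF3 I/O
converts to 1-based closed and BED output stays 0-based half-open.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte codes for the four bases in the fixed internal order
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def min_rotation(seq: str) -> str:
    """Lexicographically minimal rotation of ``seq``."""
    n = len(seq)
    doubled = seq + seq
    return min(doubled[i : i + n] for i in range(n))


def primitive_unit(seq: str) -> str:
    """Smallest unit ``u`` such that ``seq == u * k`` (``seq`` itself if primitive)."""
    n = len(seq)
    for d in range(1, n // 2 + 1):
        if n % d == 0 and seq == seq[:d] * (n // d):
            return seq[:d]
    return seq


def is_primitive(seq: str) -> bool:
    return primitive_unit(seq) == seq


def canonical_monomer(seq: str) -> str:
    """Canonical form of a tandem-repeat unit.

    The unit is reduced to its primitive period, then the lexicographically
    minimal rotation over both the unit and its reverse complement is taken,
    so a monomer and any rotation of either strand map to one representative.
    """
    unit = primitive_unit(seq.upper())
    return min(min_rotation(unit), min_rotation(revcomp(unit)))


def seq_to_bytes(seq: str) -> np.ndarray:
    """Uppercase byte view of a sequence for vectorised comparisons."""
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.44) -> str:
    """I.i.d. random DNA with the given GC content."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    arr = rng.choice(BASE_BYTES, size=length, p=p)
    return arr.tobytes().decode()


def mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: list[tuple[int, int]] | None = None,
) -> str:
    """Substitute each site independently with probability ``rate``.

    ``protected`` lists 0-based half-open intervals left untouched (used to
    keep planted satellite arrays identical across simulated subgenomes).
    """
    arr = seq_to_bytes(seq).copy()
    hit = rng.random(arr.size) < rate
    if protected:
        for s, e in protected:
            hit[s:e] = False
    idx = np.nonzero(hit)[0]
    if idx.size:
        # map byte -> base index, add a random offset in 1..3: always a new base
        lut = np.zeros(256, dtype=np.int64)
        lut[BASE_BYTES] = np.arange(4)
        new = (lut[arr[idx]] + rng.integers(1, 4, size=idx.size)) % 4
        arr[idx] = BASE_BYTES[new]
    return arr.tobytes().decode()


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrences of ``needle``."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def fasta_bytes(sequences: dict[str, str], width: int = 60) -> bytes:
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=width)
    writer.write_file(records)
    return buf.getvalue().encode()
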