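"""Nucleotide sequence handling: validation, FASTA I/O, window scanning, fixtures.

Sequences are plain Python strings over the alphabet ``ACGT`` (optionally
``N`` where a caller policy allows ambiguous bases).  Numeric code works on
encoded ``uint8`` arrays with A,C,G,T -> 0,1,2,3 and N -> 4.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
NUCLEOSOME_WINDOW = 147

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for sequences containing symbols outside the allowed alphabet."""


def clean_sequence(seq: str, allow_n: bool = False) -> str:
    """Uppercase *seq* and verify every symbol is in ``ACGT`` (plus ``N`` if allowed)."""
    s = seq.upper()
    allowed = "ACGTN" if allow_n else ALPHABET
    bad = set(s) - set(allowed)
    if bad:
        raise SequenceError(f"invalid nucleotide symbol(s): {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (A,C,G,T,N -> 0..4)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        pos = int(np.argmax(arr == 255))
        raise SequenceError(f"invalid symbol {seq[pos]!r} at position {pos}")
    return arr


def encode_ensemble(seqs: Iterable[str]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    rows = [encode(s) for s in seqs]
    if not rows:
        raise ValueError("empty ensemble")
    lengths = {r.shape[0] for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"ragged sequence lengths: {sorted(lengths)}")
    return np.vstack(rows)


def decode(arr: np.ndarray) -> str:
    return _DECODE[np.asarray(arr, dtype=np.uint8)].tobytes().decode("ascii")


def read_fasta(path: str | Path, allow_n: bool = True) -> list[tuple[str, str]]:
    """Read all FASTA records in file order as (identifier, sequence) pairs.

    Input is uppercased; symbols outside ``ACGTN`` raise :class:`SequenceError`.
    An empty file yields an empty list.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, clean_sequence(str(rec.seq), allow_n=allow_n)))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def windows(genome: str, width: int = NUCLEOSOME_WINDOW, step: int = 1) -> Iterator[tuple[int, str]]:
    """Yield (start, subsequence) for every width-bp window, skipping N windows.

    Coordinates are 0-based, half-open.  Starts are 0, step, 2*step, ...
    Windows that overlap an ``N`` are silently skipped; use :func:`scan_windows`
    to also recover the skipped starts.
    """
    starts, mat, _ = scan_windows(genome, width, step)
    for s, row in zip(starts.tolist(), mat):
        yield s, decode(row)


def scan_windows(
    genome: str, width: int = NUCLEOSOME_WINDOW, step: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window scan returning (starts, encoded window matrix, skipped N-window starts)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    enc = encode(clean_sequence(genome, allow_n=True))
    L = enc.shape[0]
    if width > L:
        raise ValueError(f"window width {width} exceeds genome length {L}")
    all_starts = np.arange(0, L - width + 1, step)
    view = np.lib.stride_tricks.sliding_window_view(enc, width)[all_starts]
    has_n = (view == 4).any(axis=1)
    return all_starts[~has_n], view[~has_n], all_starts[has_n]


def random_genome(length: int, seed: int, gc: float = 0.5) -> str:
    """I.i.d. random sequence with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def symmetrize_ensemble(seqs: Iterable[str]) -> list[str]:
    """Append the reverse complement of every sequence (optional; off by
    default throughout the package, since models are trained on the given
    strand unless a caller opts in)."""
    seqs = list(seqs)
    return seqs + [reverse_complement(s) for s in seqs]


def random_ensemble(n: int, length: int, seed: int, gc: float = 0.5) -> list[str]:
    """*n* independent i.i.d. sequences of the given length (training fixture)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    mat = rng.choice(4, size=(n, length), p=p).astype(np.uint8)
    return [decode(row) for row in mat]
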