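"""Position-specific oligonucleotide probability tables.

A :class:`PositionOligoTable` stores, for every start position ``n`` of a
fixed-length window and every k-mer ``w``, the probability that an ensemble
sequence carries ``w`` at ``n``.  These are the per-position mono-, di- and
trinucleotide distributions from which position-dependent Markov models are
assembled.  K-mers are indexed in base 4 with the first base most significant
(``AA.. = 0``, last base fastest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .sequences import ALPHABET, decode, encode_ensemble

_SIMPLEX_TOL = 1e-9


def kmer_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        idx = idx * 4 + ALPHABET.index(ch)
    return idx


def kmer_string(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(idx % 4)
        idx //= 4
    return decode(np.array(out[::-1], dtype=np.uint8))


def kmer_index_matrix(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-4 k-mer indices at every start of each row of an (n, L) code matrix."""
    enc = np.asarray(enc)
    L = enc.shape[-1]
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    idx = enc[..., : L - k + 1].astype(np.int64)
    for j in range(1, k):
        idx = idx * 4 + enc[..., j : L - k + 1 + j]
    return idx


@dataclass
class PositionOligoTable:
    """Per-position k-mer probability table over a fixed window.

    ``probs`` has shape (n_positions, 4**k); row ``n`` is the distribution of
    k-mers starting at window position ``n`` (0-based).  ``n_sequences`` is the
    ensemble size the probabilities were estimated from (``None`` for analytic
    tables); exact counts are then recoverable as ``probs * n_sequences``.
    """

    k: int
    window_length: int
    probs: np.ndarray
    n_sequences: int | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4**self.k:
            raise ValueError(f"probs must have shape (n_positions, {4 ** self.k})")
        if (self.probs < 0).any():
            raise ValueError("negative probability entry")

    @property
    def n_positions(self) -> int:
        return self.probs.shape[0]

    def validate_simplex(self, tol: float = _SIMPLEX_TOL) -> None:
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=tol):
            worst = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"row {worst} sums to {sums[worst]!r}, not 1")

    def marginalize_last(self) -> "PositionOligoTable":
        """Sum out the last base: the (k-1)-mer table at the same start positions.

        The derived table spans starts 0..window_length-k (one position fewer
        than a directly counted (k-1)-mer table would), which is exactly the
        range the Markov-chain denominators need.
        """
        if self.k < 1:
            raise ValueError("cannot marginalize a 0-mer table")
        marg = self.probs.reshape(self.n_positions, 4 ** (self.k - 1), 4).sum(axis=2)
        return PositionOligoTable(
            k=self.k - 1,
            window_length=self.window_length,
            probs=marg,
            n_sequences=self.n_sequences,
            smoothed=self.smoothed,
        )

    def to_tsv(self, path: str | Path) -> None:
        """TSV with columns (position, kmer, probability) plus a JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("position\tkmer\tprobability\n")
            for n in range(self.n_positions):
                for w in range(4**self.k):
                    fh.write(f"{n}\t{kmer_string(w, self.k)}\t{self.probs[n, w]:.17g}\n")
        meta = {
            "k": self.k,
            "window_length": self.window_length,
            "n_sequences": self.n_sequences,
            "smoothed": self.smoothed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionOligoTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        k = meta["k"]
        rows: dict[int, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("position"):
                raise ValueError(f"malformed table file {path}")
            for line in fh:
                pos_s, kmer, p_s = line.rstrip("\n").split("\t")
                n = int(pos_s)
                if n not in rows:
                    rows[n] = np.zeros(4**k)
                rows[n][kmer_index(kmer)] = float(p_s)
        probs = np.vstack([rows[n] for n in sorted(rows)])
        return cls(
            k=k,
            window_length=meta["window_length"],
            probs=probs,
            n_sequences=meta["n_sequences"],
            smoothed=meta["smoothed"],
        )


def count_oligos(ensemble: list[str] | np.ndarray, k: int) -> PositionOligoTable:
    """Position-specific k-mer frequencies of an equal-length sequence ensemble.

    The value at (n, w) is the number of ensemble sequences whose k-mer starting
    at position n equals w, divided by the ensemble size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    enc = ensemble if isinstance(ensemble, np.ndarray) else encode_ensemble(ensemble)
    n_seq, L = enc.shape
    if k > L:
        raise ValueError(f"k={k} exceeds window length {L}")
    idx = kmer_index_matrix(enc, k)  # (n_seq, L-k+1)
    n_pos = L - k + 1
    counts = np.zeros((n_pos, 4**k), dtype=np.int64)
    flat = idx + np.arange(n_pos, dtype=np.int64) * 4**k
    np.add.at(counts.reshape(-1), flat.ravel(), 1)
    return PositionOligoTable(
        k=k, window_length=L, probs=counts / n_seq, n_sequences=n_seq
    )


def smooth_positions(table: PositionOligoTable) -> PositionOligoTable:
    """3-bp positional running average of a table, renormalized per position.

    The value at (n, w) becomes the mean over positions n-1, n, n+1 of the
    original values for w; at the two boundary positions the mean runs over the
    two available positions.  Each row is renormalized to sum to 1 afterwards
    (a no-op up to rounding when the input rows are normalized).
    """
    if table.n_positions < 3:
        raise ValueError("need at least 3 positions to smooth")
    p = table.probs
    acc = p.copy()
    acc[:-1] += p[1:]
    acc[1:] += p[:-1]
    counts = np.full((table.n_positions, 1), 3.0)
    counts[0] = counts[-1] = 2.0
    sm = acc / counts
    sm /= sm.sum(axis=1, keepdims=True)
    return replace(table, probs=sm, smoothed=True)


def subsample(ensemble: list[str] | np.ndarray, n: int, seed: int):
    """Uniform random subset of *n* sequences without replacement (seeded).

    Accepts either a list of strings or an encoded (n, L) matrix; the return
    type matches the input.
    """
    if not 1 <= n <= len(ensemble):
        raise ValueError(f"n={n} out of range 1..{len(ensemble)}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(ensemble), size=n, replace=False)
    if isinstance(ensemble, np.ndarray):
        return ensemble[picks]
    return [ensemble[i] for i in picks]
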