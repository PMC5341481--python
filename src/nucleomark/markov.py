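"""Position-dependent Markov-chain models of nucleosomal sequence probability.

An order-m model writes the probability of a 147-bp sequence S as

    P(S) = prod_n P(w_n) / prod_n P(v_n)

with numerator (m+1)-mers w_n at every window start and denominator m-mers
v_n at the interior starts, both read off position-specific ensemble
frequency tables.  Equivalently P(S) is the leading m-mer probability times a
product of position-specific conditionals P(base | preceding m bases).  The
free energy of a sequence is F(S) = -kT log P(S), defined up to the unknown
partition-function offset; only differences between sequences are meaningful.

Zero-probability policies handle k-mers never seen in the training ensemble:

``flat_quarter``
    treat the event as an ensemble failure carrying no information and insert
    a flat conditional probability of 0.25 at the affected position;
``smoothed``
    train on tables smoothed with a 3-bp positional running average (any
    residual zero still falls back to the flat 0.25 conditional);
``strict``
    raise :class:`EnsembleZeroError` identifying the position and k-mer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequences import encode, encode_ensemble
from .tables import (
    PositionOligoTable,
    count_oligos,
    kmer_index_matrix,
    kmer_string,
    smooth_positions,
)

ZERO_POLICIES = ("flat_quarter", "smoothed", "strict")
_LOG_QUARTER = math.log(0.25)


class EnsembleZeroError(RuntimeError):
    """A required k-mer probability is 0 under the strict zero policy."""

    def __init__(self, position: int, kmer: str):
        self.position = position
        self.kmer = kmer
        super().__init__(
            f"ensemble failure: k-mer {kmer!r} unobserved at window position {position}"
        )


@dataclass
class MarkovModel:
    """Order-m position-dependent Markov chain over fixed-length windows."""

    order: int
    joint: PositionOligoTable  # k = order + 1
    marginal: PositionOligoTable | None  # k = order, derived; None for order 0
    zero_policy: str = "flat_quarter"
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.zero_policy not in ZERO_POLICIES:
            raise ValueError(f"unknown zero policy {self.zero_policy!r}")
        if self.joint.k != self.order + 1:
            raise ValueError("joint table k must equal order + 1")
        if self.order > 0:
            if self.marginal is None:
                raise ValueError("order > 0 requires a marginal table")
            if self.marginal.k != self.order:
                raise ValueError("marginal table k must equal order")

    @property
    def window_length(self) -> int:
        return self.joint.window_length

    # -- scoring ---------------------------------------------------------

    def log_probability_many(self, enc: np.ndarray) -> np.ndarray:
        """Natural-log probabilities for an (n, L) matrix of encoded windows."""
        enc = np.atleast_2d(np.asarray(enc, dtype=np.uint8))
        if enc.shape[1] != self.window_length:
            raise ValueError(
                f"sequence length {enc.shape[1]} != model window {self.window_length}"
            )
        m = self.order
        idx = kmer_index_matrix(enc, m + 1)  # (n, L-m)
        n_pos = idx.shape[1]
        pos = np.arange(n_pos)
        J = self.joint.probs[pos[None, :], idx]
        zero = J <= 0.0
        if zero.any() and self.zero_policy == "strict":
            i, s = np.argwhere(zero)[0]
            raise EnsembleZeroError(int(s), kmer_string(int(idx[i, s]), m + 1))
        if m == 0:
            logp = np.where(zero, _LOG_QUARTER, np.log(np.where(zero, 1.0, J))).sum(axis=1)
            return logp
        ctx = idx // 4
        M = self.marginal.probs[pos[None, :], ctx]
        # conditional factors P(next | context); zero joints are information-free
        cond = np.where(zero, _LOG_QUARTER, np.log(np.where(zero, 1.0, J)))
        cond -= np.where(zero, 0.0, np.log(np.where(zero, 1.0, M)))
        # leading m-mer factor P(first m bases); if unseen, m flat factors
        p0 = self.marginal.probs[0, ctx[:, 0]]
        lead_zero = p0 <= 0.0
        if lead_zero.any() and self.zero_policy == "strict":
            i = int(np.argmax(lead_zero))
            raise EnsembleZeroError(0, kmer_string(int(ctx[i, 0]), m))
        lead = np.where(lead_zero, m * _LOG_QUARTER, np.log(np.where(lead_zero, 1.0, p0)))
        return lead + cond.sum(axis=1)

    def log_probability(self, seq: str) -> float:
        return float(self.log_probability_many(encode(seq)[None, :])[0])

    def free_energy_many(self, enc: np.ndarray) -> np.ndarray:
        """F(S) = -kT log P(S), in kT units set by ``self.kT``."""
        return -self.kT * self.log_probability_many(enc)

    def free_energy(self, seq: str) -> float:
        return -self.kT * self.log_probability(seq)

    def conditional_probability(self, position: int, context: str, next_base: str) -> float:
        """P(next_base | context) at a window position, zero policy applied.

        ``position`` is the 0-based start of the (m+1)-mer formed by context +
        next_base.  Exposed mainly for inspection and tests; scoring uses the
        vectorized path.
        """
        from .tables import kmer_index

        m = self.order
        if len(context) != m:
            raise ValueError(f"context must have length {m}")
        w = kmer_index(context + next_base)
        pj = self.joint.probs[position, w]
        if pj > 0.0:
            pm = self.marginal.probs[position, w // 4] if m else 1.0
            return float(pj / pm)
        if self.zero_policy == "strict":
            raise EnsembleZeroError(position, context + next_base)
        return 0.25

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.joint.to_tsv(directory / "joint.tsv")
        if self.marginal is not None:
            self.marginal.to_tsv(directory / "marginal.tsv")
        meta = {
            "order": self.order,
            "window_length": self.window_length,
            "zero_policy": self.zero_policy,
            "kT": self.kT,
            "n_sequences": self.joint.n_sequences,
            "smoothed": self.joint.smoothed,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "MarkovModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        joint = PositionOligoTable.from_tsv(directory / "joint.tsv")
        marginal = None
        if meta["order"] > 0:
            marginal = PositionOligoTable.from_tsv(directory / "marginal.tsv")
        return cls(
            order=meta["order"],
            joint=joint,
            marginal=marginal,
            zero_policy=meta["zero_policy"],
            kT=meta["kT"],
        )


def from_joint_table(
    joint: PositionOligoTable, zero_policy: str = "flat_quarter", kT: float = 1.0
) -> MarkovModel:
    """Build a model from an (m+1)-mer joint table, deriving the m-mer marginal.

    The marginal is obtained by exact marginalization over the last base, never
    recounted, so numerator and denominator estimates are internally consistent
    and the model's probabilities telescope to a normalized distribution.
    """
    order = joint.k - 1
    marginal = joint.marginalize_last() if order > 0 else None
    return MarkovModel(order=order, joint=joint, marginal=marginal, zero_policy=zero_policy, kT=kT)


def train(
    ensemble: list[str] | np.ndarray,
    order: int = 1,
    zero_policy: str = "flat_quarter",
    kT: float = 1.0,
) -> MarkovModel:
    """Train an order-m model on an ensemble of equal-length sequences.

    Counts (m+1)-mers at every window position, optionally smooths the table
    (``zero_policy="smoothed"``), and derives the m-mer marginals by
    marginalization.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    enc = ensemble if isinstance(ensemble, np.ndarray) else encode_ensemble(ensemble)
    joint = count_oligos(enc, order + 1)
    if zero_policy == "smoothed":
        joint = smooth_positions(joint)
    return from_joint_table(joint, zero_policy=zero_policy, kT=kT)
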