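"""Sliding-window energy landscapes: computation, normalization, decomposition.

A landscape assigns one energy (in kT) to every 147-bp window of a genomic
sequence, indexed by the window's 0-based start.  Landscapes from different
models are made comparable by Boltzmann normalization: shift the track by the
unique constant such that the Boltzmann weights over the analyzed windows sum
to one.  The shift leaves all pairwise differences untouched.

For benchmarking, a landscape splits into a slowly varying part (the 11-bp
centered running average, about one helical period) and a periodic component
(signal minus local average) dominated by the ~10-bp helical periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .markov import MarkovModel
from .sequences import NUCLEOSOME_WINDOW, decode, scan_windows
from .toy import ToyNucleosomeModel, exact_free_energy_many, exact_mean_energy_many

LOCAL_AVERAGE_WINDOW = 11


@dataclass
class EnergyLandscape:
    """Per-window energy track in kT, indexed by 0-based window starts."""

    positions: np.ndarray
    values: np.ndarray
    kT: float = 1.0
    normalized: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if self.positions.size and (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("landscape values must be finite")

    def __len__(self) -> int:
        return self.positions.size

    def shifted(self, offset: int) -> "EnergyLandscape":
        """Same values at positions displaced by *offset* base pairs."""
        return replace(self, positions=self.positions + offset, normalized=False)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tenergy_kT\n")
            for p, v in zip(self.positions.tolist(), self.values.tolist()):
                fh.write(f"{p}\t{v:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, kT: float = 1.0, source: str = "") -> "EnergyLandscape":
        data = np.loadtxt(path, skiprows=1, ndmin=2)
        return cls(positions=data[:, 0].astype(np.int64), values=data[:, 1], kT=kT, source=source)

    def to_wiggle(self, path: str | Path, chrom: str = "chr") -> None:
        """fixedStep wiggle export for genome browsers (1-based starts)."""
        with open(path, "w") as fh:
            prev = None
            for p, v in zip(self.positions.tolist(), self.values.tolist()):
                if prev is None or p != prev + 1:
                    fh.write(f"fixedStep chrom={chrom} start={p + 1} step=1\n")
                fh.write(f"{v:.6g}\n")
                prev = p


def common_positions(a: EnergyLandscape, b: EnergyLandscape):
    """Values of both landscapes restricted to their shared window starts."""
    pos, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
    if pos.size == 0:
        raise ValueError("landscapes share no positions")
    return pos, a.values[ia], b.values[ib]


def compute_landscape(
    genome: str,
    scorer: MarkovModel | ToyNucleosomeModel | Callable[[str], float],
    width: int | None = None,
    kT: float | None = None,
    source: str = "",
    toy_quantity: str = "free_energy",
) -> EnergyLandscape:
    """Score every width-bp window of *genome* (step 1, N windows excluded).

    ``scorer`` may be a trained :class:`MarkovModel` (scored as F = -kT log P),
    a :class:`ToyNucleosomeModel` (``toy_quantity`` picks the exact free energy
    or the exact thermal mean energy), or any callable mapping a window
    sequence to an energy.  ``width`` defaults to the scorer's window length
    (147 for a plain callable).
    """
    if width is None:
        width = getattr(scorer, "window_length", NUCLEOSOME_WINDOW)
    starts, mat, _skipped = scan_windows(genome, width)
    if isinstance(scorer, MarkovModel):
        values = scorer.free_energy_many(mat)
        kT = scorer.kT if kT is None else kT
        source = source or f"markov-order-{scorer.order}"
    elif isinstance(scorer, ToyNucleosomeModel):
        if width != scorer.window_length:
            scorer = scorer.replace(window_length=width)
        if toy_quantity == "free_energy":
            values = exact_free_energy_many(scorer, mat)
            source = source or "toy-exact-F"
        elif toy_quantity == "mean_energy":
            values = exact_mean_energy_many(scorer, mat)
            source = source or "toy-exact-meanE"
        else:
            raise ValueError(f"unknown toy quantity {toy_quantity!r}")
        kT = scorer.kT if kT is None else kT
    else:
        values = np.array([scorer(decode(row)) for row in mat], dtype=float)
        kT = 1.0 if kT is None else kT
    return EnergyLandscape(positions=starts, values=values, kT=kT, source=source)


def normalize_landscape(ls: EnergyLandscape) -> EnergyLandscape:
    """Boltzmann-normalize: shift so the window weights exp(-E/kT) sum to 1.

    A pure additive offset (idempotent); the landscape's shape is unchanged.
    A constant landscape of N windows becomes the constant kT log N.
    """
    if len(ls) < 1:
        raise ValueError("cannot normalize an empty landscape")
    shift = ls.kT * logsumexp(-ls.values / ls.kT)
    return replace(ls, values=ls.values + shift, normalized=True)


def local_average(ls: EnergyLandscape, window: int = LOCAL_AVERAGE_WINDOW) -> EnergyLandscape:
    """Centered running average over *window* consecutive positions.

    Only positions with full support are retained ((window-1)/2 trimmed at
    each end); entries whose neighbourhood is interrupted by excluded
    (N-containing) windows are dropped too.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if len(ls) < window:
        raise ValueError(f"need at least {window} windows")
    half = window // 2
    kernel = np.full(window, 1.0 / window)
    avg = np.convolve(ls.values, kernel, mode="valid")
    centers = ls.positions[half:-half]
    contiguous = (ls.positions[window - 1 :] - ls.positions[: 1 - window]) == window - 1
    return EnergyLandscape(
        positions=centers[contiguous],
        values=avg[contiguous],
        kT=ls.kT,
        normalized=False,
        source=ls.source and f"{ls.source}-avg{window}",
    )


def periodic_component(ls: EnergyLandscape, window: int = LOCAL_AVERAGE_WINDOW) -> EnergyLandscape:
    """Signal minus its local average, on the positions where both exist."""
    avg = local_average(ls, window)
    pos, full_v, avg_v = common_positions(ls, avg)
    return EnergyLandscape(
        positions=pos,
        values=full_v - avg_v,
        kT=ls.kT,
        normalized=False,
        source=ls.source and f"{ls.source}-periodic",
    )


def uniform_landscape(like: EnergyLandscape) -> EnergyLandscape:
    """The information-free flat landscape over the same positions (unnormalized)."""
    return EnergyLandscape(
        positions=like.positions.copy(),
        values=np.zeros(len(like)),
        kT=like.kT,
        normalized=False,
        source="uniform",
    )
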