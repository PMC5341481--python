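"""Benchmarking landscapes against a reference: RMSD decomposition and sweeps.

A model landscape is scored against a reference landscape by root-mean-square
deviation of three signals: the full landscape, its 11-bp local average, and
the periodic component.  Absolute RMSDs are put on a meaningful scale by
comparing with information-free "bad" models: a perfectly uniform landscape
for the full and averaged signals, and the reference's own periodic signal
shifted by half a period (5 bp for the ~10-bp helical repeat) to push it out
of phase.  The percentage 100 * RMSD / RMSD_bad is the headline accuracy
figure; 0% is perfect, 100% is as bad as knowing nothing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import (
    EnergyLandscape,
    common_positions,
    compute_landscape,
    local_average,
    normalize_landscape,
    periodic_component,
    uniform_landscape,
)
from .markov import train
from .sequences import encode_ensemble
from .tables import subsample

HALF_PERIOD = 5  # half of the ~10-bp helical repeat, in window starts


@dataclass
class BenchmarkReport:
    """RMSDs (kT), bad-model baselines (kT) and relative accuracies (%)."""

    rmsd_full: float
    rmsd_avg: float
    rmsd_periodic: float
    bad_full: float
    bad_avg: float
    bad_periodic: float
    rel_full: float
    rel_avg: float
    rel_periodic: float
    n_windows: int
    model_label: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def rmsd(a: EnergyLandscape, b: EnergyLandscape) -> float:
    """Root-mean-square deviation over the landscapes' common positions."""
    _, va, vb = common_positions(a, b)
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def bad_model_baselines(
    reference: EnergyLandscape, half_period: int = HALF_PERIOD
) -> tuple[float, float, float]:
    """Bad-model RMSD scales (full, local-average, periodic) for a reference.

    The uniform landscape is Boltzmann-normalized like any other model (it
    becomes the constant kT log N).  The periodic baseline compares the
    reference's periodic component with itself shifted by *half_period*
    window starts, evaluated on the overlapping positions.
    """
    if not reference.normalized:
        raise ValueError("reference landscape must be normalized first")
    uniform = normalize_landscape(uniform_landscape(reference))
    bad_full = rmsd(reference, uniform)
    bad_avg = rmsd(local_average(reference), local_average(uniform))
    per = periodic_component(reference)
    bad_periodic = rmsd(per, per.shifted(half_period))
    return bad_full, bad_avg, bad_periodic


def benchmark_model(
    approx: EnergyLandscape,
    reference: EnergyLandscape,
    half_period: int = HALF_PERIOD,
    model_label: str = "",
) -> BenchmarkReport:
    """Full RMSD decomposition of an approximate landscape vs a reference.

    Both landscapes must be Boltzmann-normalized; comparisons use only their
    common window starts.
    """
    if not (approx.normalized and reference.normalized):
        raise ValueError("both landscapes must be normalized")
    bad_full, bad_avg, bad_periodic = bad_model_baselines(reference, half_period)
    r_full = rmsd(approx, reference)
    r_avg = rmsd(local_average(approx), local_average(reference))
    r_per = rmsd(periodic_component(approx), periodic_component(reference))
    rel = lambda r, bad: 100.0 * r / bad if bad > 0 else float("nan")
    n_windows = int(np.intersect1d(approx.positions, reference.positions).size)
    return BenchmarkReport(
        rmsd_full=r_full,
        rmsd_avg=r_avg,
        rmsd_periodic=r_per,
        bad_full=bad_full,
        bad_avg=bad_avg,
        bad_periodic=bad_periodic,
        rel_full=rel(r_full, bad_full),
        rel_avg=rel(r_avg, bad_avg),
        rel_periodic=rel(r_per, bad_periodic),
        n_windows=n_windows,
        model_label=model_label,
    )


def ensemble_size_sweep(
    ensemble: list[str] | np.ndarray,
    sizes: list[int],
    orders: list[int],
    policies: list[str],
    genome: str,
    reference: EnergyLandscape,
    seed: int,
    kT: float = 1.0,
) -> pd.DataFrame:
    """RMSD of trained-model landscapes vs a reference across ensemble sizes.

    For every (size, order, policy): draw a random subset of the ensemble,
    train an order-m model under the zero policy, score the genome, normalize,
    and record the full-signal RMSD against the reference.  The subset drawn
    for a given size depends only on (seed, size index), so all orders and
    policies are compared on identical training data; the whole sweep is
    deterministic given the seed.
    """
    if max(sizes) > len(ensemble):
        raise ValueError("largest size exceeds ensemble size")
    if not reference.normalized:
        raise ValueError("reference landscape must be normalized")
    rows = []
    for i_size, size in enumerate(sizes):
        sub = subsample(ensemble, size, seed=(seed * 1000 + i_size) % 2**31)
        enc = sub if isinstance(sub, np.ndarray) else encode_ensemble(sub)
        for order in orders:
            for policy in policies:
                model = train(enc, order=order, zero_policy=policy, kT=kT)
                ls = normalize_landscape(compute_landscape(genome, model))
                rows.append(
                    {
                        "size": size,
                        "order": order,
                        "policy": policy,
                        "rmsd_full": rmsd(ls, reference),
                    }
                )
    return pd.DataFrame(rows)


def plot_correlation(approx: EnergyLandscape, reference: EnergyLandscape, ax=None, gridsize: int = 60):
    """Hexbin of model vs reference energies with the y = x diagonal (optional).

    Requires matplotlib; mirrors the usual per-window correlation plot used
    to eyeball model accuracy.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    _, va, vb = common_positions(approx, reference)
    if ax is None:
        _, ax = plt.subplots()
    ax.hexbin(vb, va, gridsize=gridsize, mincnt=1)
    lim = [min(vb.min(), va.min()), max(vb.max(), va.max())]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("reference energy (kT)")
    ax.set_ylabel("model energy (kT)")
    return ax
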