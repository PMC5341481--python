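"""Packaged benchmark experiments on the toy nucleosome model.

These functions bundle the full pipeline — simulate a Mutation Monte Carlo
sequence ensemble, train Markov models of several orders, score a random
genome, and compare against the toy model's exact free-energy landscape —
under fixed study conditions:

* working temperature 1/6 of room temperature (beta = 6), cold enough that
  sequence preferences dominate;
* nearest-step coupling lambda = 20 (same order as the on-site stiffnesses,
  K + kappa ~ 25-70), so the elastic coupling transmits sequence information
  over a few base-pair steps and the sequence distribution carries
  correlations beyond nearest neighbour — the regime where trinucleotide
  models outperform dinucleotide ones;
* a 10^6-sequence training ensemble, past the ensemble size where the
  trinucleotide model overtakes the dinucleotide model;
* a 5 kb uniform random genome as the scoring target.

Everything is deterministic given the top-level seed, which is expanded into
per-stage substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import BenchmarkReport, benchmark_model, ensemble_size_sweep
from .landscape import EnergyLandscape, compute_landscape, normalize_landscape
from .markov import train
from .sequences import random_genome
from .toy import MMCConfig, ToyNucleosomeModel, default_toy_model, mmc_sample

BENCHMARK_LAMBDA = 20.0
BENCHMARK_ENSEMBLE_SIZE = 1_000_000
BENCHMARK_GENOME_LENGTH = 5_000


@dataclass
class OrderBenchmarkResult:
    """Everything the order-comparison experiment produced."""

    model: ToyNucleosomeModel
    genome: str
    reference: EnergyLandscape
    ensemble: np.ndarray  # encoded (n, 147)
    reports: dict[int, BenchmarkReport]
    landscapes: dict[int, EnergyLandscape] = field(default_factory=dict)

    def rmsd_by_order(self) -> dict[int, float]:
        return {order: rep.rmsd_full for order, rep in self.reports.items()}


def _stage_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_training_ensemble(
    model: ToyNucleosomeModel, n_samples: int, seed: int
) -> np.ndarray:
    config = MMCConfig(
        n_samples=n_samples, burn_in_sweeps=200, thinning_sweeps=2, seed=seed
    )
    return mmc_sample(model, config, as_strings=False)


def order_benchmark(
    seed: int,
    orders: tuple[int, ...] = (0, 1, 2),
    lam: float = BENCHMARK_LAMBDA,
    n_ensemble: int = BENCHMARK_ENSEMBLE_SIZE,
    genome_length: int = BENCHMARK_GENOME_LENGTH,
    model: ToyNucleosomeModel | None = None,
) -> OrderBenchmarkResult:
    """Landscape accuracy of Markov models of increasing order.

    Trains order-m models on one MMC ensemble and reports the full RMSD
    decomposition of each model's normalized landscape against the toy
    model's exact free-energy landscape of the same genome.
    """
    genome_seed, mmc_seed = _stage_seeds(seed, 2)
    if model is None:
        model = default_toy_model(lam=lam)
    genome = random_genome(genome_length, seed=genome_seed)
    reference = normalize_landscape(compute_landscape(genome, model))
    ensemble = simulate_training_ensemble(model, n_ensemble, mmc_seed)
    result = OrderBenchmarkResult(
        model=model, genome=genome, reference=reference, ensemble=ensemble, reports={}
    )
    for order in orders:
        mk = train(ensemble, order=order, kT=model.kT)
        ls = normalize_landscape(compute_landscape(genome, mk))
        result.landscapes[order] = ls
        result.reports[order] = benchmark_model(
            ls, reference, model_label=f"markov-order-{order}"
        )
    return result


def size_sweep(
    result: OrderBenchmarkResult,
    sizes: tuple[int, ...] = (1_000, 10_000, 100_000, 1_000_000),
    orders: tuple[int, ...] = (0, 1, 2),
    policies: tuple[str, ...] = ("flat_quarter", "smoothed"),
    seed: int = 1,
) -> pd.DataFrame:
    """Ensemble-size sweep reusing an order-benchmark's ensemble and reference."""
    return ensemble_size_sweep(
        result.ensemble,
        sizes=list(sizes),
        orders=list(orders),
        policies=list(policies),
        genome=result.genome,
        reference=result.reference,
        seed=seed,
        kT=result.model.kT,
    )
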