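"""A tractable toy biophysical nucleosome model with exact analytic oracles.

The model is a one-degree-of-freedom-per-step caricature of rigid-base-pair
DNA elasticity bound to a histone surface.  A sequence S of length L defines
dinucleotide steps d_n (n = 0..L-2), each carrying one angular coordinate
theta_n with energy

    E(S, theta) = sum_n [ 1/2 K(d_n) (theta_n - theta0(d_n))^2
                        + 1/2 kappa (theta_n - c_n)^2 ]
                + sum_n 1/2 lambda (theta_{n+1} - theta_n)^2,

where K and theta0 are dinucleotide-dependent stiffness and intrinsic angle,
c_n = A cos(2 pi n / p + phi) is a periodic constraint profile imposed by the
histone surface (p ~ 10 bp, the helical repeat), and lambda couples
neighbouring steps.  The Boltzmann weight exp(-beta E) defines a joint
distribution over (sequence, conformation); integrating out theta gives the
sequence distribution P(S) and free energy F(S) = -kT log P(S).

Because E is quadratic in theta, everything is exactly computable:

* ``exact_free_energy`` - Gaussian marginalization in closed form;
* ``exact_mean_energy`` - the thermal average <E>_S via equipartition;
* ``transfer_matrix_marginals`` - for lambda = 0 the sequence distribution is
  an inhomogeneous nearest-neighbour Markov field whose position-specific
  k-mer marginals follow from forward/backward products of 4x4 transfer
  matrices.

These oracles back the Mutation Monte Carlo sampler (``mmc_sample``), which
adds nucleotide-mutation moves to a standard Metropolis simulation so that
the recorded sequences sample P(S) directly.  With lambda > 0 the sequence
distribution acquires correlations beyond nearest neighbour, which is the
regime where higher-order Markov approximations pay off.

Energies are expressed in units of kT at room temperature; the default
working temperature is 1/6 of room temperature (beta = 6), cold enough that
sequence preferences are pronounced but finite so the sampler mixes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded

from . import _kernels
from .sequences import decode, encode
from .tables import PositionOligoTable, kmer_index_matrix

__all__ = [
    "ToyNucleosomeModel",
    "MMCConfig",
    "default_toy_model",
    "toy_energy",
    "exact_free_energy",
    "exact_free_energy_many",
    "exact_mean_energy",
    "mc_mean_energy",
    "mmc_sample",
    "transfer_matrix_marginals",
]


@dataclass
class ToyNucleosomeModel:
    """Quadratic sequence-dependent nucleosome energy model.

    Parameters
    ----------
    K, theta0:
        Arrays of 16 dinucleotide stiffnesses (energy/angle^2, all > 0) and
        intrinsic angles, indexed by 4*first + second base code.
    kappa:
        Stiffness of the harmonic constraint pinning each angle to the
        periodic profile ``c_n`` (>= 0).
    amplitude, period, phase:
        Constraint profile c_n = amplitude * cos(2 pi n / period + phase).
    lam:
        Nearest-step coupling (>= 0); 0 makes the sequence model exactly
        nearest-neighbour.
    beta:
        Inverse temperature in 1/kT_room; 6.0 means 1/6 of room temperature.
    """

    K: np.ndarray
    theta0: np.ndarray
    kappa: float = 20.0
    amplitude: float = 0.2
    period: float = 10.0
    phase: float = 0.0
    lam: float = 0.0
    beta: float = 6.0
    window_length: int = 147

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.theta0 = np.asarray(self.theta0, dtype=float)
        if self.K.shape != (16,) or self.theta0.shape != (16,):
            raise ValueError("K and theta0 must have 16 entries (one per dinucleotide)")
        if (self.K <= 0).any():
            raise ValueError("all stiffnesses K must be > 0")
        if self.kappa < 0 or self.lam < 0 or self.beta <= 0:
            raise ValueError("kappa, lam must be >= 0 and beta > 0")

    @property
    def kT(self) -> float:
        return 1.0 / self.beta

    @property
    def n_steps(self) -> int:
        return self.window_length - 1

    def constraint(self) -> np.ndarray:
        n = np.arange(self.n_steps)
        return self.amplitude * np.cos(2.0 * np.pi * n / self.period + self.phase)

    def step_free_energies(self) -> np.ndarray:
        """Per-step free energies f[n, d] for lambda = 0, shape (L-1, 16).

        With lambda = 0 the Gaussian integral factorizes per step and
        F(S) = sum_n f[n, d_n] with

            f[n, d] = 1/2 (K kappa / (K + kappa)) (theta0 - c_n)^2
                    + (kT/2) log((K + kappa) / (2 pi kT)).
        """
        if self.lam != 0.0:
            raise ValueError("per-step decomposition requires lambda = 0")
        c = self.constraint()[:, None]
        K, t0 = self.K[None, :], self.theta0[None, :]
        keff = K * self.kappa / (K + self.kappa)
        ent = 0.5 * self.kT * np.log((K + self.kappa) / (2.0 * np.pi * self.kT))
        return 0.5 * keff * (t0 - c) ** 2 + ent

    def quadratic_form(self, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """(banded M, b, c0) with E = 1/2 theta' M theta - b' theta + c0.

        M is returned in scipy upper-banded form, shape (2, L-1):
        row 0 the superdiagonal (shifted right), row 1 the diagonal.
        """
        d = (enc[:-1].astype(np.int64) * 4 + enc[1:]).astype(np.int64)
        Kd, t0d = self.K[d], self.theta0[d]
        c = self.constraint()
        n = d.shape[0]
        diag = Kd + self.kappa + self.lam * np.where(
            (np.arange(n) == 0) | (np.arange(n) == n - 1), 1.0, 2.0
        )
        if n == 1:
            diag = Kd + self.kappa  # a single step has no coupling at all
        ab = np.zeros((2, n))
        ab[1] = diag
        ab[0, 1:] = -self.lam
        b = Kd * t0d + self.kappa * c
        c0 = 0.5 * float(np.sum(Kd * t0d**2) + self.kappa * np.sum(c**2))
        return ab, b, c0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "window_length": self.window_length,
            "K": self.K.tolist(),
            "theta0": self.theta0.tolist(),
            "kappa": self.kappa,
            "amplitude": self.amplitude,
            "period": self.period,
            "phase": self.phase,
            "lam": self.lam,
            "beta": self.beta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ToyNucleosomeModel":
        return cls(**json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "ToyNucleosomeModel":
        return replace(self, **kwargs)


@dataclass
class MMCConfig:
    """Run configuration for the Monte Carlo chains.

    ``mutation_fraction`` is the probability that an elementary proposal is a
    nucleotide mutation rather than a spatial move (0 gives a plain
    fixed-sequence Metropolis chain).  Sweeps count L + (L-1) elementary
    proposals.  ``spatial_step`` is the half-width of the uniform angle
    proposal.
    """

    n_samples: int
    burn_in_sweeps: int = 200
    thinning_sweeps: int = 4
    mutation_fraction: float = 0.5
    spatial_step: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.mutation_fraction < 1.0:
            raise ValueError("mutation_fraction must be in [0, 1)")


def default_toy_model(**overrides) -> ToyNucleosomeModel:
    """The packaged default parameterization (see data/toy_default.json)."""
    text = resources.files("nucleomark").joinpath("data/toy_default.json").read_text()
    params = json.loads(text)
    params.update(overrides)
    return ToyNucleosomeModel(**params)


def toy_energy(model: ToyNucleosomeModel, seq: str | np.ndarray, theta: np.ndarray) -> float:
    """E(S, theta) for one sequence/conformation pair."""
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != enc.shape[0] - 1:
        raise ValueError("theta must have length L - 1")
    d = enc[:-1].astype(np.int64) * 4 + enc[1:]
    c = model.amplitude * np.cos(
        2.0 * np.pi * np.arange(d.shape[0]) / model.period + model.phase
    )
    E = 0.5 * np.sum(model.K[d] * (theta - model.theta0[d]) ** 2)
    E += 0.5 * model.kappa * np.sum((theta - c) ** 2)
    E += 0.5 * model.lam * np.sum(np.diff(theta) ** 2)
    return float(E)


def _gaussian_free_energy(model: ToyNucleosomeModel, enc: np.ndarray) -> float:
    ab, b, c0 = model.quadratic_form(enc)
    chol = cholesky_banded(ab)
    logdet = 2.0 * float(np.sum(np.log(chol[1])))
    x = cho_solve_banded((chol, False), b)
    kT = model.kT
    n = b.shape[0]
    return c0 - 0.5 * float(b @ x) - 0.5 * kT * (n * math.log(2.0 * math.pi * kT) - logdet)


def exact_free_energy(model: ToyNucleosomeModel, seq: str | np.ndarray, method: str = "auto") -> float:
    """F(S) = -kT log integral dtheta exp(-beta E(S, theta)), exactly.

    ``method`` selects the route: "steps" (per-step closed form, lambda = 0
    only), "gaussian" (general banded-Cholesky marginalization), or "auto".
    The two routes agree to ~1e-10 and serve as mutual cross-checks.
    """
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    if method == "auto":
        method = "steps" if model.lam == 0.0 else "gaussian"
    if method == "steps":
        f = model_step_table(model)
        d = enc[:-1].astype(np.int64) * 4 + enc[1:]
        return float(f[np.arange(d.shape[0]), d].sum())
    if method == "gaussian":
        return _gaussian_free_energy(model, enc)
    raise ValueError(f"unknown method {method!r}")


def model_step_table(model: ToyNucleosomeModel) -> np.ndarray:
    return model.step_free_energies()


def exact_free_energy_many(model: ToyNucleosomeModel, enc: np.ndarray) -> np.ndarray:
    """Vectorized F(S) for an (n, L) matrix of encoded sequences."""
    enc = np.atleast_2d(enc)
    if model.lam == 0.0:
        f = model.step_free_energies()
        d = kmer_index_matrix(enc, 2)
        return f[np.arange(d.shape[1])[None, :], d].sum(axis=1)
    return np.array([_gaussian_free_energy(model, row) for row in enc])


def exact_mean_energy(model: ToyNucleosomeModel, seq: str | np.ndarray) -> float:
    """Thermal average <E>_S = E(S, theta*) + (L-1) kT / 2 (equipartition)."""
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    ab, b, c0 = model.quadratic_form(enc)
    chol = cholesky_banded(ab)
    theta_star = cho_solve_banded((chol, False), b)
    e_min = c0 - 0.5 * float(b @ theta_star)
    return e_min + 0.5 * b.shape[0] * model.kT


def exact_mean_energy_many(model: ToyNucleosomeModel, enc: np.ndarray) -> np.ndarray:
    return np.array([exact_mean_energy(model, row) for row in np.atleast_2d(enc)])


def _init_state(model: ToyNucleosomeModel, rng: np.random.Generator, seq: np.ndarray | None):
    if seq is None:
        seq = rng.integers(0, 4, size=model.window_length, dtype=np.uint8)
    seq = np.array(seq, dtype=np.uint8, copy=True)
    ab, b, _ = model.quadratic_form(seq)
    theta = cho_solve_banded((cholesky_banded(ab), False), b)  # start at the minimum
    return seq, theta


def _run(model: ToyNucleosomeModel, config: MMCConfig, seq0: np.ndarray | None, record_seq: bool):
    rng = np.random.default_rng(config.seed)
    seq, theta = _init_state(model, rng, seq0)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    return _kernels.run_chain(
        seq,
        theta,
        model.K,
        model.theta0,
        model.constraint(),
        model.kappa,
        model.lam,
        model.beta,
        config.mutation_fraction,
        config.spatial_step,
        config.burn_in_sweeps,
        config.thinning_sweeps,
        config.n_samples,
        kernel_seed,
        record_seq,
    )


def mc_mean_energy(
    model: ToyNucleosomeModel, seq: str | np.ndarray, config: MMCConfig
) -> tuple[float, float]:
    """Plain-Metropolis estimate of <E>_S with a batch-means standard error.

    The sequence is held fixed (mutation_fraction is forced to 0); the energy
    is recorded every ``thinning_sweeps`` sweeps after burn-in.  The standard
    error is computed from ~32 contiguous batches, which absorbs residual
    autocorrelation between recordings.
    """
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    cfg = replace(config, mutation_fraction=0.0)
    if model.window_length != enc.shape[0]:
        model = model.replace(window_length=int(enc.shape[0]))
    _, energies = _run(model, cfg, enc, record_seq=False)
    est = float(energies.mean())
    n_batches = min(32, max(2, energies.shape[0] // 50))
    usable = (energies.shape[0] // n_batches) * n_batches
    batches = energies[:usable].reshape(n_batches, -1).mean(axis=1)
    se = float(batches.std(ddof=1) / math.sqrt(n_batches))
    return est, se


def mmc_sample(model: ToyNucleosomeModel, config: MMCConfig, as_strings: bool = True):
    """Mutation Monte Carlo ensemble of sequences drawn from P(S).

    Alternates (randomly, per ``mutation_fraction``) nucleotide-mutation and
    spatial Metropolis moves on the joint state (S, theta), so the marginal
    law of the recorded sequences is the Boltzmann sequence distribution.
    Returns ``n_samples`` sequences recorded every ``thinning_sweeps`` sweeps
    after burn-in; fully reproducible from ``config.seed``.
    """
    if config.mutation_fraction <= 0.0:
        raise ValueError("mmc_sample needs mutation_fraction > 0")
    seqs, _ = _run(model, config, None, record_seq=True)
    if as_strings:
        return [decode(row) for row in seqs]
    return seqs


def transfer_matrix_marginals(model: ToyNucleosomeModel, k: int) -> PositionOligoTable:
    """Exact position-specific k-mer marginals of P(S) for lambda = 0.

    With lambda = 0, P(S) is proportional to prod_n exp(-beta f_n(d_n)) with
    per-step free energies f_n: an inhomogeneous nearest-neighbour Markov
    field over the bases.  Its marginals follow from forward/backward products
    of 4x4 transfer matrices W_n[a, b] = exp(-beta f_n(4a + b)), normalized at
    every site for numerical stability.
    """
    if model.lam != 0.0:
        raise ValueError("transfer-matrix marginals require lambda = 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    L = model.window_length
    if k > L:
        raise ValueError("k exceeds window length")
    f = model.step_free_energies()  # (L-1, 16)
    logW = (-model.beta * f).reshape(L - 1, 4, 4)
    logW -= logW.max(axis=(1, 2), keepdims=True)
    W = np.exp(logW)

    fwd = np.empty((L, 4))
    fwd[0] = 0.25
    for n in range(1, L):
        v = fwd[n - 1] @ W[n - 1]
        fwd[n] = v / v.sum()
    bwd = np.empty((L, 4))
    bwd[L - 1] = 0.25
    for n in range(L - 2, -1, -1):
        v = W[n] @ bwd[n + 1]
        bwd[n] = v / v.sum()

    n_pos = L - k + 1
    probs = np.empty((n_pos, 4**k))
    for n in range(n_pos):
        tensor = fwd[n]
        for j in range(k - 1):
            # grow one axis per base: tensor over bases at positions n..n+j+1
            tensor = tensor[..., :, None] * W[n + j]
        tensor = tensor * bwd[n + k - 1]
        p = tensor.reshape(-1)
        probs[n] = p / p.sum()
    return PositionOligoTable(k=k, window_length=L, probs=probs, n_sequences=None)
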