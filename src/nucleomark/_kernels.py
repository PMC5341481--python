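"""Numba kernels for the Metropolis / Mutation Monte Carlo chains.

The state is a (sequence, conformation) pair: ``seq`` holds base codes 0..3
and ``theta`` one angle per base-pair step.  Proposals are single-site:
either mutate one base to a uniformly chosen different base, or perturb one
angle by a uniform step.  Both proposals are symmetric, so the Metropolis
rule with acceptance min(1, exp(-beta dE)) leaves exp(-beta E) invariant.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def total_energy(seq, theta, K16, t016, c, kappa, lam):
    E = 0.0
    n_steps = theta.shape[0]
    for n in range(n_steps):
        d = seq[n] * 4 + seq[n + 1]
        dv = theta[n] - t016[d]
        E += 0.5 * K16[d] * dv * dv
        dc = theta[n] - c[n]
        E += 0.5 * kappa * dc * dc
    for n in range(n_steps - 1):
        dd = theta[n + 1] - theta[n]
        E += 0.5 * lam * dd * dd
    return E


@njit(cache=False)
def run_chain(
    seq,
    theta,
    K16,
    t016,
    c,
    kappa,
    lam,
    beta,
    mut_frac,
    step,
    burn_sweeps,
    thin_sweeps,
    n_samples,
    seed,
    record_seq,
):
    """Run the chain; return (recorded sequences, recorded total energies).

    One sweep is L + (L-1) elementary proposals, each independently a
    mutation with probability ``mut_frac`` and a spatial move otherwise.
    Recording happens every ``thin_sweeps`` sweeps after ``burn_sweeps``.
    """
    np.random.seed(seed)
    L = seq.shape[0]
    n_steps = L - 1
    props_per_sweep = L + n_steps
    out_seq = np.zeros((n_samples if record_seq else 1, L), np.uint8)
    out_E = np.zeros(n_samples)
    total_sweeps = burn_sweeps + thin_sweeps * n_samples
    rec = 0
    for sweep in range(total_sweeps):
        for _ in range(props_per_sweep):
            if np.random.random() < mut_frac:
                i = np.random.randint(L)
                old = seq[i]
                nb = np.random.randint(3)
                new = np.uint8(nb if nb < old else nb + 1)
                dE = 0.0
                if i > 0:
                    d_old = seq[i - 1] * 4 + old
                    d_new = seq[i - 1] * 4 + new
                    t = theta[i - 1]
                    a = t - t016[d_new]
                    b = t - t016[d_old]
                    dE += 0.5 * (K16[d_new] * a * a - K16[d_old] * b * b)
                if i < n_steps:
                    d_old = old * 4 + seq[i + 1]
                    d_new = new * 4 + seq[i + 1]
                    t = theta[i]
                    a = t - t016[d_new]
                    b = t - t016[d_old]
                    dE += 0.5 * (K16[d_new] * a * a - K16[d_old] * b * b)
                if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                    seq[i] = new
            else:
                n = np.random.randint(n_steps)
                t_old = theta[n]
                t_new = t_old + (2.0 * np.random.random() - 1.0) * step
                d = seq[n] * 4 + seq[n + 1]
                a = t_new - t016[d]
                b = t_old - t016[d]
                dE = 0.5 * K16[d] * (a * a - b * b)
                a = t_new - c[n]
                b = t_old - c[n]
                dE += 0.5 * kappa * (a * a - b * b)
                if lam != 0.0:
                    if n > 0:
                        a = t_new - theta[n - 1]
                        b = t_old - theta[n - 1]
                        dE += 0.5 * lam * (a * a - b * b)
                    if n < n_steps - 1:
                        a = theta[n + 1] - t_new
                        b = theta[n + 1] - t_old
                        dE += 0.5 * lam * (a * a - b * b)
                if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                    theta[n] = t_new
        if sweep >= burn_sweeps and (sweep - burn_sweeps + 1) % thin_sweeps == 0 and rec < n_samples:
            if record_seq:
                out_seq[rec] = seq
            out_E[rec] = total_energy(seq, theta, K16, t016, c, kappa, lam)
            rec += 1
    return out_seq, out_E
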