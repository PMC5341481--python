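import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

import nucleomark as nm
from nucleomark.sequences import encode
from nucleomark.tables import count_oligos
from nucleomark.toy import exact_free_energy_many


def enumerate_sequences(L):
    codes = np.arange(4**L)
    mat = np.empty((4**L, L), dtype=np.uint8)
    for j in range(L):
        mat[:, L - 1 - j] = (codes >> (2 * j)) & 3
    return mat


class TestToyEnergy:
    def test_ground_state_energy_zero(self):
        m = nm.default_toy_model(window_length=8, kappa=0.0)
        seq = nm.random_genome(8, seed=1)
        e = encode(seq)
        theta = m.theta0[e[:-1] * 4 + e[1:]]
        assert nm.toy_energy(m, seq, theta) == pytest.approx(0.0, abs=1e-14)

    def test_constraint_only_energy_sequence_independent(self):
        m = nm.default_toy_model(window_length=8)
        m = m.replace(K=np.full(16, 10.0), theta0=np.zeros(16))
        theta = np.zeros(7)
        expected = 0.5 * m.kappa * np.sum(m.constraint() ** 2)
        for seed in (1, 2):
            seq = nm.random_genome(8, seed=seed)
            assert nm.toy_energy(m, seq, theta) == pytest.approx(expected, abs=1e-12)

    def test_matches_termwise_reference(self):
        rng = np.random.default_rng(2)
        m = nm.default_toy_model(window_length=5, lam=3.0, kappa=7.0)
        seq = "ACGTA"
        theta = rng.normal(size=4)
        e = encode(seq)
        d = e[:-1] * 4 + e[1:]
        c = m.constraint()
        ref = sum(
            0.5 * m.K[d[n]] * (theta[n] - m.theta0[d[n]]) ** 2
            + 0.5 * m.kappa * (theta[n] - c[n]) ** 2
            for n in range(4)
        ) + sum(0.5 * m.lam * (theta[n + 1] - theta[n]) ** 2 for n in range(3))
        assert nm.toy_energy(m, seq, theta) == pytest.approx(ref, abs=1e-12)


class TestExactFreeEnergy:
    def test_two_closed_forms_agree_at_lambda_zero(self):
        m = nm.default_toy_model(window_length=12)
        for seed in range(5):
            s = nm.random_genome(12, seed=seed)
            f1 = nm.exact_free_energy(m, s, method="steps")
            f2 = nm.exact_free_energy(m, s, method="gaussian")
            assert f1 == pytest.approx(f2, abs=1e-10)

    def test_composition_symmetry_without_constraint(self):
        # kappa = 0, lam = 0: F depends on sequence only through the
        # dinucleotide-composition entropy term
        m = nm.default_toy_model(window_length=5, kappa=1e-12)
        # rotations of a cyclic sequence share the dinucleotide-step multiset
        a = "ACGCA"  # steps AC CG GC CA
        b = "CGCAC"  # steps CG GC CA AC
        fa = nm.exact_free_energy(m, a)
        fb = nm.exact_free_energy(m, b)
        assert fa == pytest.approx(fb, abs=1e-8)

    def test_low_temperature_limit_is_minimum_energy(self):
        m = nm.default_toy_model(window_length=6, lam=4.0, beta=1e6)
        s = nm.random_genome(6, seed=3)
        F = nm.exact_free_energy(m, s, method="gaussian")
        res = minimize(lambda th: nm.toy_energy(m, s, th), np.zeros(5), method="BFGS")
        assert F == pytest.approx(res.fun, abs=1e-3)

    def test_gaussian_route_against_dense_linear_algebra(self):
        m = nm.default_toy_model(window_length=7, lam=5.0)
        s = nm.random_genome(7, seed=4)
        ab, b, c0 = m.quadratic_form(encode(s))
        n = b.shape[0]
        M = np.diag(ab[1]) + np.diag(ab[0, 1:], 1) + np.diag(ab[0, 1:], -1)
        kT = m.kT
        ref = c0 - 0.5 * b @ np.linalg.solve(M, b) - 0.5 * kT * (
            n * math.log(2 * math.pi * kT) - np.linalg.slogdet(M)[1]
        )
        assert nm.exact_free_energy(m, s, method="gaussian") == pytest.approx(ref, abs=1e-10)


class TestExactMeanEnergy:
    def test_against_numeric_quadrature(self, toy10):
        # lam = 0: steps decouple, so <E> is a sum of 1-D Gaussian averages
        s = nm.random_genome(10, seed=5)
        e = encode(s)
        d = e[:-1] * 4 + e[1:]
        c = toy10.constraint()
        total = 0.0
        for n in range(9):
            K, t0 = toy10.K[d[n]], toy10.theta0[d[n]]
            En = lambda t: 0.5 * K * (t - t0) ** 2 + 0.5 * toy10.kappa * (t - c[n]) ** 2
            Z = quad(lambda t: np.exp(-toy10.beta * En(t)), -5, 5)[0]
            total += quad(lambda t: En(t) * np.exp(-toy10.beta * En(t)), -5, 5)[0] / Z
        assert nm.exact_mean_energy(toy10, s) == pytest.approx(total, abs=1e-8)

    def test_low_temperature_limit(self):
        m = nm.default_toy_model(window_length=8, beta=1e6, lam=2.0)
        s = nm.random_genome(8, seed=6)
        res = minimize(lambda th: nm.toy_energy(m, s, th), np.zeros(7), method="BFGS")
        assert nm.exact_mean_energy(m, s) == pytest.approx(res.fun, abs=1e-3)


class TestMonteCarloMeanEnergy:
    def test_agrees_with_equipartition_closed_form(self, toy20):
        cfg = nm.MMCConfig(n_samples=8000, burn_in_sweeps=200, thinning_sweeps=1, seed=21)
        s = nm.random_genome(20, seed=7)
        est, se = nm.mc_mean_energy(toy20, s, cfg)
        assert se > 0
        assert abs(est - nm.exact_mean_energy(toy20, s)) < 3 * se

    def test_deterministic(self, toy20):
        cfg = nm.MMCConfig(n_samples=500, burn_in_sweeps=50, thinning_sweeps=1, seed=8)
        s = nm.random_genome(20, seed=9)
        assert nm.mc_mean_energy(toy20, s, cfg) == nm.mc_mean_energy(toy20, s, cfg)


class TestTransferMatrix:
    def test_sequence_independent_model_gives_uniform_marginals(self):
        m = nm.default_toy_model(window_length=10)
        m = m.replace(K=np.full(16, 12.0), theta0=np.full(16, 0.05))
        for k in (1, 2, 3):
            t = m and nm.transfer_matrix_marginals(m, k)
            np.testing.assert_allclose(t.probs, 4.0**-k, atol=1e-12)
            t.validate_simplex()

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, k):
        m = nm.default_toy_model(window_length=6)
        mat = enumerate_sequences(6)
        F = exact_free_energy_many(m, mat)
        w = np.exp(-m.beta * (F - F.min()))
        w /= w.sum()
        tm = nm.transfer_matrix_marginals(m, k)
        brute = np.zeros_like(tm.probs)
        for n in range(tm.probs.shape[0]):
            idx = np.zeros(len(mat), dtype=np.int64)
            for j in range(k):
                idx = idx * 4 + mat[:, n + j]
            np.add.at(brute[n], idx, w)
        np.testing.assert_allclose(tm.probs, brute, atol=1e-10)

    def test_markov_field_exactness_order1(self):
        """An order-1 model built from exact marginals reproduces the toy
        model's free-energy differences exactly (nearest-neighbour field)."""
        m = nm.default_toy_model(window_length=6)
        mk = nm.from_joint_table(nm.transfer_matrix_marginals(m, 2), kT=m.kT)
        mat = enumerate_sequences(6)
        F = exact_free_energy_many(m, mat)
        dev = mk.free_energy_many(mat) - F
        assert dev.max() - dev.min() < 1e-10


class TestMMCSampler:
    def test_deterministic(self, toy10):
        cfg = nm.MMCConfig(n_samples=50, burn_in_sweeps=20, thinning_sweeps=2, seed=5)
        assert nm.mmc_sample(toy10, cfg) == nm.mmc_sample(toy10, cfg)

    def test_sequence_independent_model_gives_uniform_frequencies(self):
        m = nm.default_toy_model(window_length=8)
        m = m.replace(K=np.full(16, 15.0), theta0=np.full(16, -0.1))
        cfg = nm.MMCConfig(n_samples=20_000, burn_in_sweeps=100, thinning_sweeps=2, seed=6)
        seqs = nm.mmc_sample(m, cfg, as_strings=False)
        t = count_oligos(seqs, 1)
        bound = 5 * np.sqrt(0.25 * 0.75 / cfg.n_samples)
        assert np.abs(t.probs - 0.25).max() < bound

    def test_dinucleotide_frequencies_match_transfer_matrix(self, toy10):
        cfg = nm.MMCConfig(n_samples=30_000, burn_in_sweeps=200, thinning_sweeps=4, seed=7)
        seqs = nm.mmc_sample(toy10, cfg, as_strings=False)
        emp = count_oligos(seqs, 2)
        tm = nm.transfer_matrix_marginals(toy10, 2)
        sig = np.sqrt(tm.probs * (1 - tm.probs) / cfg.n_samples)
        z = np.abs(emp.probs - tm.probs) / np.where(sig > 0, sig, 1.0)
        assert (z <= 4).mean() >= 0.95

    def test_requires_mutation_moves(self, toy10):
        with pytest.raises(ValueError):
            nm.mmc_sample(toy10, nm.MMCConfig(n_samples=10, mutation_fraction=0.0))


class TestModelValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            nm.ToyNucleosomeModel(K=np.zeros(16), theta0=np.zeros(16))
        with pytest.raises(ValueError):
            nm.ToyNucleosomeModel(K=np.ones(15), theta0=np.zeros(15))

    def test_json_roundtrip(self, tmp_path):
        m = nm.default_toy_model(lam=2.5)
        p = tmp_path / "toy.json"
        m.to_json(p)
        back = nm.ToyNucleosomeModel.from_json(p)
        np.testing.assert_array_equal(back.K, m.K)
        assert back.lam == 2.5 and back.beta == m.beta
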