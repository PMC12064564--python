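"""Likelihood, predictor components, priors and log-joint against independent oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from microvi.data import AbundanceTable
from microvi.errors import DimensionError, DomainError, ParameterError
from microvi.model import (
    Hyperparameters,
    ModelData,
    ModelParameters,
    ParameterLayout,
    assemble_eta,
    eta_direct,
    eta_interaction,
    eta_latent_coupling,
    inverse_cauchy_logpdf,
    log_joint,
    log_prior,
    make_unconstrained_objective,
    nb_logpmf,
    nb_sample,
)

HYPER = Hyperparameters(k=3, lam=0.7, upsilon=0.8)


def random_instance(rng, n=10, q=8, p=3, r=2, d=2, s=2, k=3):
    """A random small data/parameter pair satisfying all type invariants."""
    W = rng.integers(0, 6, size=(n, q))
    W[:, 0] += 1  # no empty rows
    data = ModelData(
        W=W,
        X=rng.standard_normal((n, p)),
        R=np.eye(r, dtype=int)[rng.integers(0, r, n)],
        D=np.eye(d, dtype=int)[rng.integers(0, d, n)],
        S=np.eye(s, dtype=int)[rng.integers(0, s, n)],
        log_t=rng.normal(0, 0.3, n),
    )
    params = ModelParameters(
        alpha=rng.normal(0, 0.5, (r, k)),
        delta=rng.normal(0, 0.5, (d, k)),
        vartheta=rng.normal(0, 0.5, (s, k)),
        beta=rng.normal(0, 0.5, (k, q)),
        gamma=rng.normal(0, 0.5, (p, q)),
        rho=rng.normal(0, 0.5, (k, q)),
        tau=rng.uniform(0.2, 0.8, q),
        phi=rng.uniform(0.5, 3.0, q),
    )
    return data, params


# ---------------------------------------------------------------------------
# NB log-pmf
# ---------------------------------------------------------------------------

class TestNbLogpmf:
    def test_closed_forms_at_unit_mean_and_dispersion(self):
        assert nb_logpmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5))
        assert nb_logpmf(1, 1.0, 1.0) == pytest.approx(np.log(0.25))

    def test_matches_scipy_nbinom(self):
        rng = np.random.default_rng(1)
        w = rng.integers(0, 40, size=50)
        mean = rng.uniform(0.2, 20.0, size=50)
        phi = rng.uniform(0.3, 8.0, size=50)
        ours = nb_logpmf(w, mean, phi)
        ref = stats.nbinom.logpmf(w, phi, phi / (mean + phi))
        assert np.allclose(ours, ref, rtol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            nb_logpmf(-1, 1.0, 1.0)
        with pytest.raises(DomainError):
            nb_logpmf(1.5, 1.0, 1.0)
        with pytest.raises(DomainError):
            nb_logpmf(1, -1.0, 1.0)

    def test_sampler_moments(self):
        # E(w) = mean, Var(w) = mean + mean^2/phi
        rng = np.random.default_rng(2)
        mean, phi = 1.0, 2.0
        draws = nb_sample(rng, np.full(200_000, mean), phi)
        exp_var = mean + mean**2 / phi
        se_mean = np.sqrt(exp_var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert abs(draws.var() - exp_var) < 0.05


# ---------------------------------------------------------------------------
# predictor components vs loop oracles
# ---------------------------------------------------------------------------

class TestPredictorComponents:
    def test_eta_direct_examples(self):
        assert np.all(eta_direct([[1.0], [2.0]], [[0.0, 0.0]]) == 0)
        assert eta_direct([[1.0], [2.0]], [[3.0]]).tolist() == [[3.0], [6.0]]
        with pytest.raises(DimensionError):
            eta_direct(np.ones((2, 3)), np.ones((2, 3)))

    def test_eta_direct_loop_oracle(self):
        rng = np.random.default_rng(3)
        X, gamma = rng.standard_normal((10, 4)), rng.standard_normal((4, 8))
        out = eta_direct(X, gamma)
        for i in range(10):
            for j in range(8):
                assert out[i, j] == pytest.approx(sum(X[i, :] * gamma[:, j]), abs=1e-12)

    def test_latent_coupling_single_path(self):
        M = np.array([[0, 1]])
        out = eta_latent_coupling(M, [[5.0], [7.0]], [[2.0]])
        assert out[0, 0] == pytest.approx(14.0)

    def test_latent_coupling_loop_oracle(self):
        rng = np.random.default_rng(4)
        M = np.eye(3)[rng.integers(0, 3, 10)]
        coeff, beta = rng.standard_normal((3, 4)), rng.standard_normal((4, 8))
        out = eta_latent_coupling(M, coeff, beta)
        oracle = np.zeros((10, 8))
        for i in range(10):
            for j in range(8):
                for c in range(3):
                    for k in range(4):
                        oracle[i, j] += M[i, c] * coeff[c, k] * beta[k, j]
        assert np.allclose(out, oracle, atol=1e-12)

    def test_interaction_hand_example(self):
        # all taxa present, k=1: eta_I[i, 0] = (rho_0 / 2) * (beta_1 + beta_2)
        presence = np.ones((2, 3), dtype=bool)
        rho = np.array([[1.0, 0.0, 0.0]])
        beta = np.array([[5.0, 1.0, 1.0]])
        out = eta_interaction(presence, rho, beta)
        assert np.allclose(out[:, 0], 1.0)

    def test_interaction_zero_on_absent_and_degenerate(self):
        rng = np.random.default_rng(5)
        presence = rng.random((6, 5)) < 0.5
        presence[0] = [True, False, False, False, False]  # a_i = 1
        rho, beta = rng.standard_normal((3, 5)), rng.standard_normal((3, 5))
        out = eta_interaction(presence, rho, beta)
        assert np.all(out[~presence] == 0)
        assert np.all(out[0] == 0)

    def test_interaction_loop_oracle(self):
        rng = np.random.default_rng(6)
        presence = rng.random((10, 8)) < 0.6
        presence[:, 0] = True
        rho, beta = rng.standard_normal((3, 8)), rng.standard_normal((3, 8))
        out = eta_interaction(presence, rho, beta)
        n, q = presence.shape
        for i in range(n):
            a = presence[i].sum()
            for j in range(q):
                if not presence[i, j] or a < 2:
                    expected = 0.0
                else:
                    acc = np.zeros(3)
                    for m in range(q):
                        if m != j and presence[i, m]:
                            acc += beta[:, m]
                    expected = float(rho[:, j] @ acc) / (a - 1)
                assert out[i, j] == pytest.approx(expected, abs=1e-12)

    def test_assemble_eta_and_ablation(self):
        rng = np.random.default_rng(7)
        data, params = random_instance(rng)
        comps = assemble_eta(data, params)
        assert np.allclose(
            comps.eta, comps.eta_E + comps.eta_P + comps.eta_D + comps.eta_S + comps.eta_I
        )
        assert np.allclose(comps.mu, np.exp(data.log_t[:, None] + comps.eta))
        ablated = assemble_eta(data, params, ablation={"D"})
        assert np.all(ablated.eta_D == 0)
        assert np.allclose(ablated.eta_E, comps.eta_E)

    def test_assemble_eta_trivial_values(self):
        rng = np.random.default_rng(8)
        data, params = random_instance(rng, n=3, q=2)
        zero = ModelParameters(
            alpha=np.zeros_like(params.alpha),
            delta=np.zeros_like(params.delta),
            vartheta=np.zeros_like(params.vartheta),
            beta=np.zeros_like(params.beta),
            gamma=np.zeros_like(params.gamma),
            rho=np.zeros_like(params.rho),
            tau=params.tau,
            phi=params.phi,
        )
        data.log_t = np.zeros(3)
        assert np.allclose(assemble_eta(data, zero).mu, 1.0)
        data.log_t = np.full(3, np.log(3.0))
        zero.gamma = np.zeros_like(params.gamma)
        data.X = np.zeros_like(data.X)
        # eta = log 2 via a constant direct term
        data.X[:, 0] = 1.0
        zero.gamma[0, :] = np.log(2.0)
        assert np.allclose(assemble_eta(data, zero).mu, 6.0)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

class TestPriors:
    def test_laplace_mode_and_flat_tau(self):
        rng = np.random.default_rng(9)
        _, params = random_instance(rng, q=4)
        for name in ("alpha", "delta", "vartheta", "beta", "gamma", "rho"):
            setattr(params, name, np.zeros_like(getattr(params, name)))
        hyper = Hyperparameters(k=3, lam=0.5, upsilon=0.8)
        n_entries = sum(getattr(params, b).size for b in ("alpha", "delta", "vartheta", "beta", "gamma", "rho"))
        expected = -n_entries * np.log(2 * 0.5) + inverse_cauchy_logpdf(params.phi, 0.8).sum()
        assert log_prior(params, hyper) == pytest.approx(float(expected))
        # -log(2*lam) = 0 at lam = 0.5, so coefficient blocks contribute zero
        assert float(-np.log(2 * 0.5)) == 0.0

    def test_inverse_cauchy_normalized_and_equals_scaled_half_cauchy(self):
        for upsilon in (0.3, 1.0, 2.5):
            val, err = integrate.quad(
                lambda x: np.exp(inverse_cauchy_logpdf(x, upsilon)), 0, np.inf
            )
            assert val == pytest.approx(1.0, abs=1e-6)
            xs = np.linspace(0.01, 10, 50)
            ref = stats.halfcauchy.logpdf(xs, scale=1.0 / upsilon)
            assert np.allclose(inverse_cauchy_logpdf(xs, upsilon), ref, rtol=1e-10)

    def test_domain_errors(self):
        rng = np.random.default_rng(10)
        _, params = random_instance(rng)
        params.tau = params.tau.copy()
        params.tau[0] = 1.0
        with pytest.raises(DomainError):
            log_prior(params, HYPER)


# ---------------------------------------------------------------------------
# log-joint
# ---------------------------------------------------------------------------

class TestLogJoint:
    def test_scalar_oracle(self):
        data = ModelData(
            W=np.array([[3]]),
            X=np.zeros((1, 1)),
            R=np.ones((1, 1)),
            D=np.ones((1, 1)),
            S=np.ones((1, 1)),
            log_t=np.array([np.log(2.0)]),
        )
        params = ModelParameters(
            alpha=np.zeros((1, 1)),
            delta=np.zeros((1, 1)),
            vartheta=np.zeros((1, 1)),
            beta=np.zeros((1, 1)),
            gamma=np.zeros((1, 1)),
            rho=np.zeros((1, 1)),
            tau=np.array([0.6]),
            phi=np.array([1.5]),
        )
        hyper = Hyperparameters(k=1, lam=0.5, upsilon=1.0)
        expected = float(nb_logpmf(3, 0.6 * 2.0, 1.5)) + log_prior(params, hyper)
        assert log_joint(data, params, hyper) == pytest.approx(expected)

    def test_additivity_in_samples(self):
        rng = np.random.default_rng(11)
        data, params = random_instance(rng, n=6)
        # adding a sample adds exactly its likelihood rows: compare joint minus
        # prior between the full data and the data without the last sample
        sub = ModelData(
            W=data.W[:-1], X=data.X[:-1], R=data.R[:-1], D=data.D[:-1], S=data.S[:-1],
            log_t=data.log_t[:-1],
        )
        abl = {"I"}  # interaction couples samples only through presence; rows stay independent
        full = log_joint(data, params, HYPER, abl) - log_prior(params, HYPER, abl)
        part = log_joint(sub, params, HYPER, abl) - log_prior(params, HYPER, abl)
        comps = assemble_eta(data, params, abl)
        last = float(
            nb_logpmf(data.W[-1], params.tau * comps.mu[-1], params.phi).sum()
        )
        assert full == pytest.approx(part + last)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        data, params = random_instance(rng)
        pj = rng.permutation(data.q)
        pi = rng.permutation(data.n)
        data2 = ModelData(
            W=data.W[pi][:, pj], X=data.X[pi], R=data.R[pi], D=data.D[pi], S=data.S[pi],
            log_t=data.log_t[pi],
        )
        params2 = ModelParameters(
            alpha=params.alpha, delta=params.delta, vartheta=params.vartheta,
            beta=params.beta[:, pj], gamma=params.gamma[:, pj], rho=params.rho[:, pj],
            tau=params.tau[pj], phi=params.phi[pj],
        )
        assert log_joint(data2, params2, HYPER) == pytest.approx(
            log_joint(data, params, HYPER), rel=1e-12
        )

    def test_full_mask_equals_intercept_only_oracle(self):
        rng = np.random.default_rng(13)
        data, params = random_instance(rng)
        abl = frozenset("EPDSI")
        val = log_joint(data, params, HYPER, abl)
        mmean = params.tau[None, :] * np.exp(data.log_t)[:, None]
        oracle = float(nb_logpmf(data.W, mmean, params.phi[None, :]).sum()) + float(
            inverse_cauchy_logpdf(params.phi, HYPER.upsilon).sum()
        )
        assert val == pytest.approx(oracle)


# ---------------------------------------------------------------------------
# unconstrained layout and gradients
# ---------------------------------------------------------------------------

class TestParameterLayout:
    def test_pack_unpack_round_trip(self):
        rng = np.random.default_rng(14)
        data, params = random_instance(rng)
        layout = ParameterLayout(data.dims, 3)
        again = layout.unpack(layout.pack(params))
        for name in ("alpha", "delta", "vartheta", "beta", "gamma", "rho", "tau", "phi"):
            assert np.allclose(getattr(again, name), getattr(params, name), atol=1e-12)

    def test_boundary_values_rejected(self):
        rng = np.random.default_rng(15)
        data, params = random_instance(rng)
        layout = ParameterLayout(data.dims, 3)
        params.tau = params.tau.copy()
        params.tau[0] = 0.0
        with pytest.raises(DomainError):
            layout.pack(params)

    def test_ablation_removes_exact_block_sizes(self):
        rng = np.random.default_rng(16)
        data, _ = random_instance(rng)
        dims, k = data.dims, 3
        full = ParameterLayout(dims, k).dim
        assert ParameterLayout(dims, k, {"E"}).dim == full - dims["p"] * dims["q"]
        assert ParameterLayout(dims, k, {"P"}).dim == full - dims["r"] * k
        assert ParameterLayout(dims, k, {"I"}).dim == full - k * dims["q"]
        # removing every latent consumer also removes beta
        assert ParameterLayout(dims, k, set("PDSI")).dim == full - k * (
            dims["r"] + dims["d"] + dims["s"] + dims["q"] + dims["q"]
        )

    @pytest.mark.parametrize("ablation", [frozenset(), frozenset("I"), frozenset("EP"), frozenset("EPDSI")])
    def test_gradient_matches_finite_differences(self, ablation):
        rng = np.random.default_rng(17)
        data, _ = random_instance(rng, n=7, q=5)
        layout = ParameterLayout(data.dims, 3, ablation)
        objective = make_unconstrained_objective(data, HYPER, layout)
        zeta = 0.3 * rng.standard_normal(layout.dim)
        val, grad = objective(zeta)
        h = 1e-6
        for i in range(layout.dim):
            zp, zm = zeta.copy(), zeta.copy()
            zp[i] += h
            zm[i] -= h
            fd = (objective(zp)[0] - objective(zm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_objective_value_is_log_joint_plus_jacobian(self):
        rng = np.random.default_rng(18)
        data, _ = random_instance(rng)
        layout = ParameterLayout(data.dims, 3)
        objective = make_unconstrained_objective(data, HYPER, layout)
        zeta = 0.2 * rng.standard_normal(layout.dim)
        val, _ = objective(zeta)
        params = layout.unpack(zeta)
        assert val == pytest.approx(
            log_joint(data, params, HYPER) + layout.log_jacobian(zeta)
        )
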