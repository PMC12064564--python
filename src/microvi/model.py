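"""Generative model: NB likelihood, predictor decomposition, priors, log-joint.

The model couples a samples x taxa count matrix ``W`` to covariates and
context through a log-linear mean with a compositional offset:

    w_ij ~ NB(tau_j * mu_ij, phi_j),      log mu_ij = log t_i + eta_ij,
    eta  = eta_E + (eta_P + eta_D + eta_S) + eta_I,

where the five predictor components are

* ``eta_E = X gamma`` — direct coupling of continuous covariates,
* ``eta_P = R alpha beta``, ``eta_D = D delta beta``, ``eta_S = S vartheta beta``
  — one-hot context categories coupled through a shared k-dimensional latent
  space ``beta`` (k x q), and
* ``eta_I`` — an item-item latent interaction term in the style of shopping-
  basket utility models: for a present taxon j it is the inner product of its
  interaction vector ``rho_.j`` with the average latent vector of the other
  taxa present in the sample, and exactly zero where ``w_ij = 0``.

The NB is parameterized by mean ``m = tau*mu`` and dispersion ``phi`` so that
``E(w) = m`` and ``Var(w) = m + m^2/phi``. Priors: Laplace(0, lambda) on every
coefficient entry, a reciprocal half-Cauchy (scale ``upsilon``) on ``phi`` —
equivalently half-Cauchy(0, 1/upsilon) — and a flat Beta(1,1) on
``tau in (0,1)``.

Everything here is a pure deterministic function of data and parameters. The
module also supplies analytic gradients of the log-joint in the unconstrained
parameterization (identity on coefficients, log on phi, logit on tau) used by
the variational engine; their correctness is checked against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln

from .data import AbundanceTable, ContextDesign, CovariateTable, OffsetVector
from .errors import DimensionError, DomainError, NumericError, ParameterError

__all__ = [
    "COMPONENTS",
    "Hyperparameters",
    "ModelParameters",
    "ModelData",
    "PredictorComponents",
    "ParameterLayout",
    "nb_logpmf",
    "nb_sample",
    "eta_direct",
    "eta_latent_coupling",
    "eta_interaction",
    "assemble_eta",
    "log_prior",
    "log_joint",
    "build_model_data",
    "make_unconstrained_objective",
]

#: Predictor component codes: direct environmental, province, depth, season,
#: and taxon-taxon interaction.
COMPONENTS = ("E", "P", "D", "S", "I")

_BLOCK_OF_COMPONENT = {"E": "gamma", "P": "alpha", "D": "delta", "S": "vartheta", "I": "rho"}


def _check_ablation(ablation) -> frozenset:
    ablation = frozenset(ablation or ())
    unknown = ablation - set(COMPONENTS)
    if unknown:
        raise ParameterError(f"unknown component codes: {sorted(unknown)}")
    return ablation


@dataclass(frozen=True)
class Hyperparameters:
    """Latent dimension ``k``, Laplace scale ``lam``, dispersion-prior scale ``upsilon``."""

    k: int
    lam: float
    upsilon: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("latent dimension k must be >= 1")
        if self.lam <= 0 or self.upsilon <= 0:
            raise ParameterError("lam and upsilon must be positive")


@dataclass
class ModelParameters:
    """The full latent parameter set with shape metadata.

    Shapes: alpha (r,k), delta (d,k), vartheta (s,k), beta (k,q), gamma (p,q),
    rho (k,q), tau (q,) in (0,1), phi (q,) positive.
    """

    alpha: np.ndarray
    delta: np.ndarray
    vartheta: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    rho: np.ndarray
    tau: np.ndarray
    phi: np.ndarray

    def validate(self) -> None:
        for name in ("alpha", "delta", "vartheta", "beta", "gamma", "rho", "tau", "phi"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise DomainError(f"non-finite entries in {name}")
        if np.any(self.tau <= 0) or np.any(self.tau >= 1):
            raise DomainError("tau must lie strictly inside (0, 1)")
        if np.any(self.phi <= 0):
            raise DomainError("phi must be strictly positive")

    @property
    def coefficient_blocks(self) -> dict:
        return {
            "alpha": self.alpha,
            "delta": self.delta,
            "vartheta": self.vartheta,
            "beta": self.beta,
            "gamma": self.gamma,
            "rho": self.rho,
        }


@dataclass
class PredictorComponents:
    """The five predictor components, their sum ``eta`` and the mean ``mu``."""

    eta_E: np.ndarray
    eta_P: np.ndarray
    eta_D: np.ndarray
    eta_S: np.ndarray
    eta_I: np.ndarray
    eta: np.ndarray
    mu: np.ndarray


@dataclass
class ModelData:
    """Aligned model-ready arrays plus an observation mask.

    ``obs_mask`` marks the cells that enter the likelihood (and the presence
    sums of the interaction term); cross-validation masks held-out cells here.
    """

    W: np.ndarray
    X: np.ndarray
    R: np.ndarray
    D: np.ndarray
    S: np.ndarray
    log_t: np.ndarray
    obs_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        n, q = self.W.shape
        if self.obs_mask is None:
            self.obs_mask = np.ones((n, q), dtype=bool)
        self.obs_mask = np.asarray(self.obs_mask, dtype=bool)
        for name, arr, rows in (
            ("X", self.X, n),
            ("R", self.R, n),
            ("D", self.D, n),
            ("S", self.S, n),
        ):
            if np.asarray(arr).shape[0] != rows:
                raise DimensionError(f"{name} has {np.asarray(arr).shape[0]} rows, expected {rows}")
        if np.asarray(self.log_t).shape != (n,):
            raise DimensionError("log_t must have one entry per sample")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def dims(self) -> dict:
        return {
            "n": self.n,
            "q": self.q,
            "p": self.X.shape[1],
            "r": self.R.shape[1],
            "d": self.D.shape[1],
            "s": self.S.shape[1],
        }

    @property
    def presence(self) -> np.ndarray:
        """Observed-and-present mask: nonzero counts among observed cells."""
        return (self.W > 0) & self.obs_mask


def build_model_data(
    table: AbundanceTable,
    covariates: CovariateTable,
    design: ContextDesign,
    offsets: OffsetVector,
    obs_mask: np.ndarray | None = None,
) -> ModelData:
    """Bundle preprocessed inputs into a :class:`ModelData`."""
    return ModelData(
        W=table.counts,
        X=covariates.X,
        R=design.R,
        D=design.D,
        S=design.S,
        log_t=offsets.log_t,
        obs_mask=obs_mask,
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def nb_logpmf(w, mean, dispersion):
    """Log-pmf of the NB distribution in mean/dispersion form.

    ``E(w) = mean`` and ``Var(w) = mean + mean^2/dispersion``. Implemented with
    log-gamma functions for numerical stability. ``w`` must be a non-negative
    integer (array).
    """
    w = np.asarray(w)
    if np.any(w < 0) or (not np.issubdtype(w.dtype, np.integer) and np.any(w % 1 != 0)):
        raise DomainError("w must be non-negative integers")
    w = w.astype(np.int64)
    m = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    if np.any(m <= 0) or np.any(phi <= 0):
        raise DomainError("mean and dispersion must be positive")
    return (
        gammaln(w + phi)
        - gammaln(phi)
        - gammaln(w + 1)
        + w * np.log(m)
        + phi * np.log(phi)
        - (w + phi) * np.log(m + phi)
    )


def nb_sample(rng: np.random.Generator, mean, dispersion, size=None):
    """Draw NB counts with the mean/dispersion parameterization.

    Uses the (size = phi, prob = phi/(mean+phi)) mapping implied by the pmf.
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    return rng.negative_binomial(np.broadcast_to(phi, np.broadcast_shapes(mean.shape, phi.shape)),
                                 phi / (mean + phi), size=size)


# ---------------------------------------------------------------------------
# Predictor components
# ---------------------------------------------------------------------------

def eta_direct(X, gamma) -> np.ndarray:
    """Direct covariate coupling ``eta_E[i, j] = x_i . gamma_.j``."""
    X = np.asarray(X, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if X.ndim != 2 or gamma.ndim != 2 or X.shape[1] != gamma.shape[0]:
        raise DimensionError(f"cannot multiply X {X.shape} by gamma {gamma.shape}")
    return X @ gamma


def eta_latent_coupling(M, coeff, beta) -> np.ndarray:
    """Latent-space coupling ``M coeff beta`` of a one-hot category matrix.

    Because rows of ``M`` are one-hot, row i equals the coefficient row of
    sample i's category multiplied into the shared latent space ``beta``.
    """
    M = np.asarray(M, dtype=float)
    coeff = np.asarray(coeff, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if M.shape[1] != coeff.shape[0] or coeff.shape[1] != beta.shape[0]:
        raise DimensionError(
            f"shapes do not conform: M {M.shape}, coeff {coeff.shape}, beta {beta.shape}"
        )
    return (M @ coeff) @ beta


def eta_interaction(presence, rho, beta, active=None) -> np.ndarray:
    """Latent taxon-taxon interaction component.

    For a cell with the nonzero branch active, the value is the inner product
    of ``rho_.j`` with the average latent vector of the *other* present taxa of
    the sample; it is exactly zero where the count is zero. ``presence`` gives
    the taxa whose latent vectors enter the sums (and the averaging
    denominator); ``active`` (default: ``presence``) selects the cells on which
    the nonzero branch is evaluated, which lets held-out cells be scored
    against the training presence pattern. Samples with fewer than two present
    taxa yield zero (empty interaction sum).
    """
    if isinstance(presence, AbundanceTable):
        presence = presence.presence
    P = np.asarray(presence, dtype=float)
    rho = np.asarray(rho, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if rho.shape != beta.shape or P.shape[1] != beta.shape[1]:
        raise DimensionError(
            f"shapes do not conform: presence {P.shape}, rho {rho.shape}, beta {beta.shape}"
        )
    A = P if active is None else np.asarray(active, dtype=float)
    ssum = P @ beta.T                                  # (n, k) sums of present latent vectors
    cross = ssum @ rho                                 # (n, q)
    diag = np.einsum("kq,kq->q", rho, beta)            # rho_.j . beta_.j
    count = P.sum(axis=1, keepdims=True) - P           # number of *other* present taxa
    scale = np.where(count >= 1, 1.0 / np.maximum(count, 1.0), 0.0)
    return A * scale * (cross - P * diag)


def assemble_eta(
    data: ModelData,
    params: ModelParameters,
    ablation=frozenset(),
) -> PredictorComponents:
    """Compute all predictor components, their sum and the mean matrix ``mu``.

    ``ablation`` is a set of component codes from :data:`COMPONENTS`; named
    components are zeroed out exactly.
    """
    ablation = _check_ablation(ablation)
    n, q = data.W.shape
    zeros = np.zeros((n, q))
    e = zeros if "E" in ablation else eta_direct(data.X, params.gamma)
    p = zeros if "P" in ablation else eta_latent_coupling(data.R, params.alpha, params.beta)
    d = zeros if "D" in ablation else eta_latent_coupling(data.D, params.delta, params.beta)
    s = zeros if "S" in ablation else eta_latent_coupling(data.S, params.vartheta, params.beta)
    i = zeros if "I" in ablation else eta_interaction(data.presence, params.rho, params.beta)
    eta = e + p + d + s + i
    mu = np.exp(data.log_t[:, None] + eta)
    if not np.all(np.isfinite(mu)):
        ii, jj = np.argwhere(~np.isfinite(mu))[0]
        raise NumericError(f"non-finite mean at sample {ii}, taxon {jj} (eta={eta[ii, jj]})")
    return PredictorComponents(eta_E=e, eta_P=p, eta_D=d, eta_S=s, eta_I=i, eta=eta, mu=mu)


# ---------------------------------------------------------------------------
# Priors and log-joint
# ---------------------------------------------------------------------------

def _laplace_logpdf_sum(x: np.ndarray, lam: float) -> float:
    return -x.size * np.log(2.0 * lam) - float(np.abs(x).sum()) / lam


def inverse_cauchy_logpdf(phi, upsilon: float):
    """Log-density of the reciprocal of a half-Cauchy(0, upsilon) variable.

    Closed form: the reciprocal of a half-Cauchy(0, u) variable is itself
    half-Cauchy with scale 1/u, so the normalized density on phi > 0 is
    ``(2 u / pi) / (1 + (u phi)^2)``.
    """
    phi = np.asarray(phi, dtype=float)
    return np.log(2.0 * upsilon / np.pi) - np.log1p((upsilon * phi) ** 2)


def log_prior(params: ModelParameters, hyper: Hyperparameters, ablation=frozenset()) -> float:
    """Sum of independent log prior densities over the active parameter blocks."""
    ablation = _check_ablation(ablation)
    params.validate()
    active = _active_blocks(ablation)
    total = 0.0
    for name, arr in params.coefficient_blocks.items():
        if name in active:
            total += _laplace_logpdf_sum(np.asarray(arr, dtype=float), hyper.lam)
    total += float(inverse_cauchy_logpdf(params.phi, hyper.upsilon).sum())
    # Beta(1,1) on tau contributes log-density 0 on (0,1).
    return total


def log_joint(
    data: ModelData,
    params: ModelParameters,
    hyper: Hyperparameters,
    ablation=frozenset(),
) -> float:
    """Log of likelihood times prior, with held-out cells masked out.

    The likelihood sums over every observed (i, j) cell including zeros; an
    ablation mask removes the named components from both the predictor and the
    prior.
    """
    ablation = _check_ablation(ablation)
    comps = assemble_eta(data, params, ablation)
    mmean = params.tau[None, :] * comps.mu
    ll = nb_logpmf(data.W, mmean, params.phi[None, :])
    return float(ll[data.obs_mask].sum()) + log_prior(params, hyper, ablation)


def _active_blocks(ablation: frozenset) -> list[str]:
    blocks = []
    for comp, blk in _BLOCK_OF_COMPONENT.items():
        if comp not in ablation:
            blocks.append(blk)
    if not {"P", "D", "S", "I"} <= ablation:
        blocks.append("beta")
    return blocks


# ---------------------------------------------------------------------------
# Unconstrained parameterization
# ---------------------------------------------------------------------------

class ParameterLayout:
    """Ordered flat layout of the *active* parameter blocks.

    Coefficients map by identity, ``phi`` by log, ``tau`` by logit; the layout
    packs/unpacks flat unconstrained vectors and reports the total log-Jacobian
    of the constraining transform. Ablated blocks are excluded entirely (their
    constrained value is fixed at zero), so the free-parameter count shrinks by
    exactly the removed block size.
    """

    _SHAPES = ("alpha", "delta", "vartheta", "beta", "gamma", "rho", "tau", "phi")

    def __init__(self, dims: dict, k: int, ablation=frozenset()):
        self.dims = dict(dims)
        self.k = int(k)
        self.ablation = _check_ablation(ablation)
        q, p = dims["q"], dims["p"]
        r, d, s = dims["r"], dims["d"], dims["s"]
        shapes = {
            "alpha": (r, k),
            "delta": (d, k),
            "vartheta": (s, k),
            "beta": (k, q),
            "gamma": (p, q),
            "rho": (k, q),
            "tau": (q,),
            "phi": (q,),
        }
        active = set(_active_blocks(self.ablation)) | {"tau", "phi"}
        self.blocks: list[tuple[str, tuple, slice]] = []
        offset = 0
        for name in self._SHAPES:
            if name not in active:
                continue
            size = int(np.prod(shapes[name]))
            self.blocks.append((name, shapes[name], slice(offset, offset + size)))
            offset += size
        self.dim = offset
        self._shapes = shapes

    def slice_of(self, name: str) -> slice:
        for blk, _, sl in self.blocks:
            if blk == name:
                return sl
        raise KeyError(name)

    @property
    def active_names(self) -> list[str]:
        return [name for name, _, _ in self.blocks]

    def unpack(self, zeta: np.ndarray) -> ModelParameters:
        """Map a flat unconstrained vector to constrained :class:`ModelParameters`.

        Inactive blocks come back as zero arrays of the right shape so the
        predictor functions remain applicable.
        """
        zeta = np.asarray(zeta, dtype=float)
        vals = {name: np.zeros(self._shapes[name]) for name in self._SHAPES}
        for name, shape, sl in self.blocks:
            x = zeta[sl].reshape(shape)
            if name == "phi":
                x = np.exp(x)
            elif name == "tau":
                x = expit(x)
            vals[name] = x
        return ModelParameters(**vals)

    def pack(self, params: ModelParameters) -> np.ndarray:
        """Inverse of :meth:`unpack` (boundary values of tau/phi are rejected)."""
        out = np.empty(self.dim)
        for name, shape, sl in self.blocks:
            x = np.asarray(getattr(params, name), dtype=float)
            if name == "phi":
                if np.any(x <= 0):
                    raise DomainError("phi must be positive to map to log scale")
                x = np.log(x)
            elif name == "tau":
                if np.any(x <= 0) or np.any(x >= 1):
                    raise DomainError("tau must lie in (0,1) to map to logit scale")
                x = np.log(x) - np.log1p(-x)
            out[sl] = x.reshape(-1)
        return out

    def log_jacobian(self, zeta: np.ndarray) -> float:
        """Log |det J| of the unconstrained -> constrained map at ``zeta``."""
        zeta = np.asarray(zeta, dtype=float)
        u = zeta[self.slice_of("phi")]
        v = zeta[self.slice_of("tau")]
        # d phi / d u = e^u; d tau / d v = sigma(v)(1 - sigma(v))
        softplus = np.logaddexp(0.0, v)
        return float(u.sum()) + float((v - 2.0 * softplus).sum())


def make_unconstrained_objective(data: ModelData, hyper: Hyperparameters, layout: ParameterLayout):
    """Closure computing ``log_joint + log|J|`` and its gradient at a flat vector.

    This is the objective whose reparameterized Monte-Carlo average the
    variational engine maximizes (entropy added there analytically).
    """
    ablation = layout.ablation
    W = np.asarray(data.W, dtype=np.int64)
    mask = data.obs_mask
    maskf = mask.astype(float)
    X = np.asarray(data.X, dtype=float)
    R = np.asarray(data.R, dtype=float)
    Dm = np.asarray(data.D, dtype=float)
    S = np.asarray(data.S, dtype=float)
    log_t = np.asarray(data.log_t, dtype=float)
    P = data.presence.astype(float)
    a = P.sum(axis=1)
    c = np.where(a > 1, 1.0 / np.maximum(a - 1.0, 1.0), 0.0)  # 1/(a_i - 1), 0 if degenerate
    lam, upsilon = hyper.lam, hyper.upsilon
    active = set(layout.active_names)

    def objective(zeta: np.ndarray):
        params = layout.unpack(zeta)
        tau, phi = params.tau, params.phi
        beta, rho, gamma = params.beta, params.rho, params.gamma

        eta = np.zeros_like(P)
        Z = np.zeros((W.shape[0], layout.k))  # combined context coefficient rows
        if "gamma" in active:
            eta += X @ gamma
        if "alpha" in active:
            Z += R @ params.alpha
        if "delta" in active:
            Z += Dm @ params.delta
        if "vartheta" in active:
            Z += S @ params.vartheta
        if "beta" in active:
            eta += Z @ beta
        if "rho" in active:
            ssum = P @ beta.T
            diag = np.einsum("kq,kq->q", rho, beta)
            eta += P * c[:, None] * (ssum @ rho - P * diag)

        mu = np.exp(log_t[:, None] + eta)
        mmean = tau[None, :] * mu
        denom = mmean + phi[None, :]
        ll = (
            gammaln(W + phi[None, :])
            - gammaln(phi[None, :])
            - gammaln(W + 1)
            + W * np.log(mmean)
            + phi[None, :] * np.log(phi[None, :])
            - (W + phi[None, :]) * np.log(denom)
        )
        value = float((ll * maskf).sum())

        # dll/deta on observed cells
        G = maskf * (W - (W + phi[None, :]) * mmean / denom)

        grad = np.zeros(layout.dim)
        if "gamma" in active:
            g = X.T @ G - np.sign(gamma) / lam
            grad[layout.slice_of("gamma")] = g.reshape(-1)
            value += _laplace_logpdf_sum(gamma, lam)
        if "beta" in active:
            GB = G @ beta.T  # (n, k)
            grad_beta = Z.T @ G
            for blk, M in (("alpha", R), ("delta", Dm), ("vartheta", S)):
                if blk in active:
                    arr = getattr(params, blk)
                    g = M.T @ GB - np.sign(arr) / lam
                    grad[layout.slice_of(blk)] = g.reshape(-1)
                    value += _laplace_logpdf_sum(arr, lam)
            if "rho" in active:
                A = G * P * c[:, None]
                colsum = A.sum(axis=0)
                grad_rho = ssum.T @ A - beta * colsum[None, :] - np.sign(rho) / lam
                grad[layout.slice_of("rho")] = grad_rho.reshape(-1)
                grad_beta += (rho @ A.T) @ P - rho * colsum[None, :]
                value += _laplace_logpdf_sum(rho, lam)
            grad_beta -= np.sign(beta) / lam
            grad[layout.slice_of("beta")] = grad_beta.reshape(-1)
            value += _laplace_logpdf_sum(beta, lam)

        # tau: dll/dtau_j = sum_i G_ij / tau_j; flat prior; logit Jacobian
        grad_tau = G.sum(axis=0) / tau
        v = zeta[layout.slice_of("tau")]
        value += float((v - 2.0 * np.logaddexp(0.0, v)).sum())
        grad[layout.slice_of("tau")] = tau * (1.0 - tau) * grad_tau + (1.0 - 2.0 * tau)

        # phi: likelihood + reciprocal-half-Cauchy prior; log Jacobian
        dphi = (
            maskf
            * (
                digamma(W + phi[None, :])
                - digamma(phi[None, :])
                + np.log(phi[None, :])
                + 1.0
                - np.log(denom)
                - (W + phi[None, :]) / denom
            )
        ).sum(axis=0)
        dphi += -2.0 * upsilon**2 * phi / (1.0 + (upsilon * phi) ** 2)
        value += float(inverse_cauchy_logpdf(phi, upsilon).sum())
        value += float(np.log(phi).sum())  # log Jacobian of exp
        grad[layout.slice_of("phi")] = phi * dphi + 1.0

        return value, grad

    return objective
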