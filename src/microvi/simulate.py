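"""Ground-truth-known synthetic microbiome surveys from the generative model.

The generator runs the model forward: covariates are standard normal (then
mean-centered), context categories uniform one-hot, coefficients drawn at
user-set scales with optional exact zeros (Laplace-like sparsity), shape
parameters ``tau`` uniform on a sub-interval of (0,1) and dispersions ``phi``
log-uniform on a positive range. Counts are NB draws with the full predictor.

The interaction component conditions on which taxa are present, which is
circular at generation time; counts are therefore drawn in two passes: pass
one without the interaction term, pass two redrawing counts with the
interaction evaluated on the pass-one presence pattern. Offsets are unity at
generation (``t_i = 1``) so the estimated offsets are part of what the
fitting pipeline must absorb, as with real data.

Optionally the latent columns of ``beta`` are planted around well-separated
centroids so that latent-space module recovery can be scored against a known
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AbundanceTable, ContextDesign, ContextLevels, CovariateTable, OffsetVector
from .errors import ParameterError, ScenarioError
from .model import ModelParameters, eta_interaction, nb_sample

__all__ = ["ScenarioSpec", "draw_parameters", "simulate_counts", "SimulatedDataset"]

_ETA_OVERFLOW = 30.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Dimensions, effect scales and nuisance ranges of a synthetic scenario.

    Defaults describe a small but identifiable survey: n=60 samples, q=30
    taxa, p=3 covariates, binary province/depth/season, latent dimension 5,
    three planted latent modules, and moderate overdispersion.
    """

    n: int = 60
    q: int = 30
    p: int = 3
    r: int = 2
    d: int = 2
    s: int = 2
    k_true: int = 5
    sd_alpha: float = 0.6
    sd_delta: float = 0.6
    sd_vartheta: float = 0.6
    sd_beta: float = 1.0
    sd_gamma: float = 0.75
    sd_rho: float = 0.3
    tau_range: tuple = (0.2, 0.8)
    phi_range: tuple = (0.5, 2.0)
    module_structure: int | None = 3
    module_noise: float = 0.1
    sparsity: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n", "q", "p", "r", "d", "s", "k_true"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        lo, hi = self.tau_range
        if not (0 < lo < hi < 1):
            raise ParameterError("tau_range must be an interval inside (0, 1)")
        lo, hi = self.phi_range
        if not (0 < lo <= hi):
            raise ParameterError("phi_range must be a positive interval")
        if not 0 <= self.sparsity < 1:
            raise ParameterError("sparsity must lie in [0, 1)")
        if self.module_structure is not None and self.module_structure > self.k_true:
            raise ParameterError("module_structure cannot exceed k_true")


@dataclass
class SimulatedDataset:
    """A simulated survey with its generating truth."""

    table: AbundanceTable
    covariates: CovariateTable
    design: ContextDesign
    offsets: OffsetVector
    truth: ModelParameters
    module_labels: np.ndarray | None


def _sparsify(arr: np.ndarray, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    if sparsity > 0:
        arr = arr * (rng.random(arr.shape) >= sparsity)
    return arr


def _planted_beta(spec: ScenarioSpec, rng: np.random.Generator, context_coeffs: np.ndarray):
    """Latent columns around g well-separated planted centroids.

    Centroids are a regular-simplex arrangement (pairwise cosine -1/(g-1),
    i.e. cosine distance 1 + 1/(g-1) > 0.5) embedded in the leading right-
    singular subspace of the stacked context coefficient rows. Communities
    thus differ maximally in angle *and* carry distinct spatiotemporal
    signatures, the feature the latent coupling is designed to express.
    """
    k, q, g = spec.k_true, spec.q, spec.module_structure
    if g is None or g < 2:
        return rng.normal(0.0, spec.sd_beta, size=(k, q)), None
    if g > k:
        raise ParameterError("module_structure cannot exceed k_true")
    _, _, Vt = np.linalg.svd(context_coeffs)
    basis = Vt[: g - 1].T  # k x (g-1) directions the context coupling reads
    M = np.eye(g) - np.ones((g, g)) / g
    _, _, V2 = np.linalg.svd(M, full_matrices=False)
    simplex = M @ V2[: g - 1].T
    simplex /= np.linalg.norm(simplex, axis=1, keepdims=True)
    centroids = (basis @ simplex.T) * spec.sd_beta * np.sqrt(k)
    labels = rng.integers(0, g, size=q)
    # guarantee every module is populated
    labels[rng.permutation(q)[:g]] = np.arange(g)
    noise = rng.normal(0.0, spec.module_noise * spec.sd_beta, size=(k, q))
    return centroids[:, labels] + noise, labels


def draw_parameters(spec: ScenarioSpec, rng=None) -> tuple[ModelParameters, np.ndarray | None]:
    """Draw ground-truth parameters; returns (truth, module labels or None)."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    k = spec.k_true
    alpha = rng.normal(0.0, spec.sd_alpha, size=(spec.r, k))
    delta = rng.normal(0.0, spec.sd_delta, size=(spec.d, k))
    vartheta = rng.normal(0.0, spec.sd_vartheta, size=(spec.s, k))
    beta, labels = _planted_beta(spec, rng, np.vstack([alpha, delta, vartheta]))
    params = ModelParameters(
        alpha=alpha,
        delta=delta,
        vartheta=vartheta,
        beta=beta,
        gamma=_sparsify(
            rng.normal(0.0, spec.sd_gamma, size=(spec.p, spec.q)), spec.sparsity, rng
        ),
        rho=_sparsify(rng.normal(0.0, spec.sd_rho, size=(k, spec.q)), spec.sparsity, rng),
        tau=rng.uniform(*spec.tau_range, size=spec.q),
        phi=np.exp(rng.uniform(np.log(spec.phi_range[0]), np.log(spec.phi_range[1]), size=spec.q)),
    )
    # zero effect scales must give exactly zero couplings
    for name, sd in (
        ("alpha", spec.sd_alpha),
        ("delta", spec.sd_delta),
        ("vartheta", spec.sd_vartheta),
        ("beta", spec.sd_beta),
        ("gamma", spec.sd_gamma),
        ("rho", spec.sd_rho),
    ):
        if sd == 0:
            setattr(params, name, np.zeros_like(getattr(params, name)))
    return params, labels


def _one_hot_uniform(rng, n, c):
    M = np.zeros((n, c), dtype=np.int64)
    M[np.arange(n), rng.integers(0, c, size=n)] = 1
    return M


def simulate_counts(truth: ModelParameters, spec: ScenarioSpec, rng=None) -> SimulatedDataset:
    """Run the generative process forward from known truth.

    Two-pass scheme for the presence-conditional interaction term (see module
    docstring). Rows that come out empty are redrawn so every sample has at
    least one present taxon.
    """
    rng = np.random.default_rng(spec.seed + 1 if rng is None else rng)
    n, q = spec.n, spec.q
    X = rng.standard_normal((n, spec.p))
    X = X - X.mean(axis=0, keepdims=True)
    R = _one_hot_uniform(rng, n, spec.r)
    D = _one_hot_uniform(rng, n, spec.d)
    S = _one_hot_uniform(rng, n, spec.s)

    eta_fixed = (
        X @ truth.gamma
        + (R @ truth.alpha + D @ truth.delta + S @ truth.vartheta) @ truth.beta
    )
    if np.any(np.abs(eta_fixed) > _ETA_OVERFLOW):
        raise ScenarioError(
            "predictor exceeds a safe range; choose smaller effect scales"
        )
    mmean = truth.tau[None, :] * np.exp(eta_fixed)  # t_i = 1 at generation

    w1 = nb_sample(rng, mmean, truth.phi[None, :])
    presence = w1 > 0
    eta = eta_fixed + eta_interaction(presence, truth.rho, truth.beta)
    if np.any(np.abs(eta) > _ETA_OVERFLOW):
        raise ScenarioError("predictor exceeds a safe range; choose smaller effect scales")
    counts = nb_sample(rng, truth.tau[None, :] * np.exp(eta), truth.phi[None, :])

    # every sample must have at least one present taxon
    for _ in range(100):
        empty = counts.sum(axis=1) == 0
        if not empty.any():
            break
        idx = np.flatnonzero(empty)
        counts[idx] = nb_sample(
            rng, truth.tau[None, :] * np.exp(eta[idx]), truth.phi[None, :]
        )
    else:
        # pathological scenario; force the largest-mean taxon to be observed once
        for i in np.flatnonzero(counts.sum(axis=1) == 0):
            counts[i, np.argmax(eta[i])] = 1

    # reuse the survey level names where they fit so written TSVs round-trip
    # through the default reader configuration
    base = ContextLevels()
    levels = ContextLevels(
        provinces=base.provinces[: spec.r]
        if spec.r <= len(base.provinces)
        else tuple(f"P{j + 1}" for j in range(spec.r)),
        depths=base.depths[: spec.d]
        if spec.d <= len(base.depths)
        else tuple(f"D{j + 1}" for j in range(spec.d)),
        seasons=base.seasons[: spec.s]
        if spec.s <= len(base.seasons)
        else tuple(f"Q{j + 1}" for j in range(spec.s)),
    )
    table = AbundanceTable(
        counts=counts,
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        taxon_ids=[f"T{j + 1:04d}" for j in range(q)],
    )
    covariates = CovariateTable(
        X=X, covariate_names=[f"x{j + 1}" for j in range(spec.p)], centered=True
    )
    design = ContextDesign(
        R=R,
        D=D,
        S=S,
        province_levels=levels.provinces,
        depth_levels=levels.depths,
        season_levels=levels.seasons,
    )
    offsets = OffsetVector(t=np.ones(n))
    return SimulatedDataset(
        table=table,
        covariates=covariates,
        design=design,
        offsets=offsets,
        truth=truth,
        module_labels=None,
    )


def simulate_scenario(spec: ScenarioSpec) -> SimulatedDataset:
    """Draw truth and data for a scenario in one call (seeded by the spec)."""
    root = np.random.SeedSequence(spec.seed)
    truth_rng, count_rng = [np.random.default_rng(s) for s in root.spawn(2)]
    truth, labels = draw_parameters(spec, truth_rng)
    ds = simulate_counts(truth, spec, count_rng)
    ds.module_labels = labels
    return ds
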