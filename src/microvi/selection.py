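"""Hyperparameter search, cross-validated LLPD, multi-start robustness, ablation.

Model selection scores a hyperparameter setting (latent dimension ``k``,
Laplace scale ``lambda``, dispersion-prior scale ``upsilon``) by the held-out
log posterior predictive density (LLPD) under random-cell cross-validation:
cells of the count matrix are partitioned into folds, the model is fitted with
each fold's cells strictly masked out of the likelihood *and* of the
interaction term's presence sums, and the fold is scored by the per-cell LLPD.

Whole-sample holdout is deliberately not used: the interaction component and
the compositional offset both need the sample's own presence pattern, which an
entirely unseen sample does not have.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MicroviError, ParameterError
from .model import COMPONENTS, Hyperparameters, ModelData
from .vi import FitOptions, fit, llpd, sample_posterior

__all__ = [
    "SearchSpec",
    "AblationReport",
    "fold_masks",
    "crossval_llpd",
    "random_search",
    "multi_init",
    "ablate",
]


@dataclass(frozen=True)
class SearchSpec:
    """Random-search configuration.

    ``k`` is sampled uniformly over its integer range, ``lambda`` and
    ``upsilon`` log-uniformly. Published-scale defaults (50 draws, 5 folds,
    50 initializations) are configuration, not hard-coded; reduced budgets are
    legitimate for small studies.
    """

    n_draws: int = 50
    k_range: tuple = (25, 300)
    lambda_range: tuple = (0.01, 1.0)
    upsilon_range: tuple = (0.01, 1.0)
    folds: int = 5
    inits_per_setting: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ParameterError("n_draws must be >= 1")
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if self.k_range[0] > self.k_range[1] or self.k_range[0] < 1:
            raise ParameterError("invalid k_range")


@dataclass
class AblationReport:
    """Cross-validated LLPD of an ablated model next to the full model."""

    component: str
    mean_llpd: float
    fold_llpds: list
    full_mean_llpd: float
    full_fold_llpds: list


def fold_masks(n: int, q: int, folds: int, rng: np.random.Generator):
    """Random-cell partition of an n x q matrix into ``folds`` boolean masks.

    The masks are disjoint and exhaustive; each cell is held out exactly once.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if folds > n * q:
        raise ParameterError("more folds than cells: some fold would be empty")
    perm = rng.permutation(n * q)
    masks = []
    for chunk in np.array_split(perm, folds):
        m = np.zeros(n * q, dtype=bool)
        m[chunk] = True
        masks.append(m.reshape(n, q))
    return masks


def crossval_llpd(
    data: ModelData,
    hyper: Hyperparameters,
    folds: int,
    seed: int,
    fit_opts: FitOptions = FitOptions(),
    ablation=frozenset(),
    m_samples: int = 25,
):
    """Per-fold and mean held-out LLPD under random-cell cross-validation."""
    rng = np.random.default_rng(seed)
    masks = fold_masks(data.n, data.q, folds, rng)
    fold_seeds = np.random.SeedSequence(seed).generate_state(2 * folds) % (2**31)
    scores = []
    for f, held in enumerate(masks):
        train = replace(data, obs_mask=data.obs_mask & ~held)
        opts = replace(fit_opts, seed=int(fold_seeds[2 * f]), ablation=frozenset(ablation))
        result = fit(train, hyper, opts)
        samples = sample_posterior(result, m_samples, int(fold_seeds[2 * f + 1]))
        scores.append(llpd(samples, train, held & data.obs_mask, ablation=frozenset(ablation)))
    return scores, float(np.mean(scores))


def random_search(
    data: ModelData,
    spec: SearchSpec,
    fit_opts: FitOptions = FitOptions(),
    m_samples: int = 25,
) -> pd.DataFrame:
    """Randomly sample hyperparameter settings and rank them by mean CV LLPD.

    Settings whose fits fail are marked ``status="failed"`` and excluded from
    the ranking (they sort last with NaN scores). Fully seeded: identical
    ``spec.seed`` gives an identical table.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for draw in range(spec.n_draws):
        k = int(rng.integers(spec.k_range[0], spec.k_range[1] + 1))
        lam = float(np.exp(rng.uniform(*np.log(spec.lambda_range))))
        upsilon = float(np.exp(rng.uniform(*np.log(spec.upsilon_range))))
        hyper = Hyperparameters(k=k, lam=lam, upsilon=upsilon)
        cv_seed = int(rng.integers(0, 2**31 - 1))
        try:
            scores, mean = crossval_llpd(
                data, hyper, spec.folds, cv_seed, fit_opts, m_samples=m_samples
            )
            status = "ok"
        except (MicroviError, FloatingPointError) as exc:  # pragma: no cover - rare
            scores, mean, status = [], float("nan"), f"failed: {exc}"
        rows.append(
            {
                "draw": draw,
                "k": k,
                "lambda": lam,
                "upsilon": upsilon,
                "fold_llpds": scores,
                "mean_llpd": mean,
                "status": status,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("mean_llpd", ascending=False, na_position="last").reset_index(
        drop=True
    )


def multi_init(
    data: ModelData,
    hyper: Hyperparameters,
    n_inits: int,
    fit_opts: FitOptions = FitOptions(),
    seed: int = 0,
    holdout_fraction: float = 0.2,
    m_samples: int = 25,
):
    """Refit from ``n_inits`` random starts; report LLPD mean, spread and seeds.

    All starts share one fixed random-cell holdout (derived from ``seed``) so
    the spread reflects optimization noise only. Returns a dict with
    ``llpds``, ``mean``, ``sd`` and the distinct ``seeds`` used.
    """
    if n_inits < 1:
        raise ParameterError("n_inits must be >= 1")
    rng = np.random.default_rng(seed)
    held = np.zeros(data.n * data.q, dtype=bool)
    held[rng.permutation(data.n * data.q)[: max(1, int(holdout_fraction * data.n * data.q))]] = True
    held = held.reshape(data.n, data.q)
    train = replace(data, obs_mask=data.obs_mask & ~held)
    init_seeds = (np.random.SeedSequence(seed).generate_state(2 * n_inits) % (2**31)).tolist()
    llpds = []
    for i in range(n_inits):
        opts = replace(fit_opts, seed=int(init_seeds[2 * i]))
        result = fit(train, hyper, opts)
        samples = sample_posterior(result, m_samples, int(init_seeds[2 * i + 1]))
        llpds.append(llpd(samples, train, held & data.obs_mask, ablation=opts.ablation))
    return {
        "llpds": llpds,
        "mean": float(np.mean(llpds)),
        "sd": float(np.std(llpds)),
        "seeds": [int(s) for s in init_seeds[::2]],
    }


def ablate(
    data: ModelData,
    hyper: Hyperparameters,
    component: str,
    folds: int = 5,
    seed: int = 0,
    fit_opts: FitOptions = FitOptions(),
    m_samples: int = 25,
) -> AblationReport:
    """Cross-validated LLPD with one predictor component removed.

    The component's predictor term and its parameter block are dropped from
    the model; the same fold partition scores the full model alongside.
    """
    if component not in COMPONENTS:
        raise ParameterError(f"unknown component {component!r}; choose from {COMPONENTS}")
    full_scores, full_mean = crossval_llpd(data, hyper, folds, seed, fit_opts, m_samples=m_samples)
    scores, mean = crossval_llpd(
        data, hyper, folds, seed, fit_opts, ablation=frozenset({component}), m_samples=m_samples
    )
    return AblationReport(
        component=component,
        mean_llpd=mean,
        fold_llpds=scores,
        full_mean_llpd=full_mean,
        full_fold_llpds=full_scores,
    )
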