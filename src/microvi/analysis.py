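"""Downstream read-outs: latent modules, symmetrized interactions, effect summaries.

After fitting, the k x q latent matrix ``beta`` embeds every taxon; cosine
distances between columns (invariant to the latent scale indeterminacy) feed a
k-nearest-neighbor graph whose greedy-modularity communities are the latent
"modules". The asymmetric item-item couplings ``rho' beta`` are symmetrized
into an interaction matrix ``I = (rho_i'beta_j + rho_j'beta_i)/2`` whose sign
significance is assessed with equal-tailed posterior credible intervals.
Effect summaries aggregate the direct covariate effects (``gamma``) and the
context effects (``delta beta`` for depth, ``alpha beta`` for province,
``vartheta beta`` for season) over taxon groups such as ecologically relevant
classes (ERCs) or the latent modules themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import ModelParameters
from .vi import PosteriorSamples

__all__ = [
    "LatentEmbedding",
    "InteractionMatrix",
    "EffectSummary",
    "cosine_distances",
    "knn_edges",
    "embed_and_cluster",
    "interaction_matrix",
    "credible_masks",
    "aggregate_interactions",
    "aggregate_effects",
    "effect_summaries",
]


@dataclass
class LatentEmbedding:
    """Cosine-distance kNN graph of the latent taxon vectors and its modules."""

    beta_hat: np.ndarray
    distance: np.ndarray
    edges: list
    k_nn: int
    module_labels: np.ndarray
    modularity_score: float

    @property
    def n_modules(self) -> int:
        return int(self.module_labels.max()) + 1

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.module_labels)


@dataclass
class InteractionMatrix:
    """Symmetrized taxon-taxon interactions with credible-sign masks."""

    I: np.ndarray
    sig_pos: np.ndarray
    sig_neg: np.ndarray
    credible_level: float


@dataclass
class EffectSummary:
    """Group-averaged effect sizes per model component."""

    environment: pd.DataFrame  # covariates x groups, from gamma
    depth: pd.DataFrame        # depth levels x groups, from delta beta
    province: pd.DataFrame     # province levels x groups, from alpha beta
    season: pd.DataFrame       # season levels x groups, from vartheta beta


def cosine_distances(beta: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances ``1 - cos`` between the columns of ``beta``.

    Symmetric with zero diagonal, entries in [0, 2]. An all-zero column has no
    direction; its distance to every other taxon is defined as 1 (a warning is
    emitted).
    """
    beta = np.asarray(beta, dtype=float)
    norms = np.linalg.norm(beta, axis=0)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero latent columns; distances set to 1")
    safe = np.where(zero, 1.0, norms)
    unit = beta / safe
    dist = 1.0 - unit.T @ unit
    dist[zero, :] = 1.0
    dist[:, zero] = 1.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def knn_edges(distance: np.ndarray, k_nn: int) -> list:
    """Union-symmetrized k-nearest-neighbor edge list.

    Each taxon selects its ``k_nn`` nearest others (distance ties broken by
    ascending taxon index); an edge exists if either endpoint selects the
    other.
    """
    q = distance.shape[0]
    if not 1 <= k_nn < q:
        raise ParameterError("k_nn must satisfy 1 <= k_nn < number of taxa")
    edges = set()
    for i in range(q):
        row = distance[i].copy()
        row[i] = np.inf
        order = np.argsort(row, kind="stable")[:k_nn]
        for j in order:
            edges.add((min(i, int(j)), max(i, int(j))))
    return sorted(edges)


def embed_and_cluster(beta_hat: np.ndarray, k_nn: int = 10) -> LatentEmbedding:
    """Cluster taxa by greedy modularity maximization on the latent kNN graph.

    Communities are found by Clauset-Newman-Moore greedy agglomeration on the
    unweighted union-kNN graph; labels are 0-based, ordered by decreasing
    module size (smallest member index breaking ties), so the procedure is
    deterministic for a fixed input.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    dist = cosine_distances(beta_hat)
    edges = knn_edges(dist, k_nn)
    G = nx.Graph()
    G.add_nodes_from(range(dist.shape[0]))
    G.add_edges_from(edges)
    communities = [set(c) for c in nx.community.greedy_modularity_communities(G)]
    communities.sort(key=lambda c: (-len(c), min(c)))
    labels = np.empty(dist.shape[0], dtype=np.int64)
    for lab, comm in enumerate(communities):
        for node in comm:
            labels[node] = lab
    score = nx.community.modularity(G, communities)
    return LatentEmbedding(
        beta_hat=beta_hat,
        distance=dist,
        edges=edges,
        k_nn=k_nn,
        module_labels=labels,
        modularity_score=float(score),
    )


def credible_masks(draws: np.ndarray, credible_level: float):
    """Equal-tailed credible-interval sign masks for draws along axis 0.

    ``sig_pos`` where the interval lies strictly above zero, ``sig_neg`` where
    strictly below; the two masks are mutually exclusive by construction.
    """
    if not 0 < credible_level < 1:
        raise ParameterError("credible_level must lie in (0, 1)")
    alpha = (1.0 - credible_level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    return lo > 0, hi < 0


def interaction_matrix(samples: PosteriorSamples, credible_level: float = 0.95) -> InteractionMatrix:
    """Symmetrized interaction matrix with posterior sign significance.

    The point estimate uses the posterior-mean ``rho`` and ``beta``; the sign
    masks use the per-draw symmetrized matrices.
    """
    if samples.m < 1:
        raise ParameterError("need at least one posterior draw")
    mean = samples.mean()
    M = mean.rho.T @ mean.beta
    I = (M + M.T) / 2.0
    draws = np.stack(
        [(d.rho.T @ d.beta + (d.rho.T @ d.beta).T) / 2.0 for d in samples.draws]
    )
    sig_pos, sig_neg = credible_masks(draws, credible_level)
    np.fill_diagonal(sig_pos, False)
    np.fill_diagonal(sig_neg, False)
    return InteractionMatrix(I=I, sig_pos=sig_pos, sig_neg=sig_neg, credible_level=credible_level)


def _group_index(group_labels, q: int):
    labels = list(group_labels) if group_labels is not None else []
    if len(labels) < q:
        missing = q - len(labels)
        warnings.warn(f"{missing} unlabeled taxa assigned to 'Unclassified'")
        labels = labels + ["Unclassified"] * missing
    labels = ["Unclassified" if lab is None else str(lab) for lab in labels]
    groups = sorted(set(labels))
    members = {g: [j for j, lab in enumerate(labels) if lab == g] for g in groups}
    return groups, members


def aggregate_interactions(
    interactions: InteractionMatrix, group_labels
) -> dict:
    """Count significant positive/negative taxon pairs per group pair.

    Returns square DataFrames ``pos`` and ``neg`` of unordered-pair counts and
    a ``combined`` table whose lower triangle holds positive counts, upper
    triangle negative counts, and diagonal the maximum of the two within-group
    counts.
    """
    q = interactions.I.shape[0]
    groups, members = _group_index(group_labels, q)
    g = len(groups)
    pos = np.zeros((g, g), dtype=np.int64)
    neg = np.zeros((g, g), dtype=np.int64)
    for mats, counts in ((interactions.sig_pos, pos), (interactions.sig_neg, neg)):
        ii, jj = np.where(np.triu(mats, k=1))
        gidx = {gr: a for a, gr in enumerate(groups)}
        lab_of = np.empty(q, dtype=np.int64)
        for gr, mem in members.items():
            lab_of[mem] = gidx[gr]
        for i, j in zip(ii, jj):
            a, b = sorted((lab_of[i], lab_of[j]))
            counts[a, b] += 1
            if a != b:
                counts[b, a] += 1
    combined = np.where(np.tri(g, k=-1, dtype=bool), pos, neg)
    np.fill_diagonal(combined, np.maximum(np.diag(pos), np.diag(neg)))
    idx = pd.Index(groups)
    return {
        "pos": pd.DataFrame(pos, index=idx, columns=idx),
        "neg": pd.DataFrame(neg, index=idx, columns=idx),
        "combined": pd.DataFrame(combined, index=idx, columns=idx),
    }


def aggregate_effects(effect: np.ndarray, group_labels, feature_names=None) -> pd.DataFrame:
    """Mean effect size per group for a features x taxa effect matrix.

    The aggregation weights are uniform within each group (they sum to one).
    """
    effect = np.atleast_2d(np.asarray(effect, dtype=float))
    q = effect.shape[1]
    groups, members = _group_index(group_labels, q)
    out = np.column_stack([effect[:, members[g]].mean(axis=1) for g in groups])
    index = feature_names if feature_names is not None else range(effect.shape[0])
    return pd.DataFrame(out, index=index, columns=groups)


def effect_summaries(
    params: ModelParameters,
    group_labels,
    covariate_names=None,
    depth_levels=None,
    province_levels=None,
    season_levels=None,
) -> EffectSummary:
    """Group-level effect summaries for every coupling component.

    Environment effects are the direct coefficients ``gamma``; depth, province
    and season effects are the latent products ``delta beta``, ``alpha beta``
    and ``vartheta beta``.
    """
    return EffectSummary(
        environment=aggregate_effects(params.gamma, group_labels, covariate_names),
        depth=aggregate_effects(params.delta @ params.beta, group_labels, depth_levels),
        province=aggregate_effects(params.alpha @ params.beta, group_labels, province_levels),
        season=aggregate_effects(params.vartheta @ params.beta, group_labels, season_levels),
    )
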