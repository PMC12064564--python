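"""Reading, validation, filtering and normalization of microbiome survey tables.

This module turns plain-text (TSV) count, covariate and sample-metadata tables
into the aligned, validated arrays the model consumes:

* an :class:`AbundanceTable` of non-negative integer counts (samples x taxa),
* a mean-centered :class:`CovariateTable` of continuous covariates,
* a :class:`ContextDesign` of one-hot spatial/temporal indicators
  (biogeographic province, depth layer, season), and
* an :class:`OffsetVector` of per-sample compositional offsets ``t_i``
  (a zero-aware geometric-mean library-size surrogate) whose logarithm enters
  the linear predictor as a fixed offset.

Two standard survey-preprocessing steps are provided: restriction to the union
of each sample's top contributors (taxa that cumulatively make up a fraction of
the library), and common-sum scaling to the smallest library size.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "ContextLevels",
    "AbundanceTable",
    "CovariateTable",
    "ContextDesign",
    "OffsetVector",
    "read_tables",
    "filter_top_contributors",
    "common_sum_scale",
    "compute_offsets",
    "encode_context",
    "season_from_date",
    "write_counts",
    "write_covariates",
    "write_metadata",
]


@dataclass(frozen=True)
class ContextLevels:
    """Declared category levels (and their fixed column order) for the context design.

    Defaults are the marine survey configuration: four Longhurst biomes, four
    depth layers (surface, deep chlorophyll maximum, mixed layer, mesopelagic)
    and four calendar-quarter seasons. Arbitrary level sets are allowed.
    """

    provinces: tuple[str, ...] = ("Polar", "Westerlies", "Trades", "Coastal")
    depths: tuple[str, ...] = ("SRF", "DCM", "MIX", "MES")
    seasons: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class AbundanceTable:
    """Samples x taxa count matrix with identifiers and optional taxon class labels.

    Invariants enforced on construction: counts are non-negative integers,
    every sample (row) has at least one nonzero entry, and identifiers are
    unique. ``presence_counts`` is the number of taxa present per sample.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    erc_labels: list[str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D samples x taxa matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts % 1 != 0):
                raise FormatError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("counts has negative entries")
        if np.any(counts.sum(axis=1) == 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(counts.sum(axis=1) == 0)]
            raise ValidationError(f"samples with all-zero counts: {bad}")
        n, q = counts.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != q:
            raise ValidationError("identifier lengths do not match counts shape")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids are not unique")
        if len(set(self.taxon_ids)) != q:
            raise ValidationError("taxon_ids are not unique")
        if self.erc_labels is not None and len(self.erc_labels) != q:
            raise ValidationError("erc_labels length does not match number of taxa")
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def presence(self) -> np.ndarray:
        """Boolean mask of nonzero counts."""
        return self.counts > 0

    @property
    def presence_counts(self) -> np.ndarray:
        """Number of taxa present in each sample (a_i)."""
        return (self.counts > 0).sum(axis=1)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class CovariateTable:
    """Samples x covariates real matrix; columns are mean-centered when ``centered``."""

    X: np.ndarray
    covariate_names: list[str]
    centered: bool = False

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("covariates must form a 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise ValidationError("covariates contain non-finite values")
        if len(self.covariate_names) != X.shape[1]:
            raise ValidationError("covariate_names length mismatch")
        self.X = X

    def center(self) -> "CovariateTable":
        """Return a copy with each column mean-centered."""
        return replace(self, X=self.X - self.X.mean(axis=0, keepdims=True), centered=True)


@dataclass
class ContextDesign:
    """One-hot sample design matrices for province (R), depth (D) and season (S)."""

    R: np.ndarray
    D: np.ndarray
    S: np.ndarray
    province_levels: tuple[str, ...]
    depth_levels: tuple[str, ...]
    season_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, M in (("R", self.R), ("D", self.D), ("S", self.S)):
            M = np.asarray(M)
            if M.ndim != 2 or not np.all(np.isin(M, (0, 1))):
                raise ValidationError(f"{name} must be a binary matrix")
            if not np.all(M.sum(axis=1) == 1):
                raise ValidationError(f"every row of {name} must sum to exactly 1")
        self.R = np.asarray(self.R, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int64)
        self.S = np.asarray(self.S, dtype=np.int64)


@dataclass
class OffsetVector:
    """Per-sample compositional offsets ``t_i`` and their logarithms."""

    t: np.ndarray
    log_t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValidationError("offsets must be strictly positive and finite")
        self.t = t
        if self.log_t is None:
            self.log_t = np.log(t)
        else:
            self.log_t = np.asarray(self.log_t, dtype=float)


def season_from_date(date_str: str) -> str:
    """Map an ISO-8601 date to its calendar-quarter season Q1..Q4.

    Q1 covers January-March, Q2 April-June, Q3 July-September and Q4
    October-December.
    """
    try:
        d = datetime.date.fromisoformat(str(date_str))
    except ValueError as exc:
        raise FormatError(f"cannot parse ISO-8601 date: {date_str!r}") from exc
    return f"Q{(d.month - 1) // 3 + 1}"


def _one_hot(values: pd.Series, levels: tuple[str, ...], column: str) -> np.ndarray:
    index = {lev: j for j, lev in enumerate(levels)}
    out = np.zeros((len(values), len(levels)), dtype=np.int64)
    for i, v in enumerate(values):
        if v not in index:
            raise ValidationError(
                f"unknown {column} level {v!r}; declared levels are {list(levels)}"
            )
        out[i, index[v]] = 1
    return out


def encode_context(metadata: pd.DataFrame, levels: ContextLevels | None = None) -> ContextDesign:
    """One-hot encode province / depth / season metadata into a :class:`ContextDesign`.

    ``metadata`` must carry ``province`` and ``depth_layer`` columns and either
    a ``season`` column (values in the declared season levels) or a ``date``
    column of ISO-8601 dates from which the calendar-quarter season is derived.
    """
    levels = levels or ContextLevels()
    for col in ("province", "depth_layer"):
        if col not in metadata.columns:
            raise FormatError(f"metadata is missing required column {col!r}")
    if "season" in metadata.columns:
        seasons = metadata["season"]
    elif "date" in metadata.columns:
        seasons = metadata["date"].map(season_from_date)
    else:
        raise FormatError("metadata needs a 'season' or 'date' column")
    return ContextDesign(
        R=_one_hot(metadata["province"], levels.provinces, "province"),
        D=_one_hot(metadata["depth_layer"], levels.depths, "depth_layer"),
        S=_one_hot(seasons, levels.seasons, "season"),
        province_levels=levels.provinces,
        depth_levels=levels.depths,
        season_levels=levels.seasons,
    )


def read_tables(
    counts_path,
    covariates_path,
    metadata_path,
    erc_path=None,
    levels: ContextLevels | None = None,
    center_covariates: bool = True,
):
    """Read and align the count, covariate and metadata TSVs.

    All three tables must cover exactly the same sample set; rows are reordered
    to the count table's sample order, so external row order never matters.
    Taxa missing from the optional taxon->class (ERC) map are labeled
    ``"Unclassified"``.

    Returns ``(AbundanceTable, CovariateTable, ContextDesign)``.
    """
    counts_df = pd.read_csv(counts_path, sep="\t", index_col=0)
    cov_df = pd.read_csv(covariates_path, sep="\t", index_col=0)
    meta_df = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)

    vals = counts_df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.all(np.isfinite(vals.astype(float))) or np.any(vals.astype(float) % 1 != 0):
            raise FormatError(f"non-integer counts in {counts_path}")

    sample_ids = [str(s) for s in counts_df.index]
    for name, other in (("covariates", cov_df), ("metadata", meta_df)):
        other_ids = {str(s) for s in other.index}
        missing = sorted(set(sample_ids) - other_ids)
        extra = sorted(other_ids - set(sample_ids))
        if missing or extra:
            raise AlignmentError(
                f"sample sets differ between counts and {name}: "
                f"missing from {name}: {missing}; only in {name}: {extra}"
            )
    cov_df = cov_df.loc[sample_ids]
    meta_df = meta_df.loc[sample_ids]

    taxon_ids = [str(t) for t in counts_df.columns]
    erc_labels = None
    if erc_path is not None:
        erc_df = pd.read_csv(erc_path, sep="\t", index_col=0, dtype=str)
        mapping = erc_df.iloc[:, 0].to_dict()
        erc_labels = [mapping.get(t, "Unclassified") for t in taxon_ids]

    table = AbundanceTable(
        counts=counts_df.to_numpy(),
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        erc_labels=erc_labels,
    )
    covariates = CovariateTable(
        X=cov_df.to_numpy(dtype=float),
        covariate_names=[str(c) for c in cov_df.columns],
    )
    if center_covariates:
        covariates = covariates.center()
    design = encode_context(meta_df, levels=levels)
    return table, covariates, design


def filter_top_contributors(table: AbundanceTable, fraction: float = 0.40) -> AbundanceTable:
    """Restrict the table to the union of each sample's top contributors.

    For every sample, taxa are ranked by descending count (ties broken by
    ascending taxon index) and the shortest prefix whose cumulative count first
    reaches ``fraction`` of the library size is retained. The returned table
    keeps the surviving taxa in their original column order.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction}")
    counts = table.counts
    keep = np.zeros(table.n_taxa, dtype=bool)
    for row in counts:
        order = np.argsort(-row, kind="stable")
        cum = np.cumsum(row[order])
        target = fraction * row.sum()
        stop = int(np.searchsorted(cum, target, side="left"))
        keep[order[: stop + 1]] = True
    idx = np.flatnonzero(keep)
    return AbundanceTable(
        counts=counts[:, idx],
        sample_ids=list(table.sample_ids),
        taxon_ids=[table.taxon_ids[j] for j in idx],
        erc_labels=None if table.erc_labels is None else [table.erc_labels[j] for j in idx],
    )


def common_sum_scale(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample to the smallest library size (common-sum scaling).

    Each row is multiplied by ``min library size / own library size`` and
    rounded half-to-even back to integers, since the count likelihood consumes
    integer data.
    """
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValidationError("common_sum_scale requires positive row totals")
    factor = totals.min() / totals
    scaled = np.rint(table.counts * factor[:, None]).astype(np.int64)
    return replace(table, counts=scaled)


def compute_offsets(table: AbundanceTable, pseudo: float = 1.0, estimator=None) -> OffsetVector:
    """Per-sample zero-aware geometric-mean offsets ``t_i``.

    The default estimator is the pseudo-count geometric mean
    ``t_i = exp( mean_j log(w_ij + pseudo) )`` with ``pseudo`` defaulting to 1,
    a simple consistent surrogate for the geometric mean in the presence of
    excess zeros. ``pseudo = 0`` is only admissible when the table has no
    zeros (then ``t_i`` is the exact geometric mean).

    A different strategy can be plugged in as ``estimator``, a callable mapping
    the integer count matrix to a positive vector of length ``n``; callers are
    unaffected by the choice.

    ``table`` may be an :class:`AbundanceTable` or a raw count matrix.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else np.asarray(table)
    if estimator is not None:
        t = np.asarray(estimator(counts), dtype=float)
        return OffsetVector(t=t)
    if pseudo < 0 or (pseudo == 0 and np.any(counts == 0)):
        raise ParameterError(
            "pseudo must be positive (zero is allowed only for tables without zeros)"
        )
    log_t = np.log(counts + float(pseudo)).mean(axis=1)
    return OffsetVector(t=np.exp(log_t), log_t=log_t)


def write_counts(table: AbundanceTable, path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def write_covariates(cov: CovariateTable, sample_ids: list[str], path) -> None:
    pd.DataFrame(cov.X, index=sample_ids, columns=cov.covariate_names).rename_axis(
        "sample_id"
    ).to_csv(path, sep="\t")


def write_metadata(design: ContextDesign, sample_ids: list[str], path) -> None:
    prov = [design.province_levels[j] for j in np.argmax(design.R, axis=1)]
    depth = [design.depth_levels[j] for j in np.argmax(design.D, axis=1)]
    seas = [design.season_levels[j] for j in np.argmax(design.S, axis=1)]
    pd.DataFrame(
        {"province": prov, "depth_layer": depth, "season": seas}, index=sample_ids
    ).rename_axis("sample_id").to_csv(path, sep="\t")
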