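"""Batch correction, completeness partitioning and local least-squares imputation.

All modeling here happens on log2 intensities.  Completeness and imputation
are assessed on the replicate-collapsed (per-sample median) matrix: a
protein is *complete* when it has a value in every biological sample.
Missing cells of incomplete proteins are estimated by regressing the
protein's observed cells on the representative profiles of ``k`` clusters of
complete proteins (local least squares), never touching observed cells.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .containers import AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)


def log_transform(matrix: AbundanceMatrix, base: float = 2.0) -> AbundanceMatrix:
    """Raw -> log2 intensities; missing cells preserved."""
    if matrix.scale == "log2":
        raise ValidationError("matrix is already on the log scale")
    arr = matrix.values.to_numpy(dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValidationError("non-positive intensity cannot be log-transformed")
    vals = np.log(matrix.values) / np.log(base)
    return AbundanceMatrix(vals, matrix.runs.copy(), scale="log2")


def unlog_transform(matrix: AbundanceMatrix, base: float = 2.0, scale: str = "raw") -> AbundanceMatrix:
    """Inverse of :func:`log_transform`."""
    if matrix.scale != "log2":
        raise ValidationError("matrix is not on the log scale")
    return AbundanceMatrix(np.power(base, matrix.values), matrix.runs.copy(), scale=scale)


class BatchMeanCenterer(BaseEstimator):
    """Per-protein batch mean-centering on the log scale.

    For every protein, each batch's mean (over non-missing cells) is shifted
    onto the protein's grand mean, removing additive (multiplicative on the
    raw scale) batch offsets while preserving the grand mean.  Missing cells
    are untouched.  Idempotent.
    """

    def fit(self, matrix: AbundanceMatrix, y=None):
        if matrix.scale != "log2":
            raise ValidationError("batch mean-centering expects log2 intensities")
        batches = matrix.runs["batch_id"]
        self.grand_mean_ = matrix.values.mean(axis=1)
        self.batch_means_ = matrix.values.T.groupby(batches).mean().T
        empty = self.batch_means_.isna()
        if empty.to_numpy().any():
            n = int(empty.to_numpy().sum())
            logger.warning(
                "%d (protein, batch) cells have no observations; left missing", n
            )
        return self

    def transform(self, matrix: AbundanceMatrix) -> AbundanceMatrix:
        batches = matrix.runs["batch_id"]
        offset = self.batch_means_.sub(self.grand_mean_, axis=0)
        per_run_offset = offset.loc[:, batches.to_numpy()]
        per_run_offset.columns = matrix.values.columns
        out = matrix.values - per_run_offset
        return AbundanceMatrix(out, matrix.runs.copy(), scale=matrix.scale)

    def fit_transform(self, matrix: AbundanceMatrix, y=None) -> AbundanceMatrix:
        return self.fit(matrix).transform(matrix)


def batch_mean_center(matrix: AbundanceMatrix) -> AbundanceMatrix:
    return BatchMeanCenterer().fit_transform(matrix)


@dataclasses.dataclass
class CompletenessPartition:
    """Disjoint complete / incomplete / excluded protein id sets."""

    complete_ids: list
    incomplete_ids: list
    excluded_ids: list

    def __post_init__(self):
        sets = [set(self.complete_ids), set(self.incomplete_ids), set(self.excluded_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValidationError("partition sets are not disjoint")

    @property
    def all_ids(self) -> list:
        return list(self.complete_ids) + list(self.incomplete_ids) + list(self.excluded_ids)


def partition_by_completeness(matrix: AbundanceMatrix) -> CompletenessPartition:
    """Classify proteins by missingness of the replicate-collapsed matrix."""
    collapsed = matrix.collapse_replicates()
    n_missing = collapsed.values.isna().sum(axis=1)
    complete = n_missing.index[n_missing == 0].tolist()
    incomplete = n_missing.index[n_missing > 0].tolist()
    return CompletenessPartition(complete, incomplete, [])


@dataclasses.dataclass
class ProteinClustering:
    """k groups of complete proteins and their representative profiles."""

    k: int
    members: dict  # cluster id -> list of protein ids
    representatives: pd.DataFrame  # cluster id x runs (member-mean profile)


def cluster_complete_proteins(
    matrix: AbundanceMatrix, complete_ids, k: int = 15
) -> ProteinClustering:
    """Average-linkage agglomerative clustering on 1 - Pearson r.

    Proteins with a constant profile (correlation undefined) are assigned to
    the nearest cluster by Euclidean distance to the representatives and
    logged.
    """
    complete_ids = list(complete_ids)
    if len(complete_ids) < k:
        raise ValueError(f"need >= k={k} complete proteins, got {len(complete_ids)}")
    profiles = matrix.collapse_replicates().values.loc[complete_ids]
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = sd <= 1e-12
    usable = np.where(~constant)[0]
    if len(usable) < k:
        raise ValueError("fewer non-constant complete proteins than clusters")

    corr = np.corrcoef(arr[usable])
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")

    members: dict[int, list] = {c: [] for c in range(1, int(flat.max()) + 1)}
    for pos, c in zip(usable, flat):
        members[int(c)].append(complete_ids[pos])
    reps = pd.DataFrame(
        {c: profiles.loc[ids].mean(axis=0) for c, ids in members.items()}
    ).T
    if constant.any():
        const_ids = [complete_ids[i] for i in np.where(constant)[0]]
        logger.warning("constant profile(s) %s assigned by Euclidean fallback", const_ids)
        for pid in const_ids:
            d = ((reps - profiles.loc[pid]) ** 2).sum(axis=1)
            nearest = int(d.idxmin())
            members[nearest].append(pid)
        reps = pd.DataFrame(
            {c: profiles.loc[ids].mean(axis=0) for c, ids in members.items()}
        ).T
    return ProteinClustering(k=k, members=members, representatives=reps)


class LLSImputer(BaseEstimator):
    """Local least-squares imputation against cluster representative profiles.

    fit: partitions proteins by completeness and clusters the complete ones.
    transform: for each incomplete protein, ordinary least squares of its
    observed (per-sample) cells on the ``k`` representative profiles plus an
    intercept; missing cells are replaced by fitted values.  Observed cells
    are never altered.  Proteins with fewer than ``k + 2`` observed cells are
    excluded (left missing, recorded in ``partition_.excluded_ids``).
    Rank-deficient designs fall back to ridge with a small fixed penalty.
    """

    def __init__(self, k: int = 15, ridge: float = 1e-6):
        self.k = k
        self.ridge = ridge

    def fit(self, matrix: AbundanceMatrix, y=None):
        self.partition_ = partition_by_completeness(matrix)
        self.clustering_ = cluster_complete_proteins(
            matrix, self.partition_.complete_ids, k=self.k
        )
        return self

    def transform(self, matrix: AbundanceMatrix) -> AbundanceMatrix:
        collapsed = matrix.collapse_replicates()
        vals = collapsed.values.copy()
        reps = self.clustering_.representatives.loc[:, vals.columns].to_numpy(dtype=float)
        design_full = np.column_stack([np.ones(vals.shape[1]), reps.T])
        excluded = []
        for pid in self.partition_.incomplete_ids:
            y = vals.loc[pid].to_numpy(dtype=float)
            obs = ~np.isnan(y)
            if obs.sum() < design_full.shape[1] + 1:
                excluded.append(pid)
                logger.warning("protein %s: too few observed cells to impute", pid)
                continue
            X = design_full[obs]
            coef, _, rank, _ = np.linalg.lstsq(X, y[obs], rcond=None)
            if rank < X.shape[1]:
                logger.warning("protein %s: rank-deficient design, ridge fallback", pid)
                A = X.T @ X + self.ridge * np.eye(X.shape[1])
                coef = np.linalg.solve(A, X.T @ y[obs])
            y[~obs] = design_full[~obs] @ coef
            vals.loc[pid] = y
        self.partition_ = CompletenessPartition(
            self.partition_.complete_ids,
            [p for p in self.partition_.incomplete_ids if p not in excluded],
            list(self.partition_.excluded_ids) + excluded,
        )
        return AbundanceMatrix(vals, collapsed.runs.copy(), scale=matrix.scale)

    def fit_transform(self, matrix: AbundanceMatrix, y=None) -> AbundanceMatrix:
        return self.fit(matrix).transform(matrix)


def impute_lls(
    matrix: AbundanceMatrix,
    partition: CompletenessPartition | None = None,
    clustering: ProteinClustering | None = None,
    k: int = 15,
):
    """Functional wrapper over :class:`LLSImputer`.

    Returns ``(imputed_sample_matrix, partition)`` where the partition's
    excluded set records proteins with too few observations.
    """
    imp = LLSImputer(k=k)
    if partition is not None and clustering is not None:
        imp.partition_ = partition
        imp.clustering_ = clustering
    else:
        imp.fit(matrix)
    out = imp.transform(matrix)
    return out, imp.partition_
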