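"""Endogenous normalizer selection and normalization scaling factors (NSF).

Stability of candidate reference proteins is scored with a model-based
(NormFinder-type) measure from the two-way gene x sample model fitted per
response group: gene-specific intra-group variances (method-of-moments with
a k/(k-2) small-panel correction) are combined with empirical-Bayes-shrunken
inter-group biases; lower stability = more stable.  Normalizers are then the
``n`` most stable candidates whose group difference is non-significant
(mixed-model p > 0.05) and which are not on a prior-disease-association
exclusion list.

The per-sample NSF is a robust summary (median by default, geometric mean as
an option) of the six ratios N_{i,s} / N-hat_i between each normalizer's raw
abundance in the sample and its across-sample reference value; all raw
intensities of the sample are divided by it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import AbundanceMatrix, ValidationError


def normfinder_stability(
    values: pd.DataFrame, groups: pd.Series, full: bool = False
):
    """Model-based stability value per protein (lower = more stable).

    Parameters
    ----------
    values : DataFrame
        Proteins x samples, log scale, no missing cells among candidates.
    groups : Series
        sample id -> group label; >= 2 groups with >= 2 samples each.

    Model per group g: ``y_igj = gene_ig + sample_gj + eps_igj`` with
    gene-specific noise variance sigma^2_ig.  Method-of-moments residual
    variances use the correction for sample effects estimated from k genes:
    ``sigma2_ig = (s2_ig - mean_i(s2)/(k-1)) * k/(k-2)`` (clipped at 0).
    Inter-group bias ``d_ig`` (gene's group-mean deviation, centred across
    groups) is shrunk towards zero with the across-gene bias variance;
    stability = mean over groups of |shrunk d| + posterior SD.
    """
    if values.isna().to_numpy().any():
        bad = values.index[values.isna().any(axis=1)][:5].tolist()
        raise ValidationError(f"candidate(s) with missing values: {bad}")
    groups = groups.loc[values.columns]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    k = values.shape[0]
    if k < 3:
        raise ValidationError("need >= 3 candidate proteins")

    d = pd.DataFrame(index=values.index, columns=levels, dtype=float)
    var_d = pd.DataFrame(index=values.index, columns=levels, dtype=float)
    for g in levels:
        z = values.loc[:, groups.index[groups == g]].to_numpy(dtype=float)
        n_g = z.shape[1]
        if n_g < 2:
            raise ValidationError(f"group {g!r} has < 2 samples")
        gene_mean = z.mean(axis=1, keepdims=True)
        sample_mean = z.mean(axis=0, keepdims=True)
        grand = z.mean()
        resid = z - gene_mean - sample_mean + grand
        s2 = (resid ** 2).sum(axis=1) / (n_g - 1)
        sigma2 = np.clip((s2 - s2.mean() / (k - 1)) * k / (k - 2), 0.0, None)
        d[g] = gene_mean[:, 0] - grand
        var_d[g] = sigma2 / n_g
    # centre the bias across groups: only differential deviation counts
    d = d.sub(d.mean(axis=1), axis=0)
    gamma2 = max(float((d.to_numpy() ** 2).mean() - var_d.to_numpy().mean()), 0.0)
    denom = gamma2 + var_d
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma2 / denom, 0.0)
    d_star = d * shrink
    # uncertainty term: sampling SD of the bias estimate.  (The shrunk
    # posterior SD collapses to zero for every gene when the across-gene
    # bias variance estimate hits zero, which would leave the measure
    # unable to rank by intra-group variance.)
    stability = pd.Series(
        (np.abs(d_star) + np.sqrt(var_d)).mean(axis=1),
        index=values.index,
        name="stability",
    )
    if full:
        return stability, {"d": d, "d_star": d_star, "var_d": var_d, "gamma2": gamma2}
    return stability


def select_normalizers(
    stability: pd.Series,
    group_p: pd.Series,
    exclusion_list=(),
    n: int = 6,
    p_threshold: float = 0.05,
) -> list:
    """Three-criterion normalizer selection.

    Keep candidates with group-difference p > 0.05 that are not on the
    exclusion list; rank by stability ascending (ties broken by protein id);
    take the top ``n``.
    """
    candidates = stability.index.intersection(group_p.index)
    keep = [
        pid for pid in candidates
        if group_p[pid] > p_threshold and pid not in set(exclusion_list)
    ]
    if len(keep) < n:
        raise ValueError(f"only {len(keep)} candidates survive the filters, need {n}")
    ranked = sorted(keep, key=lambda pid: (stability[pid], str(pid)))
    return ranked[:n]


def _aggregate(arr: np.ndarray, how: str, axis: int):
    if how == "median":
        return np.median(arr, axis=axis)
    if how == "geomean":
        return np.exp(np.mean(np.log(arr), axis=axis))
    raise ValueError(f"unknown aggregate {how!r}")


def compute_nsf(
    matrix: AbundanceMatrix,
    selected_ids,
    aggregate: str = "median",
    ratio_summary: str = "median",
) -> pd.Series:
    """Per-sample normalization scaling factor.

    ``ratio_{i,s} = N_{i,s} / N-hat_i`` with ``N-hat_i`` the across-sample
    ``aggregate`` (median by default) of normalizer ``i``'s raw abundance;
    ``NSF_s`` = ``ratio_summary`` (median by default) of the ratios over the
    selected normalizers.  Equivariant: scaling sample s by c scales NSF_s
    by exactly c.
    """
    if matrix.scale == "log2":
        raise ValidationError("NSF is defined on raw-scale abundances")
    collapsed = matrix.collapse_replicates()
    norm = collapsed.values.loc[list(selected_ids)].to_numpy(dtype=float)
    if np.isnan(norm).any():
        raise ValidationError("normalizer abundances must be observed in every sample")
    if np.any(norm <= 0):
        raise ValidationError("non-positive abundance among normalizers")
    reference = _aggregate(norm, aggregate, axis=1)  # N-hat_i
    ratios = norm / reference[:, None]
    nsf = _aggregate(ratios, ratio_summary, axis=0)
    return pd.Series(nsf, index=collapsed.values.columns, name="nsf")


def apply_nsf(matrix: AbundanceMatrix, nsf: pd.Series) -> AbundanceMatrix:
    """Divide every raw intensity of a sample by that sample's NSF."""
    if matrix.scale == "log2":
        raise ValidationError("NSF applies to raw-scale abundances")
    sample_of_run = matrix.runs["sample_id"]
    missing = set(sample_of_run) - set(nsf.index)
    if missing:
        raise ValidationError(f"no NSF for sample(s): {sorted(missing)[:5]}")
    factors = nsf.loc[sample_of_run.to_numpy()].to_numpy(dtype=float)
    if np.any(factors <= 0):
        raise ValidationError("NSF must be strictly positive")
    out = matrix.values / factors[None, :]
    return AbundanceMatrix(out, matrix.runs.copy(), scale="normalized")


@dataclasses.dataclass
class NormalizerSelection:
    """Stability table, selected normalizers and per-sample NSF."""

    stability: pd.Series
    group_p: pd.Series
    exclusion_list: list
    selected_ids: list
    nsf: pd.Series
    reference_abundance: pd.Series

    def to_dict(self) -> dict:
        return {
            "selected_ids": list(self.selected_ids),
            "exclusion_list": list(self.exclusion_list),
            "stability": {k: float(v) for k, v in self.stability.items()},
            "group_p": {k: float(v) for k, v in self.group_p.items()},
            "nsf": {k: float(v) for k, v in self.nsf.items()},
            "reference_abundance": {
                k: float(v) for k, v in self.reference_abundance.items()
            },
        }


class NSFNormalizer(BaseEstimator):
    """Endogenous-normalizer scaling as an estimator.

    fit(matrix_raw, stability=..., group_p=...) selects the normalizer panel
    and computes per-sample NSFs; transform divides a raw-scale matrix by
    them.  ``selection_`` holds the full report.
    """

    def __init__(self, n_normalizers: int = 6, aggregate: str = "median",
                 ratio_summary: str = "median", exclusion_list: tuple = ()):
        self.n_normalizers = n_normalizers
        self.aggregate = aggregate
        self.ratio_summary = ratio_summary
        self.exclusion_list = exclusion_list

    def fit(self, matrix: AbundanceMatrix, stability: pd.Series, group_p: pd.Series):
        selected = select_normalizers(
            stability, group_p, self.exclusion_list, n=self.n_normalizers
        )
        nsf = compute_nsf(matrix, selected, self.aggregate, self.ratio_summary)
        collapsed = matrix.collapse_replicates()
        reference = pd.Series(
            _aggregate(collapsed.values.loc[selected].to_numpy(dtype=float),
                       self.aggregate, axis=1),
            index=selected,
            name="reference_abundance",
        )
        self.selection_ = NormalizerSelection(
            stability=stability,
            group_p=group_p,
            exclusion_list=list(self.exclusion_list),
            selected_ids=selected,
            nsf=nsf,
            reference_abundance=reference,
        )
        return self

    def transform(self, matrix: AbundanceMatrix) -> AbundanceMatrix:
        return apply_nsf(matrix, self.selection_.nsf)
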