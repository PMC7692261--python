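"""Permutation-adjusted Spearman screens of proteins against clinical indices.

Protein abundance (per-sample medians) is paired with the same-visit score
of six psychiatric indices; Spearman's rho is tested by permutation
(shuffling scores against abundances), p-values are BH-adjusted over the
protein x index grid, and proteins significantly correlated with two or
more indices are reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AbundanceMatrix, ClinicalTable
from .stats import bh_adjust

#: indices entering the multi-index screen
SCREEN_INDICES = ("MADRS", "CGI_S", "BDI", "HAM_D", "CUDOS", "WHOQOL_psychological")


def align_protein_clinical(
    matrix: AbundanceMatrix, clinical: ClinicalTable, indices=SCREEN_INDICES
):
    """One row per (patient, visit): per-sample protein medians paired with
    same-visit index scores.

    Returns ``(abundance, scores)``: two DataFrames with identical row
    indexing.  Visits must map onto the matrix's timepoint labels.
    """
    collapsed = matrix.collapse_replicates()
    ann = collapsed.runs
    keys = list(zip(ann["patient_id"], ann["timepoint"]))
    abundance = collapsed.values.T.copy()
    abundance.index = pd.MultiIndex.from_tuples(keys, names=["patient_id", "visit"])

    known = set(ann["timepoint"])
    bad = set(clinical.scores["visit"]) - known
    if bad:
        raise ValueError(f"unmappable visit label(s): {sorted(bad)}")
    scores = clinical.scores.set_index(["patient_id", "visit"])[list(indices)]
    common = abundance.index.intersection(scores.index)
    missing_patients = set(abundance.index.get_level_values(0)) - set(
        scores.index.get_level_values(0)
    )
    if missing_patients:
        raise ValueError(f"patient id(s) without clinical scores: {sorted(missing_patients)}")
    return abundance.loc[common], scores.loc[common]


def spearman_perm(x, y, B: int = 10000, seed: int = 0):
    """Spearman rho (midrank ties) and two-sided permutation p-value.

    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (B + 1)``, permuting y against
    x; the smallest attainable p is 1/(B+1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    rxc = (rx - rx.mean()) / (rx.std() * np.sqrt(x.size))
    ryc = (ry - ry.mean()) / (ry.std() * np.sqrt(x.size))
    count = 0
    for _ in range(B):
        perm = rng.permutation(ryc)
        if abs(float(rxc @ perm)) >= abs(rho) - 1e-12:
            count += 1
    return rho, (1 + count) / (B + 1)


@dataclasses.dataclass
class CorrelationResult:
    rho: pd.DataFrame  # protein x index
    p: pd.DataFrame  # permutation p
    p_adj: pd.DataFrame  # BH over the protein x index grid
    n_pairs: int
    B: int
    skipped: list  # constant proteins (rho undefined)


def correlate_indices(
    matrix: AbundanceMatrix,
    clinical: ClinicalTable,
    indices=SCREEN_INDICES,
    B: int = 10000,
    seed: int = 0,
) -> CorrelationResult:
    """Permutation Spearman screen of every protein against every index.

    One shared set of B permutations (of the paired visits) is used for the
    whole grid; BH adjustment runs over all protein x index cells.
    Constant proteins are flagged and excluded.
    """
    abundance, scores = align_protein_clinical(matrix, clinical, indices)
    n = abundance.shape[0]
    rng = np.random.default_rng(seed)

    def _std_ranks(df):
        r = np.apply_along_axis(sps.rankdata, 0, df.to_numpy(dtype=float))
        r = r - r.mean(axis=0)
        sd = r.std(axis=0)
        return r, sd

    ra, sa = _std_ranks(abundance)
    ri, si = _std_ranks(scores)
    skipped = [p for p, s in zip(abundance.columns, sa) if s <= 0]
    keep = sa > 0
    ra = ra[:, keep] / sa[keep]
    cols = abundance.columns[keep]
    ri = ri / si
    rho_obs = (ra.T @ ri) / n  # proteins x indices

    exceed = np.zeros_like(rho_obs, dtype=int)
    for _ in range(B):
        perm = rng.permutation(n)
        rho_b = (ra[perm].T @ ri) / n
        exceed += np.abs(rho_b) >= np.abs(rho_obs) - 1e-12
    pvals = (1 + exceed) / (B + 1)

    rho = pd.DataFrame(rho_obs, index=cols, columns=list(indices))
    p = pd.DataFrame(pvals, index=cols, columns=list(indices))
    adj = pd.DataFrame(
        bh_adjust(p.to_numpy().ravel()).reshape(p.shape),
        index=cols, columns=list(indices),
    )
    return CorrelationResult(rho=rho, p=p, p_adj=adj, n_pairs=n, B=B, skipped=skipped)


def multi_index_screen(result: CorrelationResult, alpha: float = 0.05) -> pd.DataFrame:
    """Proteins whose adjusted p is < alpha for two or more indices.

    Returns one row per passing protein with the count and the list of
    significant indices (the bubble-table content).  Monotone in alpha.
    """
    sig = result.p_adj < alpha
    n_sig = sig.sum(axis=1)
    passing = n_sig.index[n_sig >= 2]
    rows = []
    for pid in passing:
        idxs = [c for c in sig.columns if sig.loc[pid, c]]
        rows.append({"protein_id": pid, "n_indices": int(n_sig[pid]),
                     "indices": ",".join(idxs)})
    return pd.DataFrame(rows, columns=["protein_id", "n_indices", "indices"])
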