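"""Longitudinal per-protein testing: rank screens, mixed models, SGoF,
GEE with small-sample-corrected covariance, and paired targeted-MS validation.

The central fixed-effect design, shared by the mixed model and the GEE, is

    abundance ~ group + time + group:time (+ replicate)

with time as a four-level factor (T0 reference), the non-responder group as
reference level, and — in the mixed model — a per-patient random intercept.
The response/time interaction (3 parameters) is the quantity of interest:
it captures group differences in the time course.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, NON_RESPONDER, RESPONDER, TIMEPOINTS
from .hypotests import mannwhitney_p, wilcoxon_signed_p


def merge_replicates_median(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Median over technical replicates: one column per biological sample."""
    return matrix.collapse_replicates()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# time-point rank screens
# ---------------------------------------------------------------------------

def _sample_values(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Protein x (patient, timepoint) per-sample values."""
    collapsed = matrix.collapse_replicates()
    cols = pd.MultiIndex.from_frame(collapsed.runs[["patient_id", "timepoint"]])
    out = collapsed.values.copy()
    out.columns = cols
    return out


def screen_timepoints(matrix: AbundanceMatrix, labels) -> pd.DataFrame:
    """Uncorrected Mann-Whitney screens per protein and post-baseline visit.

    Two contrast families per timepoint Tk in {T1, T4, T10}:

    * ``within``:  per group, the T0 values vs the Tk values;
    * ``between``: the per-patient deltas Tk - T0, responders vs
      non-responders.

    Direction is the sign of the median shift (Tk minus T0 within a group;
    responder delta minus non-responder delta between groups).
    """
    vals = _sample_values(matrix)
    resp, nonr = list(labels.responders), list(labels.non_responders)
    if min(len(resp), len(nonr)) < 2:
        raise ValueError("need >= 2 patients per group")
    rows = []
    for tp in TIMEPOINTS[1:]:
        for pid in vals.index:
            row = vals.loc[pid]
            for gname, members in ((RESPONDER, resp), (NON_RESPONDER, nonr)):
                a = row.loc[[(m, "T0") for m in members]].dropna().to_numpy(float)
                b = row.loc[[(m, tp) for m in members]].dropna().to_numpy(float)
                if len(a) < 2 or len(b) < 2:
                    continue
                p = mannwhitney_p(a, b)
                shift = float(np.median(b) - np.median(a))
                rows.append(
                    {"protein_id": pid, "timepoint": tp, "family": "within",
                     "group": gname, "p_value": p, "direction": int(np.sign(shift)),
                     "median_shift": shift}
                )
            d_r = (row.loc[[(m, tp) for m in resp]].to_numpy(float)
                   - row.loc[[(m, "T0") for m in resp]].to_numpy(float))
            d_n = (row.loc[[(m, tp) for m in nonr]].to_numpy(float)
                   - row.loc[[(m, "T0") for m in nonr]].to_numpy(float))
            d_r, d_n = d_r[~np.isnan(d_r)], d_n[~np.isnan(d_n)]
            if len(d_r) < 2 or len(d_n) < 2:
                continue
            p = mannwhitney_p(d_r, d_n)
            shift = float(np.median(d_r) - np.median(d_n))
            rows.append(
                {"protein_id": pid, "timepoint": tp, "family": "between",
                 "group": "both", "p_value": p, "direction": int(np.sign(shift)),
                 "median_shift": shift}
            )
    return pd.DataFrame(rows)


def venn_counts(named_sets: dict) -> dict:
    """Counts of every non-empty intersection region of the given sets."""
    names = list(named_sets)
    out = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(named_sets[c]) for c in combo))
            outside = set().union(*(set(named_sets[c]) for c in names if c not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


def screen_summary(screen: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Up/down counts per group and visit, and the three-visit Venn regions
    of within-group significant proteins."""
    within = screen[(screen.family == "within") & (screen.p_value < alpha)]
    counts = {}
    for (tp, grp), sub in within.groupby(["timepoint", "group"], observed=True):
        counts[f"{tp}_{grp}"] = {
            "up": int((sub.direction > 0).sum()),
            "down": int((sub.direction < 0).sum()),
        }
    sets = {
        tp: set(within.loc[within.timepoint == tp, "protein_id"])
        for tp in TIMEPOINTS[1:]
    }
    return {"counts": counts, "venn": venn_counts(sets)}


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

def _design(runs: pd.DataFrame, interaction: bool = True, replicate: bool = True):
    """Fixed-effect design matrix from run annotations.

    Treatment coding: non-responder and T0 are reference levels.
    Returns (X DataFrame, interaction column names).
    """
    g = (runs["group"] == RESPONDER).astype(float)
    X = pd.DataFrame({"const": 1.0, "group": g}, index=runs.index)
    for tp in TIMEPOINTS[1:]:
        X[f"time_{tp}"] = (runs["timepoint"] == tp).astype(float)
    inter_cols = []
    if interaction:
        for tp in TIMEPOINTS[1:]:
            col = f"group:time_{tp}"
            X[col] = X["group"] * X[f"time_{tp}"]
            inter_cols.append(col)
    if replicate:
        for r in sorted(runs["replicate_no"].unique())[1:]:
            X[f"replicate_{r}"] = (runs["replicate_no"] == r).astype(float)
    return X, inter_cols


@dataclasses.dataclass
class LmmResult:
    """Per-protein mixed-model results (one row per protein in ``table``)."""

    table: pd.DataFrame
    design_columns: list
    interaction_columns: list


def _fit_mixedlm(y, X, patients, reml):
    """MixedLM fit with an optimizer retry cascade (L-BFGS is fast but
    fragile near variance boundaries)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=patients)
        fit = None
        for method in ("lbfgs", None, "powell"):
            try:
                kwargs = {} if method is None else {"method": method}
                fit = model.fit(reml=reml, maxiter=500, disp=False, **kwargs)
            except np.linalg.LinAlgError:
                continue
            if fit.converged:
                return fit
        if fit is None:
            raise np.linalg.LinAlgError("all optimizers failed")
    return fit


def fit_lmm(
    matrix: AbundanceMatrix,
    proteins=None,
    reml_estimates: bool = True,
) -> LmmResult:
    """Per-protein mixed model with patient random intercept.

    Fixed effects: group, time, group x time, technical replicate.  The
    interaction p-value is a joint likelihood-ratio test of the three
    interaction terms, comparing maximum-likelihood fits of the full and
    reduced models (chi-square, 3 df).  Fixed-effect estimates and variance
    components are reported from the REML fit (skipped when
    ``reml_estimates`` is False, e.g. for large calibration runs).

    Proteins whose fit fails or ends singular get ``converged = False`` and
    no p-value; downstream corrections must skip them.
    """
    if matrix.scale not in ("log2",):
        raise ValueError("fit_lmm expects log2-scale (normalized) intensities")
    X_full, inter_cols = _design(matrix.runs)
    X_red = X_full.drop(columns=inter_cols)
    patients_all = matrix.runs["patient_id"]
    proteins = list(proteins) if proteins is not None else matrix.protein_ids

    rows = []
    for pid in proteins:
        y = matrix.values.loc[pid]
        obs = y.notna()
        yv = y[obs].to_numpy(float)
        Xf = X_full.loc[obs]
        keep = [c for c in Xf.columns if c == "const" or Xf[c].nunique() > 1]
        Xf = Xf[keep]
        inter_here = [c for c in inter_cols if c in keep]
        Xr = X_red.loc[obs, [c for c in X_red.columns if c in keep]]
        pats = patients_all[obs]
        n_tp = matrix.runs.loc[obs.index[obs]].groupby("patient_id", observed=True)[
            "timepoint"].nunique()
        record = {"protein_id": pid, "n_obs": int(obs.sum()), "converged": False,
                  "interaction_lrt": np.nan, "interaction_p": np.nan,
                  "patient_var": np.nan, "resid_var": np.nan}
        if (n_tp < 2).any() or len(inter_here) != len(inter_cols):
            rows.append(record)
            continue
        try:
            full_ml = _fit_mixedlm(yv, Xf.to_numpy(), pats.to_numpy(), reml=False)
            red_ml = _fit_mixedlm(yv, Xr.to_numpy(), pats.to_numpy(), reml=False)
            lrt = max(2.0 * (full_ml.llf - red_ml.llf), 0.0)
            record["interaction_lrt"] = float(lrt)
            record["interaction_p"] = float(sps.chi2.sf(lrt, len(inter_cols)))
            est_fit = full_ml
            if reml_estimates:
                est_fit = _fit_mixedlm(yv, Xf.to_numpy(), pats.to_numpy(), reml=True)
            for name, b in zip(Xf.columns, est_fit.fe_params):
                record[f"b_{name}"] = float(b)
            record["patient_var"] = float(np.asarray(est_fit.cov_re)[0, 0])
            record["resid_var"] = float(est_fit.scale)
            record["converged"] = bool(full_ml.converged and red_ml.converged)
        except (np.linalg.LinAlgError, ValueError):
            pass
        rows.append(record)
    table = pd.DataFrame(rows).set_index("protein_id")
    return LmmResult(table=table, design_columns=list(X_full.columns),
                     interaction_columns=inter_cols)


def lmm_group_pvalues(matrix: AbundanceMatrix, proteins=None) -> pd.Series:
    """Wald p-value of the group main effect from a no-interaction mixed
    model (used as the group-difference criterion for normalizer candidacy)."""
    X, _ = _design(matrix.runs, interaction=False)
    patients = matrix.runs["patient_id"]
    proteins = list(proteins) if proteins is not None else matrix.protein_ids
    out = {}
    gpos = list(X.columns).index("group")
    # group is a between-patient contrast: t reference with n_patients - 2 df
    df = patients.nunique() - 2
    for pid in proteins:
        y = matrix.values.loc[pid]
        obs = y.notna()
        try:
            fit = _fit_mixedlm(y[obs].to_numpy(float), X.loc[obs].to_numpy(),
                               patients[obs].to_numpy(), reml=True)
            z = fit.fe_params[gpos] / fit.bse_fe[gpos]
            out[pid] = float(2.0 * sps.t.sf(abs(z), df))
        except (np.linalg.LinAlgError, ValueError):
            out[pid] = np.nan
    return pd.Series(out, name="group_p")


# ---------------------------------------------------------------------------
# sequential goodness-of-fit metatest
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SgofOutcome:
    pvalues: np.ndarray
    alpha: float
    gamma: float
    p0: float
    a0: float
    b0: float
    n_significant: int
    flags: np.ndarray  # True for the n_significant smallest p-values

    @property
    def significant_indices(self) -> np.ndarray:
        return np.where(self.flags)[0]


def bayes_posterior_h0(s: int, n: int, gamma: float = 0.05, p0: float = 0.5,
                       a0: float = 1.0, b0: float = 1.0) -> float:
    """Posterior probability that the sub-gamma p-value count is null.

    Mixture prior on theta = P(p <= gamma): point mass ``p0`` at
    ``theta = gamma`` (complete null) and weight ``1 - p0`` on a
    Beta(a0, b0) density truncated to ``theta > gamma`` (one-sided
    alternative: an excess of small p-values).
    """
    if not 0 <= s <= n:
        raise ValueError("need 0 <= s <= n")
    log_m0 = s * np.log(gamma) + (n - s) * np.log1p(-gamma)
    log_bb = special.betaln(a0 + s, b0 + n - s) - special.betaln(a0, b0)
    tail_post = 1.0 - special.betainc(a0 + s, b0 + n - s, gamma)
    tail_prior = 1.0 - special.betainc(a0, b0, gamma)
    if tail_post <= 0.0:
        return 1.0
    log_m1 = log_bb + np.log(tail_post) - np.log(tail_prior)
    bayes_factor = np.exp(log_m1 - log_m0)
    return float(1.0 / (1.0 + (1.0 - p0) / p0 * bayes_factor))


def _flag_smallest(p: np.ndarray, n_sig: int) -> np.ndarray:
    flags = np.zeros(p.size, dtype=bool)
    if n_sig > 0:
        order = np.argsort(p, kind="stable")
        flags[order[:n_sig]] = True
    return flags


def sgof_bayesian(pvalues, alpha: float = 0.05, gamma: float = 0.05,
                  p0: float = 0.5, a0: float = 1.0, b0: float = 1.0) -> SgofOutcome:
    """Bayesian sequential goodness-of-fit metatest.

    Counts ``s`` p-values at or below ``gamma``; when the posterior
    probability of the complete null falls below ``alpha`` (the metatest
    rejects), the excess of ``s`` over its null expectation ``n * gamma``
    is declared significant and that many smallest p-values are flagged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0 or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be a non-empty array within [0, 1]")
    if not (0 < alpha < 1 and 0 < gamma < 1 and 0 < p0 < 1 and a0 > 0 and b0 > 0):
        raise ValueError("invalid SGoF parameters")
    n = p.size
    s = int((p <= gamma).sum())
    n_sig = 0
    if s > 0 and bayes_posterior_h0(s, n, gamma, p0, a0, b0) < alpha:
        n_sig = max(int(np.floor(s - n * gamma)), 0)
    return SgofOutcome(pvalues=p, alpha=alpha, gamma=gamma, p0=p0, a0=a0, b0=b0,
                       n_significant=n_sig, flags=_flag_smallest(p, n_sig))


def sgof_binomial(pvalues, alpha: float = 0.05, gamma: float = 0.05) -> SgofOutcome:
    """Classic (frequentist) SGoF metatest, for cross-checking.

    Same excess counting, with a one-sided exact binomial pre-test of the
    sub-gamma count against its null expectation n*gamma.
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    s = int((p <= gamma).sum())
    n_sig = 0
    if s > 0 and sps.binom.sf(s - 1, n, gamma) <= alpha:
        n_sig = max(int(np.floor(s - n * gamma)), 0)
    return SgofOutcome(pvalues=p, alpha=alpha, gamma=gamma, p0=np.nan, a0=np.nan,
                       b0=np.nan, n_significant=n_sig, flags=_flag_smallest(p, n_sig))


# ---------------------------------------------------------------------------
# GEE with Wang-Long small-sample covariance
# ---------------------------------------------------------------------------

def wang_long_covariance(X: np.ndarray, y: np.ndarray, clusters: np.ndarray):
    """Gaussian GEE with independence working correlation and the
    Wang-Long bias-corrected sandwich covariance.

    With an independence working structure and identity link the estimating
    equations are the OLS normal equations, so ``beta`` equals OLS.  The
    covariance pools leverage-corrected residual outer products across
    clusters: ``R = mean_i (I - H_ii)^{-1} e_i e_i' (I - H_ii)^{-T}`` (equal
    cluster sizes required), then ``cov = (X'X)^{-1} [sum_i X_i' R X_i]
    (X'X)^{-1}``.

    Returns ``(beta, cov)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    clusters = np.asarray(clusters)
    ids = pd.unique(clusters)
    sizes = {c: int((clusters == c).sum()) for c in ids}
    if len(set(sizes.values())) != 1:
        raise ValueError("Wang-Long pooling requires equal cluster sizes")
    if len(ids) <= X.shape[1] / sizes[ids[0]]:
        pass  # cluster count adequacy is the caller's concern; keep permissive
    bread = np.linalg.inv(X.T @ X)
    beta = bread @ (X.T @ y)
    resid = y - X @ beta
    m = sizes[ids[0]]
    R = np.zeros((m, m))
    blocks = []
    for c in ids:
        sel = clusters == c
        Xi = X[sel]
        ei = resid[sel]
        Hii = Xi @ bread @ Xi.T
        ci = np.linalg.solve(np.eye(m) - Hii, ei)
        R += np.outer(ci, ci)
        blocks.append(Xi)
    R /= len(ids)
    meat = np.zeros((X.shape[1], X.shape[1]))
    for Xi in blocks:
        meat += Xi.T @ R @ Xi
    cov = bread @ meat @ bread
    return beta, cov


@dataclasses.dataclass
class GeeResult:
    table: pd.DataFrame
    design_columns: list
    interaction_columns: list
    covariances: dict  # protein -> covariance matrix


def fit_gee(matrix: AbundanceMatrix, proteins=None) -> GeeResult:
    """Per-protein GEE on the replicate-merged matrix.

    Clusters are patients; the fixed design matches the mixed model without
    the replicate term.  The interaction p-value is a joint Wald test
    (chi-square, 3 df) of the three interaction coefficients under the
    Wang-Long covariance.  Proteins with missing cells (imputation skipped
    or excluded) are reported unconverged.
    """
    merged = matrix if (matrix.runs["replicate_no"] == 1).all() else matrix.collapse_replicates()
    X, inter_cols = _design(merged.runs, replicate=False)
    clusters = merged.runs["patient_id"].to_numpy()
    n_clusters = len(pd.unique(clusters))
    if n_clusters < len(inter_cols) + 1:
        raise ValueError("too few clusters for the interaction Wald test")
    proteins = list(proteins) if proteins is not None else merged.protein_ids
    idx = [list(X.columns).index(c) for c in inter_cols]
    rows, covs = [], {}
    for pid in proteins:
        y = merged.values.loc[pid].to_numpy(float)
        record = {"protein_id": pid, "converged": False,
                  "interaction_wald": np.nan, "interaction_p": np.nan}
        if not np.isnan(y).any():
            beta, cov = wang_long_covariance(X.to_numpy(), y, clusters)
            bI = beta[idx]
            covI = cov[np.ix_(idx, idx)]
            try:
                w = float(bI @ np.linalg.solve(covI, bI))
                record["interaction_wald"] = w
                record["interaction_p"] = float(sps.chi2.sf(w, len(idx)))
                record["converged"] = True
            except np.linalg.LinAlgError:
                w = np.nan
            for name, b in zip(X.columns, beta):
                record[f"b_{name}"] = float(b)
            covs[pid] = cov
        rows.append(record)
    table = pd.DataFrame(rows).set_index("protein_id")
    return GeeResult(table=table, design_columns=list(X.columns),
                     interaction_columns=inter_cols, covariances=covs)


# ---------------------------------------------------------------------------
# targeted-MS (MRM) validation
# ---------------------------------------------------------------------------

def wilcoxon_mrm_validation(mrm: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired signed-rank validation of T0 -> T1 ratio changes per group.

    Differences are taken on the log2 ratio scale.  p-values are
    BH-adjusted across proteins within each group; a protein is *validated*
    when significant in responders (adjusted p < alpha) and not in
    non-responders.
    """
    wide = mrm.pivot_table(index=["group", "patient_id", "protein_id"],
                           columns="timepoint", values="ratio").reset_index()
    for tp in ("T0", "T1"):
        if tp not in wide.columns:
            raise ValueError(f"MRM table lacks timepoint {tp}")
    wide["diff"] = np.log2(wide["T1"]) - np.log2(wide["T0"])
    proteins = sorted(mrm["protein_id"].unique())
    out = pd.DataFrame(index=pd.Index(proteins, name="protein_id"))
    for grp, tag in ((RESPONDER, "responders"), (NON_RESPONDER, "non_responders")):
        ps, dirs = [], []
        for pid in proteins:
            d = wide.loc[(wide.group == grp) & (wide.protein_id == pid), "diff"]
            d = d.dropna().to_numpy(float)
            if (d != 0).sum() < 2:
                raise ValueError(f"group {grp!r} has < 2 non-zero pairs for {pid}")
            ps.append(wilcoxon_signed_p(d))
            dirs.append(int(np.sign(np.median(d))))
        out[f"p_{tag}"] = ps
        out[f"p_adj_{tag}"] = bh_adjust(ps)
        out[f"direction_{tag}"] = dirs
    out["validated"] = (out["p_adj_responders"] < alpha) & (
        out["p_adj_non_responders"] >= alpha
    )
    return out


def select_mrm_candidates(
    screen: pd.DataFrame,
    lmm_significant,
    alpha: float = 0.05,
    timepoint: str = "T1",
) -> dict:
    """Early-response candidate triage: three-way intersection.

    Candidates must be significant (uncorrected p < alpha) in (1) the
    within-group T0-vs-T1 comparison in either group, (2) the between-group
    comparison of the T1 - T0 deltas, and (3) the mixed-model interaction
    test after SGoF correction (``lmm_significant``).  Returns the candidate
    set and the Venn region counts.
    """
    at_tp = screen[screen.timepoint == timepoint]
    within = set(
        at_tp.loc[(at_tp.family == "within") & (at_tp.p_value < alpha), "protein_id"]
    )
    between = set(
        at_tp.loc[(at_tp.family == "between") & (at_tp.p_value < alpha), "protein_id"]
    )
    sets = {
        f"T0_vs_{timepoint}": within,
        f"delta_{timepoint}_between_groups": between,
        "lmm_interaction": set(lmm_significant),
    }
    candidates = within & between & set(lmm_significant)
    return {"candidates": sorted(candidates), "venn": venn_counts(sets), "sets": sets}
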