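"""Stability scoring, normalizer selection and NSF computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from longiprot.containers import ValidationError
from longiprot.normalize import (
    NSFNormalizer,
    apply_nsf,
    compute_nsf,
    normfinder_stability,
    select_normalizers,
)
from longiprot.preprocess import batch_mean_center, log_transform
from longiprot.stats import lmm_group_pvalues

from conftest import build_matrix


# ---------------------------------------------------------------------------
# independent spreadsheet-style oracle for the stability model
# ---------------------------------------------------------------------------

def stability_oracle(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Step-by-step loop evaluation of the two-way stability model,
    written independently of the vectorised implementation."""
    levels = sorted(groups.unique())
    k = values.shape[0]
    d = {}
    var_d = {}
    for g in levels:
        cols = [s for s in values.columns if groups[s] == g]
        n_g = len(cols)
        z = values[cols]
        grand = float(np.mean(z.to_numpy()))
        s2 = {}
        for i in values.index:
            total = 0.0
            for j in cols:
                r = (z.loc[i, j] - z.loc[i].mean()
                     - z[j].mean() + grand)
                total += r * r
            s2[i] = total / (n_g - 1)
        sbar = float(np.mean(list(s2.values())))
        for i in values.index:
            sig2 = max((s2[i] - sbar / (k - 1)) * k / (k - 2), 0.0)
            d.setdefault(i, {})[g] = z.loc[i].mean() - grand
            var_d.setdefault(i, {})[g] = sig2 / n_g
    # centre bias across groups
    for i in values.index:
        m = np.mean([d[i][g] for g in levels])
        for g in levels:
            d[i][g] -= m
    all_d2 = [d[i][g] ** 2 for i in values.index for g in levels]
    all_v = [var_d[i][g] for i in values.index for g in levels]
    gamma2 = max(np.mean(all_d2) - np.mean(all_v), 0.0)
    out = {}
    for i in values.index:
        acc = 0.0
        for g in levels:
            denom = gamma2 + var_d[i][g]
            shrink = gamma2 / denom if denom > 0 else 0.0
            d_star = d[i][g] * shrink
            acc += abs(d_star) + np.sqrt(var_d[i][g])
        out[i] = acc / len(levels)
    return pd.Series(out)


def _toy_table(seed=0, k=4, n=6):
    rng = np.random.default_rng(seed)
    cols = [f"s{j}" for j in range(n)]
    values = pd.DataFrame(rng.normal(20, 1, (k, n)),
                          index=[f"g{i}" for i in range(k)], columns=cols)
    groups = pd.Series(["A"] * (n // 2) + ["B"] * (n - n // 2), index=cols)
    return values, groups


def test_stability_matches_independent_oracle():
    values, groups = _toy_table(seed=1)
    got = normfinder_stability(values, groups)
    expected = stability_oracle(values, groups)
    assert np.allclose(got.to_numpy(), expected.loc[got.index].to_numpy(),
                       atol=1e-12)


def test_stability_oracle_agreement_across_sizes():
    for seed, k, n in [(2, 5, 8), (3, 8, 10), (4, 4, 6)]:
        values, groups = _toy_table(seed=seed, k=k, n=n)
        got = normfinder_stability(values, groups)
        expected = stability_oracle(values, groups)
        assert np.allclose(got.to_numpy(), expected.loc[got.index].to_numpy(),
                           atol=1e-12)


def test_constant_protein_is_most_stable():
    """An exactly constant candidate gets the minimum stability value.

    The panel is large enough (k=20) that the sample-effect estimates —
    which leak a ~sigma^2/k share of the other genes' noise into every
    gene's residuals — cannot mask the zero-variance candidate."""
    values, groups = _toy_table(seed=5, k=20, n=12)
    values.loc["g0"] = 20.0  # exactly constant across samples
    stab = normfinder_stability(values, groups)
    assert stab.idxmin() == "g0"


def test_group_shift_increases_stability_value():
    """With small residual noise, a planted group-specific shift raises the
    shifted gene's stability value (bias-term monotonicity)."""
    rng = np.random.default_rng(6)
    cols = [f"s{j}" for j in range(8)]
    values = pd.DataFrame(rng.normal(20, 0.05, (6, 8)),
                          index=[f"g{i}" for i in range(6)], columns=cols)
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cols)
    stab0 = normfinder_stability(values, groups)
    shifted = values.copy()
    shifted.loc["g2", groups.index[groups == "B"]] += 1.5
    stab1 = normfinder_stability(shifted, groups)
    assert stab1["g2"] > stab0["g2"]


def test_missing_candidate_rejected():
    values, groups = _toy_table()
    values.iloc[0, 0] = np.nan
    with pytest.raises(ValidationError, match="missing"):
        normfinder_stability(values, groups)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_selection_filters_and_ranking():
    stab = pd.Series({"a": 0.1, "b": 0.2, "c": 0.05, "d": 0.3, "e": 0.15,
                      "f": 0.25, "g": 0.4})
    group_p = pd.Series({k: 0.5 for k in stab.index})
    group_p["c"] = 0.01  # significant group difference: excluded
    chosen = select_normalizers(stab, group_p, exclusion_list=("a",), n=3)
    assert chosen == ["e", "b", "f"]


def test_selection_error_when_too_few_survive():
    stab = pd.Series({"a": 0.1, "b": 0.2})
    group_p = pd.Series({"a": 0.01, "b": 0.5})
    with pytest.raises(ValueError, match="survive"):
        select_normalizers(stab, group_p, n=2)


def test_planted_normalizers_recovered_in_synthetic_cohort(
        default_cohort, preprocessed):
    """The six stable planted reference proteins are exactly the selection
    at the fixture seed."""
    _, _, truth = default_cohort
    imputed = preprocessed["imputed"]
    part = preprocessed["partition"]
    stab = normfinder_stability(imputed.values.loc[part.complete_ids],
                                imputed.runs["group"])
    group_p = lmm_group_pvalues(preprocessed["centered"],
                                proteins=part.complete_ids)
    chosen = select_normalizers(stab, group_p, n=6)
    assert set(chosen) == set(truth.is_normalizer.index[truth.is_normalizer])


# ---------------------------------------------------------------------------
# NSF
# ---------------------------------------------------------------------------

def test_nsf_is_one_when_samples_match_reference():
    vals = np.tile([[10.0], [20.0], [5.0], [8.0], [12.0], [40.0]], (1, 4))
    m = build_matrix(vals, n_patients=1)
    nsf = compute_nsf(m, m.protein_ids)
    assert np.allclose(nsf, 1.0)


def test_doubled_sample_gets_nsf_two():
    vals = np.tile([[10.0], [20.0], [5.0], [8.0], [12.0], [40.0]], (1, 4))
    vals[:, 2] *= 2.0
    m = build_matrix(vals, n_patients=1)
    nsf = compute_nsf(m, m.protein_ids)
    assert nsf.iloc[2] == pytest.approx(2.0)
    assert np.allclose(nsf.drop(nsf.index[2]), 1.0)


def test_nsf_matches_hand_computation():
    rng = np.random.default_rng(7)
    vals = rng.lognormal(2, 0.4, (6, 3))
    m = build_matrix(vals, n_patients=1, timepoints=("T0", "T1", "T4"))
    nsf = compute_nsf(m, m.protein_ids)
    ref = np.median(vals, axis=1)
    ratios = vals / ref[:, None]
    assert np.allclose(nsf.to_numpy(), np.median(ratios, axis=0), atol=1e-12)
    # geometric-mean option
    nsf_g = compute_nsf(m, m.protein_ids, aggregate="geomean",
                        ratio_summary="geomean")
    ref_g = np.exp(np.mean(np.log(vals), axis=1))
    assert np.allclose(nsf_g.to_numpy(),
                       np.exp(np.mean(np.log(vals / ref_g[:, None]), axis=0)),
                       atol=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), c=st.floats(1.0, 10.0))
def test_nsf_equivariance_under_sample_scaling(seed, c):
    """Scaling a sample by c scales its NSF by exactly c.

    Exact as long as the scaling does not move the across-sample median
    reference, so the scaled sample is constructed componentwise maximal
    and c >= 1 (an odd number of samples keeps the median a fixed order
    statistic)."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(2, 0.3, (6, 5))
    vals[:, 1] = vals.max(axis=1) * 1.5
    m = build_matrix(vals, n_patients=5, timepoints=("T0",))
    base = compute_nsf(m, m.protein_ids)
    scaled_vals = vals.copy()
    scaled_vals[:, 1] *= c
    m2 = build_matrix(scaled_vals, n_patients=5, timepoints=("T0",))
    scaled = compute_nsf(m2, m2.protein_ids)
    assert scaled.iloc[1] == pytest.approx(base.iloc[1] * c, rel=1e-9)
    # other samples' NSFs are untouched
    assert np.allclose(scaled.drop(scaled.index[1]),
                       base.drop(base.index[1]), rtol=1e-9)


def test_apply_nsf_identity_and_division():
    vals = np.full((2, 4), 10.0)
    m = build_matrix(vals, n_patients=1)
    ones = pd.Series(1.0, index=m.samples.index)
    out = apply_nsf(m, ones)
    assert np.allclose(out.values, m.values)
    assert out.scale == "normalized"
    twos = pd.Series(2.0, index=m.samples.index)
    assert np.allclose(apply_nsf(m, twos).values, 5.0)


def test_apply_nsf_preserves_missing_and_rejects_zero():
    vals = np.full((1, 4), 10.0)
    m = build_matrix(vals, n_patients=1)
    m.values.iloc[0, 1] = np.nan
    nsf = pd.Series(2.0, index=m.samples.index)
    out = apply_nsf(m, nsf)
    assert np.isnan(out.values.iloc[0, 1])
    with pytest.raises(ValidationError):
        apply_nsf(m, nsf * 0.0)


def test_loading_factor_removed_by_normalization(default_cohort, preprocessed):
    """Per-sample loadings injected by the generator are recovered: after
    dividing by the NSF, the planted normalizers' sample medians agree
    across samples within a few percent."""
    _, _, truth = default_cohort
    imputed = preprocessed["imputed"]
    from longiprot.preprocess import unlog_transform

    raw = unlog_transform(imputed)
    norm_ids = sorted(truth.is_normalizer.index[truth.is_normalizer])
    nsf = compute_nsf(raw, norm_ids)
    normalized = apply_nsf(raw, nsf)
    log_norm = np.log2(normalized.values.loc[norm_ids])
    spread = (log_norm - log_norm.mean(axis=1).to_numpy()[:, None]).median(axis=0)
    assert spread.abs().max() < np.log2(1.05)
    # and the NSF tracks the planted loading (up to a common constant)
    planted = truth.loading.loc[normalized.runs["sample_id"].drop_duplicates()]
    corr = np.corrcoef(np.log2(nsf.loc[planted.index]), planted)[0, 1]
    assert corr > 0.9


def test_nsf_normalizer_estimator_roundtrip(default_cohort, preprocessed):
    _, _, truth = default_cohort
    from longiprot.preprocess import unlog_transform

    imputed = preprocessed["imputed"]
    part = preprocessed["partition"]
    raw = unlog_transform(imputed)
    stab = normfinder_stability(imputed.values.loc[part.complete_ids],
                                imputed.runs["group"])
    group_p = lmm_group_pvalues(preprocessed["centered"],
                                proteins=part.complete_ids)
    est = NSFNormalizer(n_normalizers=6)
    est.fit(raw, stab, group_p)
    out = est.transform(raw)
    assert out.scale == "normalized"
    assert est.get_params()["n_normalizers"] == 6
    assert len(est.selection_.selected_ids) == 6
    assert (est.selection_.nsf > 0).all()
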