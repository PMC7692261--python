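"""Response labeling from MADRS trajectories and baseline-group comparison.

Response is defined by the depression-rating reduction rule: a patient is a
responder when the MADRS score has dropped by at least ``threshold`` (default
50%) of the baseline value at every configured evaluation week (default
weeks 4 and 10; the rule is configurable to final-week-only).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import ClinicalTable, NON_RESPONDER, RESPONDER, ValidationError
from .hypotests import fisher_exact_p, mannwhitney_p

#: mapping from evaluation week to visit label
WEEK_TO_VISIT = {0: "T0", 1: "T1", 4: "T4", 10: "T10"}


@dataclasses.dataclass
class ResponseLabeling:
    """Per-patient responder/non-responder labels and reduction fractions."""

    labels: pd.Series  # patient_id -> {"responder", "non_responder"}
    reductions: pd.DataFrame  # patient_id x eval week -> (baseline - week)/baseline
    threshold: float = 0.5

    @property
    def responders(self) -> list:
        return sorted(self.labels.index[self.labels == RESPONDER])

    @property
    def non_responders(self) -> list:
        return sorted(self.labels.index[self.labels == NON_RESPONDER])


def derive_response_labels(
    clinical: ClinicalTable,
    threshold: float = 0.5,
    eval_weeks: tuple = (4, 10),
) -> ResponseLabeling:
    """Label each patient by the >=50%-MADRS-reduction rule.

    A patient is a responder iff the reduction fraction
    ``(baseline - week)/baseline`` is >= ``threshold`` at *every* evaluation
    week.  Boundary equality counts as response.
    """
    baseline = clinical.score_at("T0", "MADRS")
    if (baseline == 0).any():
        bad = baseline.index[baseline == 0].tolist()
        raise ValidationError(f"baseline MADRS = 0 for patient(s) {bad}")
    red = {}
    for week in eval_weeks:
        visit = WEEK_TO_VISIT.get(week)
        if visit is None:
            raise ValueError(f"no visit mapped to week {week}")
        score = clinical.score_at(visit, "MADRS").reindex(baseline.index)
        if score.isna().any():
            bad = score.index[score.isna()].tolist()
            raise ValidationError(f"missing MADRS at week {week} for patient(s) {bad}")
        red[week] = (baseline - score) / baseline
    reductions = pd.DataFrame(red)
    is_resp = (reductions >= threshold).all(axis=1)
    labels = pd.Series(
        np.where(is_resp, RESPONDER, NON_RESPONDER), index=reductions.index, name="group"
    )
    return ResponseLabeling(labels=labels, reductions=reductions, threshold=threshold)


def compare_baseline_characteristics(
    clinical: ClinicalTable,
    labels: ResponseLabeling,
    binary_variables: tuple = ("sex",),
) -> pd.DataFrame:
    """Per-variable responder vs non-responder comparison at baseline.

    Continuous variables (baseline scores and numeric covariates) are
    compared with the exact two-sided Mann-Whitney U test; binary variables
    with the two-sided Fisher's exact test.  Returns one row per variable
    with group summaries (mean (SD) or count) and the p-value, mirroring a
    demographics table layout.
    """
    resp, nonresp = labels.responders, labels.non_responders
    if len(resp) < 2 or len(nonresp) < 2:
        raise ValueError("need >= 2 patients per group")

    frames = []
    base = clinical.scores[clinical.scores["visit"] == "T0"].set_index("patient_id")
    score_cols = [c for c in base.columns if c != "visit"]
    tables = [base[score_cols]]
    if clinical.covariates is not None:
        tables.insert(0, clinical.covariates.set_index("patient_id"))
    patient_vars = pd.concat(tables, axis=1)

    rows = []
    for var in patient_vars.columns:
        col = patient_vars[var]
        if col.isna().all():
            raise ValidationError(f"variable {var!r} has no observed values")
        a = col.reindex(resp).dropna()
        b = col.reindex(nonresp).dropna()
        if var in binary_variables or col.dropna().dtype == object:
            # binary/categorical: counts of the first level vs the rest
            levels = sorted(col.dropna().unique())
            lvl = levels[0]
            table = [
                [int((a == lvl).sum()), int((a != lvl).sum())],
                [int((b == lvl).sum()), int((b != lvl).sum())],
            ]
            p = fisher_exact_p(table)
            rows.append(
                {
                    "variable": var,
                    "test": "fisher_exact",
                    "responders": f"{table[0][0]}/{len(a)}",
                    "non_responders": f"{table[1][0]}/{len(b)}",
                    "p_value": p,
                }
            )
        else:
            p = mannwhitney_p(a.to_numpy(float), b.to_numpy(float))
            rows.append(
                {
                    "variable": var,
                    "test": "mann_whitney",
                    "responders": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                    "non_responders": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                    "p_value": p,
                }
            )
    frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
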