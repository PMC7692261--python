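"""Shared fixtures: synthetic cohorts and small matrix builders."""

import logging

import numpy as np
import pandas as pd
import pytest

from longiprot import (
    CohortConfig,
    derive_response_labels,
    generate_cohort,
)
from longiprot.containers import AbundanceMatrix
from longiprot.preprocess import LLSImputer, batch_mean_center, log_transform

logging.getLogger("longiprot").setLevel(logging.ERROR)

#: low-noise / strong-effect conditions used by the recovery tests
STRONG = dict(effect_size=2.0, noise_sd=0.05, patient_sd=0.2,
              batch_shift_sd=0.1, loading_sd=0.1, missing_rate_target=0.0)


def build_matrix(values, n_patients=2, timepoints=("T0", "T1", "T4", "T10"),
                 replicates=1, scale="raw", batches=None):
    """Small AbundanceMatrix from a proteins x runs array.

    Runs are laid out patient-major, then timepoint, then replicate; the
    first half of patients are responders.
    """
    values = np.asarray(values, dtype=float)
    patients = [f"P{i+1}" for i in range(n_patients)]
    half = max(n_patients // 2, 1)
    rows = []
    for i, p in enumerate(patients):
        for t in timepoints:
            for r in range(1, replicates + 1):
                rows.append({
                    "run_id": f"{p}_{t}_r{r}", "sample_id": f"{p}_{t}",
                    "patient_id": p,
                    "group": "responder" if i < half else "non_responder",
                    "timepoint": t,
                    "batch_id": (batches[i] if batches else "B1"),
                    "replicate_no": r,
                })
    runs = pd.DataFrame(rows).set_index("run_id")
    assert values.shape[1] == len(runs), (values.shape, len(runs))
    vals = pd.DataFrame(values, index=[f"PR{j+1}" for j in range(values.shape[0])],
                        columns=runs.index)
    return AbundanceMatrix(vals, runs, scale=scale)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    _, clinical, _ = default_cohort
    return derive_response_labels(clinical)


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    matrix, _, _ = default_cohort
    centered = batch_mean_center(log_transform(matrix))
    imputer = LLSImputer(k=15)
    imputed = imputer.fit_transform(centered)
    return {"centered": centered, "imputer": imputer, "imputed": imputed,
            "partition": imputer.partition_}


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(CohortConfig(seed=0, **STRONG))


@pytest.fixture(scope="session")
def strong_labels(strong_cohort):
    _, clinical, _ = strong_cohort
    return derive_response_labels(clinical)


@pytest.fixture(scope="session")
def strong_centered(strong_cohort):
    matrix, _, _ = strong_cohort
    return batch_mean_center(log_transform(matrix))
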