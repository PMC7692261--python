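"""In-memory containers and delimited-text IO for longitudinal LFQ cohorts.

The central object is :class:`AbundanceMatrix`: a proteins x runs intensity
table with per-run annotations (sample, patient, response group, time point,
batch, technical replicate).  Missing cells are ``NaN`` and are never coerced
to zero.  Tables are exchanged as long-format TSV/CSV with a header row;
missing intensities are encoded as an empty field or ``NA``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

TIMEPOINTS = ("T0", "T1", "T4", "T10")
GROUPS = ("responder", "non_responder")

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

#: canonical column names of the long-format abundance table
ABUNDANCE_COLUMNS = (
    "protein_id",
    "run_id",
    "sample_id",
    "patient_id",
    "group",
    "timepoint",
    "batch_id",
    "replicate_no",
    "intensity",
)

RUN_FIELDS = ("sample_id", "patient_id", "group", "timepoint", "batch_id", "replicate_no")

#: clinical score columns (instrument scales)
CLINICAL_SCORES = (
    "MADRS",
    "CGI_S",
    "BDI",
    "HAM_D",
    "CUDOS",
    "WHOQOL_physical",
    "WHOQOL_psychological",
    "WHOQOL_social",
    "WHOQOL_environmental",
)


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def timepoint_categorical(values) -> pd.Categorical:
    cat = pd.Categorical(values, categories=list(TIMEPOINTS), ordered=True)
    if cat.isna().any():
        bad = sorted(set(np.asarray(values)[cat.isna()]))
        raise ValidationError(f"unknown timepoint label(s): {bad}; expected {TIMEPOINTS}")
    return cat


@dataclasses.dataclass
class AbundanceMatrix:
    """Proteins x runs intensity matrix with run annotations.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by protein id, columns by run id; ``NaN`` marks a
        missing cell.
    runs : DataFrame
        Indexed by run id with columns ``sample_id, patient_id, group,
        timepoint, batch_id, replicate_no``, aligned to ``values.columns``.
    scale : {"raw", "log2", "normalized"}
        Scale of the stored intensities.  Raw and normalized intensities are
        strictly positive; log2 values are unconstrained.
    """

    values: pd.DataFrame
    runs: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in ("raw", "log2", "normalized"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != list(self.runs.index):
            raise ValidationError("values columns and run annotations are not aligned")
        missing_fields = [f for f in RUN_FIELDS if f not in self.runs.columns]
        if missing_fields:
            raise ValidationError(f"run annotation missing fields: {missing_fields}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate protein ids: {dup}")
        key = self.runs[["patient_id", "timepoint", "replicate_no"]].astype(str)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"(patient_id, timepoint, replicate_no) not unique: {tuple(dup)}"
            )
        nbatch = self.runs.groupby("patient_id", observed=True)["batch_id"].nunique()
        if (nbatch > 1).any():
            bad = nbatch[nbatch > 1].index.tolist()
            raise ValidationError(f"batch_id not constant within patient(s): {bad}")
        if self.scale in ("raw", "normalized"):
            arr = self.values.to_numpy(dtype=float)
            if np.any(arr[~np.isnan(arr)] <= 0):
                raise ValidationError(f"non-positive intensities on {self.scale} scale")

    # -- conveniences ----------------------------------------------------
    @property
    def protein_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.runs.copy(), self.scale)

    @property
    def samples(self) -> pd.DataFrame:
        """One annotation row per biological sample (patient x timepoint)."""
        cols = ["sample_id", "patient_id", "group", "timepoint", "batch_id"]
        samp = self.runs[cols].drop_duplicates("sample_id").set_index("sample_id")
        return samp

    def collapse_replicates(self) -> "AbundanceMatrix":
        """Median over technical replicates: one column per sample.

        Missing replicate cells are ignored; a sample cell is missing only
        when every replicate of that sample is missing.
        """
        sample_of_run = self.runs["sample_id"]
        med = self.values.T.groupby(sample_of_run).median().T
        med = med[sample_of_run.drop_duplicates().tolist()]  # keep run order
        runs = self.samples.loc[med.columns].copy()
        runs.insert(0, "sample_id", runs.index)
        runs["replicate_no"] = 1
        runs.index.name = "run_id"
        return AbundanceMatrix(med, runs, self.scale)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.rename_axis("protein_id")
            .reset_index()
            .melt(id_vars="protein_id", var_name="run_id", value_name="intensity")
        )
        ann = self.runs.rename_axis("run_id").reset_index()
        long = long.merge(ann, on="run_id", how="left")
        return long[list(ABUNDANCE_COLUMNS)]


# -- file IO -------------------------------------------------------------

def _sep_for(path: Path, dialect: dict | None) -> str:
    if dialect and "sep" in dialect:
        return dialect["sep"]
    return "," if str(path).endswith(".csv") else "\t"


def read_abundance_table(path, dialect: dict | None = None, scale: str = "raw") -> AbundanceMatrix:
    """Read a long-format intensity table into an :class:`AbundanceMatrix`.

    ``dialect`` may override the delimiter (``{"sep": ","}``) and map
    canonical column names to file column names
    (``{"columns": {"protein_id": "Protein"}}``).  Missing intensities are
    empty fields or ``NA``; they are kept as missing, never as zero.  Rows
    with non-positive raw intensity are rejected with their row indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True)
    colmap = (dialect or {}).get("columns", {})
    df = df.rename(columns={v: k for k, v in colmap.items()})
    required = [c for c in ABUNDANCE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")

    dup = df.duplicated(subset=["protein_id", "run_id"], keep=False)
    if dup.any():
        first = df.loc[dup, ["protein_id", "run_id"]].iloc[0]
        raise ValidationError(
            f"duplicate (protein, run) pair: ({first['protein_id']}, {first['run_id']})"
        )
    if scale in ("raw", "normalized"):
        bad = df.index[df["intensity"].notna() & (df["intensity"] <= 0)]
        if len(bad):
            raise ValidationError(
                f"non-positive raw intensity at row index(es) {bad.tolist()[:10]}"
            )
    df["timepoint"] = timepoint_categorical(df["timepoint"]).astype(str)

    values = df.pivot(index="protein_id", columns="run_id", values="intensity")
    # preserve file order (pivot sorts lexicographically)
    values = values.reindex(index=df["protein_id"].drop_duplicates(),
                            columns=df["run_id"].drop_duplicates())
    runs = (
        df[["run_id", *RUN_FIELDS]]
        .drop_duplicates("run_id")
        .set_index("run_id")
        .loc[values.columns]
    )
    runs["replicate_no"] = runs["replicate_no"].astype(int)
    if (runs["replicate_no"] < 1).any():
        raise ValidationError("replicate_no must be a positive integer")
    return AbundanceMatrix(values, runs, scale=scale)


def write_abundance_table(matrix: AbundanceMatrix, path, dialect: dict | None = None) -> None:
    """Write the long-format table; missing cells become empty fields."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    long = matrix.to_long()
    long.to_csv(path, sep=sep, index=False, na_rep="")


@dataclasses.dataclass
class ClinicalTable:
    """Patient x visit psychiatric scores plus patient-level covariates.

    ``scores`` is long-format (one row per patient x visit) with the columns
    in :data:`CLINICAL_SCORES`; ``covariates`` is one row per patient (sex,
    age, ...).  All patients must have baseline MADRS >= 18 (study inclusion
    rule) and non-negative scores.
    """

    scores: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in ("patient_id", "visit"):
            if col not in self.scores.columns:
                raise ValidationError(f"clinical scores missing column {col!r}")
        present = [c for c in CLINICAL_SCORES if c in self.scores.columns]
        if "MADRS" not in present:
            raise ValidationError("clinical scores must include MADRS")
        vals = self.scores[present].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValidationError("clinical scores must be non-negative")
        base = self.scores[self.scores["visit"] == "T0"]
        if (base["MADRS"] < 18).any():
            bad = base.loc[base["MADRS"] < 18, "patient_id"].tolist()
            raise ValidationError(f"baseline MADRS < 18 for patient(s) {bad}")

    def score_at(self, visit: str, score: str = "MADRS") -> pd.Series:
        sub = self.scores[self.scores["visit"] == visit]
        return sub.set_index("patient_id")[score]


def read_clinical_table(path, covariates_path=None, dialect: dict | None = None) -> ClinicalTable:
    path = Path(path)
    sep = _sep_for(path, dialect)
    scores = pd.read_csv(path, sep=sep, na_values=["NA"])
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(Path(covariates_path), sep=sep, na_values=["NA"])
    return ClinicalTable(scores, cov)


def write_clinical_table(table: ClinicalTable, path, covariates_path=None) -> None:
    sep = _sep_for(Path(path), None)
    table.scores.to_csv(path, sep=sep, index=False, na_rep="")
    if covariates_path is not None and table.covariates is not None:
        table.covariates.to_csv(covariates_path, sep=sep, index=False, na_rep="")


def read_mrm_table(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a targeted-MS (MRM) light/heavy ratio table.

    Long format: ``patient_id, group, timepoint, protein_id, ratio`` with
    paired T0/T1 measurements per patient.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    required = ["patient_id", "group", "timepoint", "protein_id", "ratio"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"MRM table missing column(s): {missing}")
    return df
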