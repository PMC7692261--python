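"""Seeded synthetic cohorts emulating a longitudinal plasma LFQ study.

The generator emits the three tables the analysis consumes — a raw
protein x run intensity matrix, a clinical score table, and a paired
targeted-MS (MRM) ratio table — together with a :class:`SyntheticTruth`
bookkeeping object for recovery tests.

Design being emulated: two response groups of five patients, four visits
(weeks 0/1/4/10), two or three technical replicates per plasma sample,
316 quantified proteins of which six are stable endogenous normalizers,
three preparation batches of 2/2/6 patients (each balanced across groups),
six planted trajectory archetypes covering 37 proteins, abundance-dependent
(MNAR) dropout plus a small MCAR floor calibrated so that ~43% of proteins
carry at least one missing cell, and MADRS trajectories that satisfy (or
fail) the >=50%-reduction response rule by construction.

Generative model per protein, on the log2 scale::

    x = mu_j + u_{j,patient} + b_{j,batch} + delta_{archetype(group, time)}
        + beta_link * severity(patient, time) + loading_sample + eps

with everything exponentiated to the raw scale.  The per-sample loading
factor (log-normal) is shared by all proteins, giving the endogenous
normalization step real signal to remove.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import (
    AbundanceMatrix,
    ClinicalTable,
    NON_RESPONDER,
    RESPONDER,
    TIMEPOINTS,
)

# Six trajectory archetypes: log2 change from baseline at (T1, T4, T10), in
# units of ``effect_size``, for responders (R) and non-responders (N).
# The shapes realise, with piecewise-linear surfaces: (1) gradual R decrease /
# N increase; (2) near-flat R, N decrease; (3) early R jump then plateau,
# sharp N drop at week 4; (4) R decrease / N increase with an early dip and
# late acceleration; (5) near-flat R, N increase; (6) R dip at week 4
# recovering by week 10, near-flat N.  The "near-flat" arms carry small
# non-zero drifts and archetype 4 a non-monotone wiggle so that the six
# Spearman rank patterns are pairwise distinct (a rank-based similarity
# cannot separate two strictly monotone surfaces of the same orientation).
ARCHETYPE_DELTAS = {
    1: ((-0.45, -0.8, -1.2), (0.45, 0.8, 1.2)),
    2: ((0.3, 0.1, 0.2), (-0.45, -0.8, -1.2)),
    3: ((0.9, 1.2, 1.05), (-0.3, -1.05, -0.9)),
    4: ((-0.8, -0.45, -1.2), (0.8, 0.45, 1.2)),
    5: ((0.1, 0.3, 0.2), (0.75, 1.05, 1.35)),
    6: ((-0.3, -1.2, -0.05), (0.1, 0.3, 0.2)),
}

#: proteins measured in the validation MRM panel (three planted markers and
#: five null candidates carried through triage)
MRM_PLANTED_DEFAULT = {"PHOX2B": "up", "SH3BGRL3": "down", "YWHAE": "down"}
MRM_NULL_PROTEINS = ("AHSG", "GC", "ITIH3", "APOD", "CALU")


@dataclasses.dataclass
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults are the emulated study's conditions; SDs are on the log2 scale.
    """

    n_responders: int = 5
    n_non_responders: int = 5
    timepoints: tuple = TIMEPOINTS
    replicates_per_sample: int = 2
    n_proteins: int = 316
    n_normalizers: int = 6
    batch_sizes: tuple = (2, 2, 6)
    archetype_counts: tuple = (3, 5, 3, 5, 10, 11)
    n_clinical_linked: int = 11
    effect_size: float = 1.0
    noise_sd: float = 0.25
    patient_sd: float = 0.5
    batch_shift_sd: float = 0.3
    loading_sd: float = 0.25
    normalizer_noise_factor: float = 0.1
    missing_rate_target: float = 0.43
    mnar_steepness: float = 0.8
    mcar_rate: float = 0.002
    clinical_link_strength: float = 0.8
    mean_log2: float = 20.0
    sd_log2: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if sum(self.archetype_counts) + self.n_normalizers + self.n_clinical_linked > self.n_proteins:
            raise ValueError("archetype, normalizer and linked counts exceed n_proteins")
        if self.n_normalizers >= self.n_proteins:
            raise ValueError("n_normalizers must be < n_proteins")
        if sum(self.batch_sizes) != self.n_responders + self.n_non_responders:
            raise ValueError("batch sizes must sum to the number of patients")
        if self.replicates_per_sample not in (2, 3):
            raise ValueError("replicates_per_sample must be 2 or 3")
        for name in ("effect_size", "noise_sd", "patient_sd", "batch_shift_sd",
                     "loading_sd", "mnar_steepness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    archetype: pd.Series  # protein -> 0 (null) .. 6
    is_normalizer: pd.Series  # protein -> bool
    surface: pd.DataFrame  # protein x (group, timepoint) planted log2 delta
    batch_shift: pd.DataFrame  # protein x batch log2 shift
    loading: pd.Series  # sample -> log2 loading factor
    clinical_linked: list  # proteins sharing the latent severity factor
    groups: pd.Series  # patient -> group
    mnar_threshold: float
    config: CohortConfig

    @property
    def archetype_proteins(self) -> list:
        return sorted(self.archetype.index[self.archetype > 0])

    def to_json(self, path) -> None:
        payload = {
            "archetype": self.archetype.astype(int).to_dict(),
            "is_normalizer": {k: bool(v) for k, v in self.is_normalizer.items()},
            "clinical_linked": list(self.clinical_linked),
            "groups": self.groups.to_dict(),
            "mnar_threshold": self.mnar_threshold,
            "config": self.config.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _patient_layout(config: CohortConfig):
    """Patients, groups and batch assignment (batches balanced by group)."""
    resp = [f"R{i+1:02d}" for i in range(config.n_responders)]
    nonr = [f"N{i+1:02d}" for i in range(config.n_non_responders)]
    interleaved = [p for pair in zip(resp, nonr) for p in pair]
    interleaved += resp[len(nonr):] + nonr[len(resp):]
    batches = {}
    start = 0
    for b, size in enumerate(config.batch_sizes, start=1):
        for p in interleaved[start:start + size]:
            batches[p] = f"B{b}"
        start += size
    groups = pd.Series(
        {p: RESPONDER for p in resp} | {p: NON_RESPONDER for p in nonr}, name="group"
    )
    return resp + nonr, groups, pd.Series(batches, name="batch_id")


def _gauss_hermite(n=31):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()


def _calibrate_mnar_threshold(config: CohortConfig, n_samples: int) -> float:
    """Detection threshold tau such that the expected fraction of proteins
    with >= 1 missing *sample-level* cell matches ``missing_rate_target``.

    A sample cell is missing only when every technical replicate dropped;
    replicates share the patient/batch/loading components and differ by
    measurement noise only.  Solved from the generator's own model with
    nested Gauss-Hermite quadrature: over protein baselines mu ~
    N(mean_log2, sd_log2^2), over the shared within-protein spread, and over
    replicate noise; per-cell dropout = mcar + (1-mcar) *
    logistic((tau - x)/steepness).
    """
    if config.missing_rate_target <= 0:
        return -np.inf
    s = max(config.mnar_steepness, 1e-9)
    shared_sd = np.sqrt(
        config.patient_sd ** 2 + config.batch_shift_sd ** 2 + config.loading_sd ** 2
    )
    r = config.replicates_per_sample
    zx, zw = _gauss_hermite()
    ex, ew = _gauss_hermite()
    mx, mw = _gauss_hermite()

    def frac_affected(tau):
        mu = config.mean_log2 + config.sd_log2 * mx  # baselines
        shared = mu[:, None] + shared_sd * zx[None, :]  # patient/batch/loading
        x = shared[:, :, None] + config.noise_sd * ex[None, None, :]  # replicates
        p_cell = config.mcar_rate + (1 - config.mcar_rate) / (1 + np.exp((x - tau) / s))
        p_sample = (p_cell @ ew) ** r  # all replicates of the sample drop
        q = (1 - p_sample) @ zw  # per-sample survival
        p_protein = 1 - q ** n_samples
        return float(p_protein @ mw)

    lo = config.mean_log2 - 8 * config.sd_log2 - 10
    hi = config.mean_log2 + 8 * config.sd_log2 + 10
    target = config.missing_rate_target
    return float(optimize.brentq(lambda t: frac_affected(t) - target, lo, hi, xtol=1e-6))


def _severity_multipliers(rng, groups: pd.Series) -> pd.DataFrame:
    """Latent severity (fraction of baseline) per patient and visit."""
    rows = {}
    for p, g in groups.items():
        if g == RESPONDER:
            m = [1.0,
                 float(np.clip(rng.normal(0.75, 0.08), 0.55, 0.95)),
                 float(rng.uniform(0.30, 0.48)),
                 float(rng.uniform(0.25, 0.45))]
        else:
            m = [1.0,
                 float(np.clip(rng.normal(0.92, 0.05), 0.8, 1.1)),
                 float(rng.uniform(0.55, 0.85)),
                 float(rng.uniform(0.55, 0.90))]
        rows[p] = m
    return pd.DataFrame(rows, index=list(TIMEPOINTS)).T


def _clinical_tables(rng, groups: pd.Series, severity: pd.DataFrame) -> ClinicalTable:
    """Clinical indices as noisy affine transforms of the latent severity."""
    base_madrs = {}
    for p, g in groups.items():
        mean, sd = (31.0, 4.6) if g == RESPONDER else (28.8, 2.5)
        base_madrs[p] = int(np.clip(np.round(rng.normal(mean, sd)), 20, 44))
    rows = []
    # (intercept, slope) on the severity fraction, per instrument scale
    affine = {
        "CGI_S": (0.3, 4.5), "BDI": (0.0, 30.0), "HAM_D": (0.0, 21.5),
        "CUDOS": (0.0, 39.0), "WHOQOL_physical": (13.5, -4.8),
        "WHOQOL_psychological": (13.0, -4.8), "WHOQOL_social": (15.5, -4.8),
        "WHOQOL_environmental": (15.0, -4.8),
    }
    for p in groups.index:
        for t in TIMEPOINTS:
            sev = severity.loc[p, t]
            score = int(np.round(base_madrs[p] * sev))
            if t == "T0":
                score = base_madrs[p]
            row = {"patient_id": p, "visit": t, "MADRS": score}
            for name, (a, b) in affine.items():
                noise = rng.normal(0.0, 0.35)
                row[name] = float(np.round(max(a + b * sev + noise, 0.0), 1))
            rows.append(row)
    scores = pd.DataFrame(rows)

    # enforce the response rule exactly at the evaluation weeks
    for p, g in groups.items():
        base = scores.loc[(scores.patient_id == p) & (scores.visit == "T0"), "MADRS"].iloc[0]
        for t in ("T4", "T10"):
            sel = (scores.patient_id == p) & (scores.visit == t)
            val = scores.loc[sel, "MADRS"].iloc[0]
            red = (base - val) / base
            if g == RESPONDER and red < 0.5:
                scores.loc[sel, "MADRS"] = int(np.floor(base * 0.5))
            if g == NON_RESPONDER and red >= 0.5:
                scores.loc[sel, "MADRS"] = int(np.ceil(base * 0.55))

    cov_rows = []
    for grp, (age_m, age_s, on_m, on_s, bmi_m, bmi_s) in {
        RESPONDER: (44.2, 14.2, 41.8, 11.9, 23.1, 3.7),
        NON_RESPONDER: (42.8, 16.4, 33.4, 9.8, 24.7, 4.6),
    }.items():
        members = [p for p, g in groups.items() if g == grp]
        n_male = max(1, int(round(0.2 * len(members))))
        for i, p in enumerate(members):
            age = float(np.clip(np.round(rng.normal(age_m, age_s), 1), 19, 65))
            onset = float(np.clip(np.round(rng.normal(on_m, on_s), 1), 18, age))
            bmi = float(np.clip(np.round(rng.normal(bmi_m, bmi_s), 1), 16, 40))
            cov_rows.append(
                {"patient_id": p, "sex": "M" if i < n_male else "F",
                 "age": age, "age_at_onset": onset, "bmi": bmi}
            )
    covariates = pd.DataFrame(cov_rows)
    return ClinicalTable(scores, covariates)


def generate_cohort(config: CohortConfig | None = None):
    """Generate (AbundanceMatrix, ClinicalTable, SyntheticTruth).

    Byte-deterministic given ``config.seed``.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    patients, groups, batch_of = _patient_layout(config)
    tps = list(config.timepoints)
    reps = range(1, config.replicates_per_sample + 1)
    run_rows = []
    for p in patients:
        for t in tps:
            sample = f"{p}_{t}"
            for r in reps:
                run_rows.append(
                    {"run_id": f"{sample}_r{r}", "sample_id": sample,
                     "patient_id": p, "group": groups[p], "timepoint": t,
                     "batch_id": batch_of[p], "replicate_no": r}
                )
    runs = pd.DataFrame(run_rows).set_index("run_id")
    samples = runs["sample_id"].drop_duplicates().tolist()
    n_runs = len(runs)

    proteins = [f"P{i+1:04d}" for i in range(config.n_proteins)]
    order = rng.permutation(config.n_proteins)
    cursor = 0
    normalizer_idx = order[cursor:cursor + config.n_normalizers]; cursor += config.n_normalizers
    archetype = np.zeros(config.n_proteins, dtype=int)
    for arch_id, count in enumerate(config.archetype_counts, start=1):
        idx = order[cursor:cursor + count]; cursor += count
        archetype[idx] = arch_id
    linked_idx = order[cursor:cursor + config.n_clinical_linked]; cursor += config.n_clinical_linked
    is_norm = np.zeros(config.n_proteins, dtype=bool)
    is_norm[normalizer_idx] = True

    # planted group x time mean surface (log2 delta from baseline)
    surface_cols = pd.MultiIndex.from_product([[RESPONDER, NON_RESPONDER], tps])
    surface = pd.DataFrame(0.0, index=proteins, columns=surface_cols)
    for j, arch_id in enumerate(archetype):
        if arch_id == 0:
            continue
        d_r, d_n = ARCHETYPE_DELTAS[arch_id]
        for t, dr, dn in zip(tps[1:], d_r, d_n):
            surface.loc[proteins[j], (RESPONDER, t)] = config.effect_size * dr
            surface.loc[proteins[j], (NON_RESPONDER, t)] = config.effect_size * dn

    severity = _severity_multipliers(rng, groups)
    clinical = _clinical_tables(rng, groups, severity)
    sev_z = (severity - severity.to_numpy().mean()) / max(severity.to_numpy().std(), 1e-12)

    noise_factor = np.where(is_norm, config.normalizer_noise_factor, 1.0)
    mu = rng.normal(config.mean_log2, config.sd_log2, config.n_proteins)
    mu[normalizer_idx] = rng.normal(config.mean_log2 + 2.0, 1.0, config.n_normalizers)
    u_patient = rng.normal(0.0, 1.0, (config.n_proteins, len(patients)))
    u_patient *= (config.patient_sd * noise_factor)[:, None]
    batches = sorted(batch_of.unique())
    b_shift = rng.normal(0.0, config.batch_shift_sd, (config.n_proteins, len(batches)))
    b_shift[normalizer_idx, :] = 0.0
    loading = pd.Series(rng.normal(0.0, config.loading_sd, len(samples)),
                        index=samples, name="log2_loading")

    pat_pos = {p: i for i, p in enumerate(patients)}
    batch_pos = {b: i for i, b in enumerate(batches)}
    x = np.empty((config.n_proteins, n_runs))
    for c, (run_id, ann) in enumerate(runs.iterrows()):
        p, t, g = ann["patient_id"], ann["timepoint"], ann["group"]
        col = (
            mu
            + u_patient[:, pat_pos[p]]
            + b_shift[:, batch_pos[ann["batch_id"]]]
            + surface[(g, t)].to_numpy()
            + loading[ann["sample_id"]]
        )
        col = col + rng.normal(0.0, 1.0, config.n_proteins) * (config.noise_sd * noise_factor)
        x[:, c] = col
    link_term = np.zeros((config.n_proteins, n_runs))
    for c, (run_id, ann) in enumerate(runs.iterrows()):
        z = sev_z.loc[ann["patient_id"], ann["timepoint"]]
        link_term[linked_idx, c] = config.clinical_link_strength * z
    x = x + link_term

    tau = _calibrate_mnar_threshold(config, len(samples))
    values = np.power(2.0, x)
    if np.isfinite(tau):
        s = max(config.mnar_steepness, 1e-9)
        p_miss = config.mcar_rate + (1 - config.mcar_rate) / (1 + np.exp((x - tau) / s))
        mask = rng.random(x.shape) < p_miss
        mask[is_norm, :] = False
        values[mask] = np.nan

    matrix = AbundanceMatrix(
        pd.DataFrame(values, index=proteins, columns=runs.index), runs, scale="raw"
    )
    truth = SyntheticTruth(
        archetype=pd.Series(archetype, index=proteins, name="archetype"),
        is_normalizer=pd.Series(is_norm, index=proteins, name="is_normalizer"),
        surface=surface,
        batch_shift=pd.DataFrame(b_shift, index=proteins, columns=batches),
        loading=loading,
        clinical_linked=sorted(proteins[i] for i in linked_idx),
        groups=groups,
        mnar_threshold=tau,
        config=config,
    )
    return matrix, clinical, truth


def generate_mrm_cohort(
    n_responders: int = 19,
    n_non_responders: int = 5,
    planted: dict | None = None,
    null_proteins: tuple = MRM_NULL_PROTEINS,
    effect_size: float = 1.5,
    between_sd: float = 0.5,
    pair_sd: float = 0.3,
    seed: int = 0,
):
    """Paired T0/T1 light-to-heavy MRM ratios for the validation cohort.

    ``planted`` maps protein name to direction ("up"/"down"); planted log2
    effects of magnitude ``effect_size`` are applied to responders only.
    Null proteins have zero expected paired difference in both groups.
    Returns ``(table, truth)`` where truth maps protein -> signed planted
    log2 effect in responders.
    """
    if n_responders < 2 or n_non_responders < 2:
        raise ValueError("group sizes must be >= 2")
    planted = MRM_PLANTED_DEFAULT if planted is None else planted
    for direction in planted.values():
        if direction not in ("up", "down"):
            raise ValueError(f"planted direction must be 'up' or 'down', got {direction!r}")
    rng = np.random.default_rng(seed)
    proteins = list(planted) + list(null_proteins)
    effects = {
        prot: (effect_size if direction == "up" else -effect_size)
        for prot, direction in planted.items()
    } | {prot: 0.0 for prot in null_proteins}

    rows = []
    patients = [(f"VR{i+1:02d}", RESPONDER) for i in range(n_responders)] + [
        (f"VN{i+1:02d}", NON_RESPONDER) for i in range(n_non_responders)
    ]
    for pid, grp in patients:
        for prot in proteins:
            base = rng.normal(0.0, between_sd)
            delta = effects[prot] if grp == RESPONDER else 0.0
            follow = base + delta + rng.normal(0.0, pair_sd)
            rows.append({"patient_id": pid, "group": grp, "timepoint": "T0",
                         "protein_id": prot, "ratio": float(2.0 ** base)})
            rows.append({"patient_id": pid, "group": grp, "timepoint": "T1",
                         "protein_id": prot, "ratio": float(2.0 ** follow)})
    table = pd.DataFrame(rows)
    truth = {"effects": effects, "planted": dict(planted), "effect_size": effect_size}
    return table, truth
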