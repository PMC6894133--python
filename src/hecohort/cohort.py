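"""Simulated longitudinal oncology cohort.

Each patient enrolls at a uniformly random day within a start window,
survives a normally distributed time drawn from their group (a standard
majority and a small exceptional-responder minority with longer survival),
and contributes one visit record per study month while alive and on
study, carrying body weight (kg) and drug dose (mg/kg).  A per-month 0/1
flag array marks, for exceptional-group patients, the month from which
their unusually long survival has been fully observed (the month
containing their death day); standard-group flags stay 0.

Time is discretized at 30 days per month; study months are 0-based
indices from study opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "PatientRecord",
    "Cohort",
    "simulate_cohort",
    "compute_flags",
    "survival_histogram",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_CSV_COLUMNS",
]

STANDARD = "standard"
EXCEPTIONAL = "exceptional"

COHORT_CSV_COLUMNS = [
    "patient_id",
    "start_day",
    "group",
    "survival_days",
    "month_index",
    "weight_kg",
    "dose_mg_per_kg",
    "flag",
]


@dataclass(frozen=True)
class CohortParams:
    """Simulation parameters; defaults are the study conditions."""

    n_patients: int = 1000
    p_exceptional: float = 0.05
    mu_std: float = 8.0  # months
    sigma_std: float = 1.0
    mu_exc: float = 11.0
    sigma_exc: float = 1.0
    study_months: int = 48
    start_window_months: int = 6
    days_per_month: int = 30
    weight_mean: float = 75.0  # kg, truncated to [40, 150]
    weight_sd: float = 10.0
    weight_min: float = 40.0
    weight_max: float = 150.0
    dose_mean: float = 2.5  # mg/kg, truncated to (0, 6]
    dose_sd: float = 0.5
    dose_max: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.p_exceptional <= 1.0:
            raise ValueError("p_exceptional must lie in [0, 1]")
        for name in ("sigma_std", "sigma_exc", "weight_sd", "dose_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mu_std <= 0 or self.mu_exc <= 0:
            raise ValueError("mean survivals must be positive")
        if self.study_months < self.start_window_months:
            raise ValueError("study_months must cover the start window")
        if self.days_per_month < 1:
            raise ValueError("days_per_month must be positive")


@dataclass
class PatientRecord:
    patient_id: str
    start_day: int
    group: str
    survival_days: int
    visit_months: np.ndarray  # 0-based study month indices with a visit
    weight_kg: np.ndarray  # int kg, aligned with visit_months
    dose_mg_per_kg: np.ndarray  # float, multiples of 0.1, aligned
    flag_by_month: np.ndarray | None = None  # (study_months,) 0/1

    @property
    def dose_tenths(self) -> np.ndarray:
        """Dose in fixed-point tenths of mg/kg (exact integers)."""
        return np.rint(self.dose_mg_per_kg * 10).astype(np.int64)

    @property
    def death_day(self) -> int:
        return self.start_day + self.survival_days


@dataclass
class Cohort:
    params: CohortParams
    patients: list[PatientRecord] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def flags_matrix(self) -> np.ndarray:
        """(n_patients, study_months) 0/1 flag matrix."""
        if any(p.flag_by_month is None for p in self.patients):
            raise ValueError("flags not computed; call compute_flags first")
        return np.stack([p.flag_by_month for p in self.patients])

    def survival_days(self) -> np.ndarray:
        return np.array([p.survival_days for p in self.patients])

    def groups(self) -> np.ndarray:
        return np.array([p.group for p in self.patients])


def _truncated_normal(
    rng: np.random.Generator, mean, sd, lo, hi, shape
) -> np.ndarray:
    """Exact rejection sampling from a truncated normal."""
    out = rng.normal(mean, sd, size=shape)
    if sd == 0:
        return np.clip(out, lo, hi)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(params: CohortParams) -> Cohort:
    """Draw a full cohort (groups, survivals, starts, visits, flags).

    Reproducible: the same params (including seed) give an identical
    cohort, and identical CSV output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    dpm = params.days_per_month
    window_days = params.start_window_months * dpm

    exceptional = rng.random(n) < params.p_exceptional
    mu = np.where(exceptional, params.mu_exc, params.mu_std) * dpm
    sigma = np.where(exceptional, params.sigma_exc, params.sigma_std) * dpm
    survival = np.maximum(1, np.rint(rng.normal(mu, sigma))).astype(np.int64)
    start = rng.integers(0, window_days, size=n)

    months = params.study_months
    weights = np.rint(
        _truncated_normal(
            rng,
            params.weight_mean,
            params.weight_sd,
            params.weight_min,
            params.weight_max,
            (n, months),
        )
    ).astype(np.int64)
    # dose truncated to (0, dose_max]; lower edge 0.05 so tenths-rounding
    # never produces a zero dose
    doses = (
        np.rint(
            _truncated_normal(
                rng, params.dose_mean, params.dose_sd, 0.05, params.dose_max, (n, months)
            )
            * 10
        ).astype(np.int64)
        / 10.0
    )

    width = len(str(n - 1))
    patients = []
    month_starts = np.arange(months) * dpm
    for i in range(n):
        death = int(start[i] + survival[i])
        on_study = (month_starts < death) & (month_starts + dpm > start[i])
        visit = np.nonzero(on_study)[0]
        patients.append(
            PatientRecord(
                patient_id=f"P{str(i).zfill(width)}",
                start_day=int(start[i]),
                group=EXCEPTIONAL if exceptional[i] else STANDARD,
                survival_days=int(survival[i]),
                visit_months=visit,
                weight_kg=weights[i, visit],
                dose_mg_per_kg=doses[i, visit],
            )
        )
    cohort = Cohort(params=params, patients=patients)
    return compute_flags(cohort)


def compute_flags(cohort: Cohort) -> Cohort:
    """Fill per-month responder flags (in place; returns the cohort).

    An exceptional-group patient is flagged from the study month containing
    their death day onward -- the month their unusually long survival has
    been completely observed.  Standard-group flags are all zero.  Flags
    are non-decreasing by construction.
    """
    months = cohort.params.study_months
    dpm = cohort.params.days_per_month
    for p in cohort.patients:
        flags = np.zeros(months, dtype=np.int64)
        if p.group == EXCEPTIONAL:
            fm = p.death_day // dpm
            if fm < months:
                flags[fm:] = 1
        p.flag_by_month = flags
    return cohort


def survival_histogram(
    cohort: Cohort, bin_days: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of survival times in days: (bin_edges, counts)."""
    if bin_days < 1:
        raise ValueError("bin_days must be at least 1")
    surv = cohort.survival_days()
    if surv.size == 0:
        return np.array([0]), np.array([], dtype=np.int64)
    hi = (int(surv.max()) // bin_days + 1) * bin_days
    edges = np.arange(0, hi + bin_days, bin_days)
    counts, _ = np.histogram(surv, bins=edges)
    return edges, counts


# --------------------------------------------------------------------------
# CSV interface: one row per patient-visit-month
# --------------------------------------------------------------------------


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for p in cohort.patients:
        flags = p.flag_by_month
        for j, m in enumerate(p.visit_months):
            rows.append(
                (
                    p.patient_id,
                    p.start_day,
                    p.group,
                    p.survival_days,
                    int(m),
                    int(p.weight_kg[j]),
                    float(p.dose_mg_per_kg[j]),
                    int(flags[m]) if flags is not None else 0,
                )
            )
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path, params: CohortParams | None = None) -> Cohort:
    """Rebuild a Cohort from its CSV serialization.

    The per-study-month flag arrays are reconstructed with the same
    flagging rule used at simulation time, so the roundtrip is lossless.
    Unknown or missing columns are rejected.
    """
    df = pd.read_csv(path)
    if df.empty and df.columns.size == 0:
        raise ValueError(f"{path}: empty cohort file")
    if list(df.columns) != COHORT_CSV_COLUMNS:
        raise ValueError(
            f"{path}: unexpected schema {list(df.columns)}; "
            f"expected {COHORT_CSV_COLUMNS}"
        )
    bad = df["group"].isin([STANDARD, EXCEPTIONAL])
    if not bad.all():
        line = int(np.nonzero(~bad.values)[0][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed group label at line {line}")
    if (df["survival_days"] < 1).any():
        line = int(np.nonzero((df["survival_days"] < 1).values)[0][0]) + 2
        raise ValueError(f"{path}: non-positive survival at line {line}")
    if params is None:
        params = CohortParams(n_patients=df["patient_id"].nunique())
    patients = []
    for pid, g in df.groupby("patient_id", sort=False):
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                start_day=int(g["start_day"].iloc[0]),
                group=str(g["group"].iloc[0]),
                survival_days=int(g["survival_days"].iloc[0]),
                visit_months=g["month_index"].to_numpy(dtype=np.int64),
                weight_kg=g["weight_kg"].to_numpy(dtype=np.int64),
                dose_mg_per_kg=g["dose_mg_per_kg"].to_numpy(dtype=float),
            )
        )
    if params.n_patients != len(patients):
        params = replace(params, n_patients=len(patients))
    return compute_flags(Cohort(params=params, patients=patients))
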