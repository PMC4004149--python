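"""Participant cohort data model, screening, and descriptive surfaces.

A cohort is one row per participant: 14 baseline covariates, the session
index at which the participant dropped out or completed (``event_time``,
1..6), and an event indicator (``event`` = 1 for treatment dropout, 0 for
completion, censored at session 6).  Dropout at session *j* means the
participant finished session *j*-1 but not session *j*.

The 14 covariates are the four EDE-Q subscales (0-6 scale), BMI, three
28-day behaviour frequencies (binge eating, vomiting, excessive exercise),
the four URICA stage-of-change subscales (1-5 scale), the HSCL-25
depression subscale (1-4 scale), and age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical ordering of the 14 baseline predictors.
COVARIATES: tuple[str, ...] = (
    "age",
    "bmi",
    "edeq_restraint",
    "edeq_eating_concerns",
    "edeq_shape_concerns",
    "edeq_weight_concerns",
    "binge_28d",
    "vomit_28d",
    "exercise_28d",
    "urica_precontemplation",
    "urica_contemplation",
    "urica_action",
    "urica_maintenance",
    "hscl_depression",
)

#: Full cohort CSV column order.
SCHEMA: tuple[str, ...] = ("id",) + COVARIATES + ("event_time", "event")

N_SESSIONS = 6

#: Rule-of-thumb minimum events-per-variable for stable unpenalized Cox fits.
RECOMMENDED_EPV = 10.0


class SchemaError(ValueError):
    """The cohort table is missing or misnaming a required column."""


class ValidationError(ValueError):
    """A row violates the cohort invariants."""


class Cohort:
    """Ordered participant table with a fixed covariate schema.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces the
    cohort invariants on construction: ``event_time`` in 1..6, ``event``
    in {0, 1}, censoring only at session 6, all covariates finite.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self._frame, other._frame)
        except AssertionError:
            return False
        return True

    @property
    def event_times(self) -> np.ndarray:
        return self._frame["event_time"].to_numpy(dtype=np.int64)

    @property
    def events(self) -> np.ndarray:
        return self._frame["event"].to_numpy(dtype=np.int64)

    @property
    def n_events(self) -> int:
        return int(self._frame["event"].sum())

    def covariate_matrix(self) -> np.ndarray:
        """n x 14 matrix of covariates on their native scales."""
        return self._frame[list(COVARIATES)].to_numpy(dtype=np.float64)

    def subset(self, indices) -> "Cohort":
        """Row subset / resample by positional indices (bootstrap draws)."""
        return Cohort(self._frame.iloc[np.asarray(indices)].reset_index(drop=True))

    # -- descriptive surface -------------------------------------------------

    def describe(self) -> pd.DataFrame:
        """Per-covariate mean, SD (n-1 denominator), min, and max.

        With a single participant the SD is reported as NaN (undefined).
        """
        if len(self) == 0:
            raise ValidationError("cannot describe an empty cohort")
        rows = {}
        for name in COVARIATES:
            col = self._frame[name]
            rows[name] = {
                "mean": col.mean(),
                "sd": col.std(ddof=1) if len(col) > 1 else np.nan,
                "min": col.min(),
                "max": col.max(),
            }
        return pd.DataFrame.from_dict(rows, orient="index")[
            ["mean", "sd", "min", "max"]
        ]

    def dropout_rate(self) -> float:
        """Overall dropout fraction (events / n)."""
        if len(self) == 0:
            raise ValidationError("empty cohort")
        return self.n_events / len(self)

    # -- standardization -----------------------------------------------------

    def standardize(self) -> tuple[np.ndarray, "StandardScale"]:
        """Column-standardized predictor matrix and the location/scale used.

        Each column of the returned matrix has mean 0 and sample SD 1
        (n-1 denominator).  The returned :class:`StandardScale` lets
        coefficients be mapped between the standardized and native scales.
        """
        X = self.covariate_matrix()
        return standardize_matrix(X, list(COVARIATES))

    def events_per_variable(self, n_predictors: int = len(COVARIATES)):
        """EPV diagnostic: events / predictors, flagged when below 10."""
        return events_per_variable(self.n_events, n_predictors)

    # -- IO ------------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return read_cohort(path)

    def to_csv(self, path) -> None:
        write_cohort(self, path)


@dataclass(frozen=True)
class StandardScale:
    """Per-covariate location/scale pairs from a standardization."""

    names: list[str]
    location: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.location) / self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale + self.location

    def coef_to_native(self, beta_std: np.ndarray) -> np.ndarray:
        """Map log-hazard-ratio coefficients to per-native-unit scale."""
        return beta_std / self.scale


def standardize_matrix(
    X: np.ndarray, names: list[str]
) -> tuple[np.ndarray, StandardScale]:
    X = np.asarray(X, dtype=np.float64)
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    for j, s in enumerate(scale):
        if not np.isfinite(s) or s <= 0:
            raise ValidationError(
                f"covariate {names[j]!r} is constant; cannot standardize"
            )
    return (X - loc) / scale, StandardScale(list(names), loc, scale)


def events_per_variable(n_events: int, n_predictors: int) -> tuple[float, bool]:
    """Events-per-variable ratio and a below-recommended flag.

    Returns ``(ratio, below)`` where ``below`` is True when the ratio is
    under the conventional minimum of 10 events per predictor.
    """
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    ratio = n_events / n_predictors
    return ratio, ratio < RECOMMENDED_EPV


# -- CSV round trip ----------------------------------------------------------


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    for col in SCHEMA:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    frame = frame[list(SCHEMA)].copy().reset_index(drop=True)
    frame["id"] = frame["id"].astype(str)
    for col in COVARIATES:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals.to_numpy(dtype=np.float64))]
        if len(bad):
            raise ValidationError(
                f"row {bad[0]}: covariate {col!r} is missing or non-numeric"
            )
        frame[col] = vals.astype(np.float64)
    for col in ("event_time", "event"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        arr = vals.to_numpy(dtype=np.float64)
        bad = vals.index[~np.isfinite(arr) | (arr != np.floor(arr))]
        if len(bad):
            raise ValidationError(f"row {bad[0]}: {col!r} must be an integer")
        frame[col] = vals.astype(np.int64)
    et = frame["event_time"].to_numpy()
    ev = frame["event"].to_numpy()
    bad = np.nonzero((et < 1) | (et > N_SESSIONS))[0]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: event_time {et[bad[0]]} outside 1..{N_SESSIONS}"
        )
    bad = np.nonzero((ev != 0) & (ev != 1))[0]
    if len(bad):
        raise ValidationError(f"row {bad[0]}: event must be 0 or 1")
    bad = np.nonzero((ev == 0) & (et != N_SESSIONS))[0]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: censored record must have event_time {N_SESSIONS}"
        )
    return frame


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (schema-checked, row-validated)."""
    frame = pd.read_csv(path, dtype={"id": str})
    return Cohort(frame)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV in the canonical column order."""
    cohort.frame.to_csv(path, index=False)


def cohort_from_arrays(
    X: np.ndarray,
    event_times: np.ndarray,
    events: np.ndarray,
    ids=None,
) -> Cohort:
    """Assemble a Cohort from a native-scale covariate matrix and outcomes."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if ids is None:
        ids = [f"p{i + 1:04d}" for i in range(n)]
    frame = pd.DataFrame(X, columns=list(COVARIATES))
    frame.insert(0, "id", list(ids))
    frame["event_time"] = np.asarray(event_times, dtype=np.int64)
    frame["event"] = np.asarray(events, dtype=np.int64)
    return Cohort(frame)


# -- eligibility screening ---------------------------------------------------


@dataclass
class ScreeningRecord:
    """Self-report screening battery summary for one applicant."""

    gender: str
    weekly_purging: bool
    weekly_dieting: bool
    weekly_excessive_exercise: bool
    binge_only_no_compensation: bool
    bmi: float
    cesd: float
    suicide_risk: bool
    severe_self_harm: bool
    psychosis_screen: float
    sdq: float
    audit: float
    dudit: float
    in_current_psychotherapy: bool


@dataclass
class EligibilityDecision:
    eligible: bool
    reasons: list[str] = field(default_factory=list)


#: Machine-readable screening failure codes, in rule order.
REASON_CODES = (
    "not_female",
    "no_weekly_symptom",
    "binge_only",
    "bmi_out_of_range",
    "severe_depression",
    "suicide_risk",
    "severe_self_harm",
    "psychosis",
    "dissociative_symptoms",
    "alcohol_use",
    "drug_use",
    "in_psychotherapy",
)


def screen_eligibility(record: ScreeningRecord) -> EligibilityDecision:
    """Apply the trial's inclusion/exclusion rules to one screening record.

    Inclusion requires female gender, at least one weekly compensatory or
    restrictive symptom (purging, dieting, or excessive exercise at least
    once per week over the past 4 weeks), and a self-reported BMI strictly
    between 15 and 30 kg/m^2.  Exclusions: binge eating without any
    compensatory behaviour, severe depression (CES-D >= 35), suicide risk,
    severe self-harm, a psychosis screen of 13 or more, a Somatoform
    Dissociation score above 8, AUDIT or DUDIT of 10 or more, and being in
    current psychotherapy.  The decision always lists every failed rule.
    """
    reasons = []
    if record.gender.strip().lower() != "female":
        reasons.append("not_female")
    if not (
        record.weekly_purging
        or record.weekly_dieting
        or record.weekly_excessive_exercise
    ):
        reasons.append("no_weekly_symptom")
    if record.binge_only_no_compensation:
        reasons.append("binge_only")
    if not (15.0 < record.bmi < 30.0):
        reasons.append("bmi_out_of_range")
    if record.cesd >= 35.0:
        reasons.append("severe_depression")
    if record.suicide_risk:
        reasons.append("suicide_risk")
    if record.severe_self_harm:
        reasons.append("severe_self_harm")
    if record.psychosis_screen >= 13.0:
        reasons.append("psychosis")
    if record.sdq > 8.0:
        reasons.append("dissociative_symptoms")
    if record.audit >= 10.0:
        reasons.append("alcohol_use")
    if record.dudit >= 10.0:
        reasons.append("drug_use")
    if record.in_current_psychotherapy:
        reasons.append("in_psychotherapy")
    return EligibilityDecision(eligible=not reasons, reasons=reasons)


def screen_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Screen a flat table of applicants; adds eligible/reasons columns."""
    bool_cols = [
        "weekly_purging",
        "weekly_dieting",
        "weekly_excessive_exercise",
        "binge_only_no_compensation",
        "suicide_risk",
        "severe_self_harm",
        "in_current_psychotherapy",
    ]
    out = frame.copy()
    eligible = []
    reasons = []
    for _, row in frame.iterrows():
        rec = ScreeningRecord(
            gender=str(row["gender"]),
            bmi=float(row["bmi"]),
            cesd=float(row["cesd"]),
            psychosis_screen=float(row["psychosis_screen"]),
            sdq=float(row["sdq"]),
            audit=float(row["audit"]),
            dudit=float(row["dudit"]),
            **{c: bool(row[c]) for c in bool_cols},
        )
        dec = screen_eligibility(rec)
        eligible.append(dec.eligible)
        reasons.append(";".join(dec.reasons))
    out["eligible"] = eligible
    out["reasons"] = reasons
    return out
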