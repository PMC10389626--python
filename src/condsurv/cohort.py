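"""Patient cohorts: records, delimited-text I/O, and characteristics tables.

A cohort holds one row per patient who survived at least one year after
esophagectomy.  Follow-up time is stored on the *landmark* scale: years since
the 1-year post-surgery anniversary, so every time is > 0 and at most the
administrative cap (default 4 landmark-years = 5 post-surgery years).
Event codes: 0 censored, 1 death from esophageal cancer, 2 death from any
other cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

SEX_LEVELS = ("male", "female")
YESNO_LEVELS = ("no", "yes")
CCI_LEVELS = ("0", "1", "2+")
HISTOLOGY_LEVELS = ("adenocarcinoma", "squamous_cell_carcinoma")
STAGE_LEVELS = ("0-i", "ii", "iii", "iv")
MARGIN_LEVELS = ("r0", "r1r2")
TIME_SCALES = ("landmark", "post_surgery")

#: default administrative censoring cap, landmark-years (5 post-surgery years)
DEFAULT_CAP = 4.0
DEFAULT_AGE_BOUNDS = (18.0, 100.0)

# canonical column order of the cohort CSV dialect
CSV_COLUMNS = (
    "patient_id", "age", "sex", "education_gt12", "cci_class", "histology",
    "chemoradiotherapy", "stage", "margin", "reoperation_30d",
    "time_years", "time_scale_hint", "event",
)

_CATEGORICALS: Mapping[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "education_gt12": YESNO_LEVELS,
    "cci": CCI_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "chemoradiotherapy": YESNO_LEVELS,
    "stage": STAGE_LEVELS,
    "margin": MARGIN_LEVELS,
    "reoperation_30d": YESNO_LEVELS,
}


class CohortSchemaError(ValueError):
    """Raised when a cohort file lacks a required column."""


class CohortValidationError(ValueError):
    """Raised when one or more rows violate the record invariants.

    ``errors`` is a list of ``(row_number, message)`` pairs; row numbers are
    1-based data rows (header excluded).
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {r}: {m}" for r, m in errors[:20])
        more = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{len(errors)} invalid row(s): {lines}{more}")


@dataclass
class PatientRecord:
    """One subject: covariates plus landmark-scale follow-up and event type."""

    patient_id: str
    age: float
    sex: str
    education_gt12: str
    comorbidity: str            # Charlson class: "0", "1", "2+"
    histology: str
    chemoradiotherapy: str
    stage: str                  # "0-i", "ii", "iii", "iv"
    margin: str                 # "r0", "r1r2"
    reoperation_30d: str
    time: float                 # landmark-years at event/censoring, > 0
    event: int                  # 0 censored, 1 cancer death, 2 other death
    extras: dict[str, float] = field(default_factory=dict)


def _record_errors(rec: Mapping, cap: float, age_bounds: tuple[float, float]) -> list[str]:
    errs: list[str] = []
    try:
        age = float(rec["age"])
        if not (age_bounds[0] <= age <= age_bounds[1]):
            errs.append(f"age {age} outside [{age_bounds[0]}, {age_bounds[1]}]")
    except (TypeError, ValueError):
        errs.append(f"unparseable age {rec['age']!r}")
    for col, levels in _CATEGORICALS.items():
        val = rec[col]
        if val not in levels:
            errs.append(f"{col}={val!r} not in {levels}")
    try:
        t = float(rec["time"])
        if not (0.0 < t <= cap + 1e-9):
            errs.append(f"time {t} outside (0, {cap}]")
    except (TypeError, ValueError):
        errs.append(f"unparseable time {rec['time']!r}")
    try:
        ev = int(rec["event"])
        if ev not in (0, 1, 2):
            errs.append(f"event={ev} not in {{0,1,2}}")
    except (TypeError, ValueError):
        errs.append(f"unparseable event {rec['event']!r}")
    return errs


@dataclass
class Cohort:
    """An ordered collection of patients backed by a pandas DataFrame.

    Internal columns: patient_id, age, sex, education_gt12, cci, histology,
    chemoradiotherapy, stage, margin, reoperation_30d, time, event, plus any
    extra numeric covariates (used e.g. for simulated predictors).
    """

    table: pd.DataFrame
    label: str = "cohort"
    cap: float = DEFAULT_CAP

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.to_records())

    @property
    def extra_columns(self) -> tuple[str, ...]:
        base = {"patient_id", "age", "sex", "education_gt12", "cci", "histology",
                "chemoradiotherapy", "stage", "margin", "reoperation_30d",
                "time", "event"}
        return tuple(c for c in self.table.columns if c not in base)

    @classmethod
    def from_table(cls, table: pd.DataFrame, label: str = "cohort",
                   cap: float = DEFAULT_CAP,
                   age_bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS,
                   on_invalid: str = "raise") -> "Cohort":
        """Validate a raw table and build a cohort.

        ``on_invalid``: "raise" (default) raises :class:`CohortValidationError`
        listing all offending rows; "drop" removes them.
        """
        table = table.reset_index(drop=True)
        errors: list[tuple[int, str]] = []
        for i, rec in enumerate(table.to_dict("records")):
            for msg in _record_errors(rec, cap, age_bounds):
                errors.append((i + 1, msg))
        if errors:
            if on_invalid == "drop":
                bad = {r - 1 for r, _ in errors}
                table = table.drop(index=sorted(bad)).reset_index(drop=True)
            else:
                raise CohortValidationError(errors)
        ids = table["patient_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortValidationError([(0, f"duplicate patient_id {dup!r}")])
        out = table.copy()
        out["patient_id"] = ids
        out["age"] = out["age"].astype(float)
        out["time"] = out["time"].astype(float)
        out["event"] = out["event"].astype(int)
        return cls(out, label=label, cap=cap)

    @classmethod
    def from_records(cls, records: list[PatientRecord], label: str = "cohort",
                     cap: float = DEFAULT_CAP) -> "Cohort":
        rows = []
        for r in records:
            row = {
                "patient_id": r.patient_id, "age": r.age, "sex": r.sex,
                "education_gt12": r.education_gt12, "cci": r.comorbidity,
                "histology": r.histology,
                "chemoradiotherapy": r.chemoradiotherapy, "stage": r.stage,
                "margin": r.margin, "reoperation_30d": r.reoperation_30d,
                "time": r.time, "event": r.event,
            }
            row.update(r.extras)
            rows.append(row)
        return cls.from_table(pd.DataFrame(rows), label=label, cap=cap)

    def to_records(self) -> list[PatientRecord]:
        extras = self.extra_columns
        recs = []
        for rec in self.table.to_dict("records"):
            recs.append(PatientRecord(
                patient_id=rec["patient_id"], age=rec["age"], sex=rec["sex"],
                education_gt12=rec["education_gt12"], comorbidity=rec["cci"],
                histology=rec["histology"],
                chemoradiotherapy=rec["chemoradiotherapy"], stage=rec["stage"],
                margin=rec["margin"], reoperation_30d=rec["reoperation_30d"],
                time=rec["time"], event=rec["event"],
                extras={c: rec[c] for c in extras},
            ))
        return recs

    def subset(self, idx, label: str | None = None) -> "Cohort":
        """Row subset / resample by integer positions (no re-validation)."""
        sub = self.table.iloc[np.asarray(idx)].reset_index(drop=True)
        return Cohort(sub, label=label or self.label, cap=self.cap)


def read_cohort(path, time_scale: str = "landmark", label: str | None = None,
                cap: float = DEFAULT_CAP,
                age_bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS,
                on_invalid: str = "raise") -> Cohort:
    """Read a cohort CSV in the canonical dialect.

    Required columns: patient_id, age, sex, histology, chemoradiotherapy,
    stage, margin, reoperation_30d, time_years, event; education as either
    education_gt12 (no/yes) or education_years (numeric, collapsed to >12);
    comorbidity as cci_class.  Times are interpreted on ``time_scale``
    ("landmark" or "post_surgery"); a constant ``time_scale_hint`` column, if
    present, overrides the argument.  Post-surgery times are shifted by −1 to
    the landmark origin.  Any extra numeric columns are carried along.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    required = ["patient_id", "age", "sex", "cci_class", "histology",
                "chemoradiotherapy", "stage", "margin", "reoperation_30d",
                "time_years", "event"]
    missing = [c for c in required if c not in raw.columns]
    if "education_gt12" not in raw.columns and "education_years" not in raw.columns:
        missing.append("education_gt12 (or education_years)")
    if missing:
        raise CohortSchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}")

    df = pd.DataFrame({"patient_id": raw["patient_id"]})
    df["age"] = pd.to_numeric(raw["age"], errors="coerce")
    df["sex"] = raw["sex"].str.strip().str.lower()
    if "education_gt12" in raw.columns:
        df["education_gt12"] = raw["education_gt12"].str.strip().str.lower()
    else:
        years = pd.to_numeric(raw["education_years"], errors="coerce")
        df["education_gt12"] = np.where(years > 12, "yes", "no")
        df.loc[years.isna(), "education_gt12"] = "invalid"
    df["cci"] = raw["cci_class"].str.strip()
    for col in ("histology", "chemoradiotherapy", "stage", "margin",
                "reoperation_30d"):
        df[col] = raw[col].str.strip().str.lower()

    if "time_scale_hint" in raw.columns:
        hints = raw["time_scale_hint"].str.strip().str.lower().unique()
        if len(hints) != 1 or hints[0] not in TIME_SCALES:
            raise CohortSchemaError(
                f"{path.name}: time_scale_hint must be constant and one of "
                f"{TIME_SCALES}, got {list(hints)}")
        time_scale = hints[0]
    if time_scale not in TIME_SCALES:
        raise ValueError(f"time_scale must be one of {TIME_SCALES}")

    t = pd.to_numeric(raw["time_years"], errors="coerce")
    if time_scale == "post_surgery":
        t = t - 1.0
    df["time"] = t
    df["event"] = pd.to_numeric(raw["event"], errors="coerce")

    known = set(CSV_COLUMNS) | {"education_years"}
    for col in raw.columns:
        if col not in known:
            df[col] = pd.to_numeric(raw[col], errors="coerce")

    # integer-ize the event column where parseable so validation messages are clean
    ev = df["event"]
    df["event"] = ev.where(ev.isna(), ev.fillna(-1)).astype("float")
    bad_event = df["event"].notna() & (df["event"] % 1 != 0)
    df.loc[bad_event, "event"] = -1
    df["event"] = df["event"].fillna(-1).astype(int)

    return Cohort.from_table(df, label=label or path.stem, cap=cap,
                             age_bounds=age_bounds, on_invalid=on_invalid)


def write_cohort(cohort: Cohort, path) -> Path:
    """Write the canonical CSV dialect (landmark time scale)."""
    path = Path(path)
    df = cohort.table
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "age": df["age"],
        "sex": df["sex"],
        "education_gt12": df["education_gt12"],
        "cci_class": df["cci"],
        "histology": df["histology"],
        "chemoradiotherapy": df["chemoradiotherapy"],
        "stage": df["stage"],
        "margin": df["margin"],
        "reoperation_30d": df["reoperation_30d"],
        "time_years": df["time"],
        "time_scale_hint": "landmark",
        "event": df["event"],
    })
    for col in cohort.extra_columns:
        out[col] = df[col]
    out.to_csv(path, index=False)
    return path


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Cohort characteristics: category counts/percentages, median (IQR) of
    age and follow-up, and deaths within the follow-up cap.

    Returns a tidy frame with columns characteristic, level, n, percent,
    median, q1, q3 (NaN where not applicable).
    """
    df = cohort.table
    if len(df) == 0:
        raise ValueError("cannot summarize an empty cohort")
    n = len(df)
    rows: list[tuple] = [("total", "", n, 100.0, np.nan, np.nan, np.nan)]

    def quantile_row(name: str, s: pd.Series):
        rows.append((name, "median (IQR)", np.nan, np.nan,
                     float(s.median()), float(s.quantile(0.25)),
                     float(s.quantile(0.75))))

    def cat_rows(name: str, col: str, levels: tuple[str, ...],
                 labels: Mapping[str, str] | None = None):
        for lev in levels:
            c = int((df[col] == lev).sum())
            lab = labels[lev] if labels else lev
            rows.append((name, lab, c, 100.0 * c / n, np.nan, np.nan, np.nan))

    quantile_row("age", df["age"])
    cat_rows("sex", "sex", SEX_LEVELS, {"male": "men", "female": "women"})
    cat_rows("education >12 years", "education_gt12", YESNO_LEVELS)
    cat_rows("charlson comorbidity index", "cci", CCI_LEVELS)
    cat_rows("tumor histology", "histology", HISTOLOGY_LEVELS)
    cat_rows("chemo(radio)therapy", "chemoradiotherapy", YESNO_LEVELS)
    cat_rows("pathological tumor stage", "stage", STAGE_LEVELS)
    cat_rows("resection margin", "margin", MARGIN_LEVELS)
    cat_rows("reoperation within 30 days", "reoperation_30d", YESNO_LEVELS)
    quantile_row("follow-up (landmark-years)", df["time"])

    dead = int((df["event"] > 0).sum())
    dead_ds = int((df["event"] == 1).sum())
    rows.append(("all-cause deaths within cap", "", dead, 100.0 * dead / n,
                 np.nan, np.nan, np.nan))
    rows.append(("disease-specific deaths within cap", "", dead_ds,
                 100.0 * dead_ds / n, np.nan, np.nan, np.nan))

    return pd.DataFrame(rows, columns=["characteristic", "level", "n",
                                       "percent", "median", "q1", "q3"])
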