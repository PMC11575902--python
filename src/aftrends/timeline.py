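"""Patient-day data model, delimited-text I/O, and cohort preprocessing.

A cohort is a list of :class:`PatientTimeline` objects.  Each timeline wraps a
``pandas.DataFrame`` of daily device diagnostics indexed by ``day_offset``
(1-based days since implant) together with the patient's index day, first CVH
day (if any) and censoring day.  Preprocessing follows the cohort protocol:

* the index date is day 22 (the day after a 21-day initialization window);
* missing follow-up days are forward-filled with the last known value;
* patients are excluded if they never show AT/AF burden > 0 on or after the
  index date, or if they have a follow-up gap of >= 30 days;
* follow-up is truncated at 730 days (2 years) and, when a CVH occurs,
  diagnostic records end the day before the event.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DAY_MINUTES, INDEX_LAG_DAYS, PERSISTENT_DAY_MIN

#: canonical daily-diagnostics column order
DAILY_COLUMNS = [
    "patient_id", "day_offset", "af_burden_min", "max_continuous_af_min",
    "activity_min", "vrate_day_bpm", "vrate_night_bpm", "hrv_sd_ms", "observed",
]

#: canonical patient-table column order
PATIENT_COLUMNS = ["patient_id", "indication", "cvh_day", "censor_day"]

VALUE_COLUMNS = DAILY_COLUMNS[2:-1]

MINUTE_COLUMNS = ("af_burden_min", "max_continuous_af_min", "activity_min")

INDICATIONS = ("AF management", "suspected AF", "cryptogenic stroke")

DEFAULT_INDEX_DAY = INDEX_LAG_DAYS + 1  # day 22: first day after the 21-day window
MAX_FOLLOW_UP_DAYS = 730

GAP_EXCLUSION_DAYS = 30

REASON_NO_AF = "no AT/AF day on/after index"
REASON_GAP = f"gap in daily follow-up >= {GAP_EXCLUSION_DAYS} days"


class SchemaError(ValueError):
    """A diagnostics file does not conform to the expected column schema."""


class RangeError(ValueError):
    """A field value is outside its physical range."""


@dataclass
class PatientTimeline:
    """Ordered daily records plus implant/index/event/censor accounting."""

    patient_id: str
    records: pd.DataFrame
    indication: str = "AF management"
    cvh_day: Optional[int] = None
    censor_day: int = MAX_FOLLOW_UP_DAYS
    index_day: int = DEFAULT_INDEX_DAY

    def __post_init__(self) -> None:
        r = self.records
        if len(r):
            days = r["day_offset"].to_numpy()
            if len(days) > 1 and not (np.diff(days) > 0).all():
                if (np.diff(np.sort(days)) == 0).any():
                    raise RangeError(f"{self.patient_id}: duplicate day_offset")
                self.records = r.sort_values("day_offset").reset_index(drop=True)
                days = self.records["day_offset"].to_numpy()
            if days[0] < 1:
                raise RangeError(f"{self.patient_id}: day_offset must be >= 1")

    @property
    def n_days(self) -> int:
        return len(self.records)

    @property
    def last_day(self) -> int:
        return int(self.records["day_offset"].iloc[-1]) if self.n_days else 0

    @property
    def first_day(self) -> int:
        return int(self.records["day_offset"].iloc[0]) if self.n_days else 0

    @property
    def had_event(self) -> bool:
        return self.cvh_day is not None

    def copy(self) -> "PatientTimeline":
        return replace(self, records=self.records.copy())

    def values(self, column: str) -> np.ndarray:
        return self.records[column].to_numpy(dtype=float)


Cohort = list  # a cohort is a list[PatientTimeline]


def make_timeline(patient_id: str,
                  day_offset: np.ndarray,
                  columns: dict[str, np.ndarray],
                  observed: np.ndarray | None = None,
                  **kwargs) -> PatientTimeline:
    """Assemble a timeline from per-day arrays (fast path used by the simulator)."""
    n = len(day_offset)
    data = {"patient_id": np.repeat(patient_id, n), "day_offset": np.asarray(day_offset, dtype=int)}
    for col in VALUE_COLUMNS:
        data[col] = np.asarray(columns[col], dtype=float)
    data["observed"] = np.ones(n, dtype=bool) if observed is None else np.asarray(observed, dtype=bool)
    return PatientTimeline(patient_id=patient_id, records=pd.DataFrame(data), **kwargs)


# ---------------------------------------------------------------------------
# I/O — comma-separated UTF-8 with a header row; optional '#' comment header
# ---------------------------------------------------------------------------

def _validate_daily(df: pd.DataFrame, source: str) -> None:
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing mandatory column(s) {missing}")
    bad_lines: list[str] = []
    for col in MINUTE_COLUMNS:
        vals = df[col]
        out = vals.notna() & ((vals < 0) | (vals > DAY_MINUTES))
        for i in df.index[out]:
            bad_lines.append(f"line {i + 2}: {col}={vals[i]} outside [0, {DAY_MINUTES:g}]")
    for col in ("vrate_day_bpm", "vrate_night_bpm"):
        out = df[col].notna() & (df[col] <= 0)
        for i in df.index[out]:
            bad_lines.append(f"line {i + 2}: {col} must be > 0")
    out = df["hrv_sd_ms"].notna() & (df["hrv_sd_ms"] < 0)
    for i in df.index[out]:
        bad_lines.append(f"line {i + 2}: hrv_sd_ms must be >= 0")
    bad = df["max_continuous_af_min"] > df["af_burden_min"]
    for i in df.index[bad.fillna(False)]:
        bad_lines.append(f"line {i + 2}: max_continuous_af_min exceeds af_burden_min")
    if bad_lines:
        raise RangeError(f"{source}: " + "; ".join(bad_lines[:20]))


def read_daily_diagnostics(daily_path: str | Path,
                           patient_path: str | Path | None = None) -> list[PatientTimeline]:
    """Read a cohort from the delimited-text pair (daily table, patient table).

    When ``patient_path`` is omitted every patient is censored at the last
    recorded day with the default indication.
    """
    daily = pd.read_csv(daily_path, comment="#")
    _validate_daily(daily, str(daily_path))
    daily["observed"] = daily["observed"].astype(bool)

    meta: dict[str, dict] = {}
    if patient_path is not None:
        pt = pd.read_csv(patient_path, comment="#")
        missing = [c for c in PATIENT_COLUMNS if c not in pt.columns]
        if missing:
            raise SchemaError(f"{patient_path}: missing mandatory column(s) {missing}")
        for row in pt.itertuples(index=False):
            cvh = None if pd.isna(row.cvh_day) else int(row.cvh_day)
            meta[str(row.patient_id)] = dict(
                indication=str(row.indication), cvh_day=cvh, censor_day=int(row.censor_day))

    cohort: list[PatientTimeline] = []
    for pid, grp in daily.groupby("patient_id", sort=True):
        grp = grp.reset_index(drop=True)
        m = meta.get(str(pid), {})
        cohort.append(PatientTimeline(
            patient_id=str(pid),
            records=grp[DAILY_COLUMNS].copy(),
            indication=m.get("indication", "AF management"),
            cvh_day=m.get("cvh_day"),
            censor_day=m.get("censor_day", int(grp["day_offset"].max()) if len(grp) else 0),
        ))
    return cohort


def write_cohort(cohort: Sequence[PatientTimeline],
                 daily_path: str | Path,
                 patient_path: str | Path,
                 header_comment: str | None = None) -> None:
    """Write the cohort as the canonical delimited-text pair."""
    frames = [tl.records[DAILY_COLUMNS] for tl in cohort if tl.n_days]
    daily = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=DAILY_COLUMNS)
    pt = pd.DataFrame({
        "patient_id": [tl.patient_id for tl in cohort],
        "indication": [tl.indication for tl in cohort],
        "cvh_day": [tl.cvh_day if tl.cvh_day is not None else "" for tl in cohort],
        "censor_day": [tl.censor_day for tl in cohort],
    })
    for path, frame in ((daily_path, daily), (patient_path, pt)):
        buf = io.StringIO()
        if header_comment:
            buf.write(f"# {header_comment}\n")
        frame.to_csv(buf, index=False, float_format="%.6g")
        Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def forward_fill(tl: PatientTimeline, end_day: int | None = None) -> PatientTimeline:
    """Impute unobserved days by carrying the last known value forward.

    Missing rows and rows flagged unobserved both count as gaps.  The filled
    timeline covers every day from the first record through ``end_day``
    (default: the later of the last record day and the follow-up end).
    Imputed days keep ``observed == False``.  Idempotent.
    """
    if tl.n_days == 0:
        return tl.copy()
    if end_day is None:
        end_day = tl.cvh_day - 1 if tl.cvh_day is not None else tl.censor_day
        end_day = max(end_day, tl.last_day)
    days = tl.values("day_offset").astype(int)
    observed = tl.records["observed"].to_numpy(dtype=bool)
    if (end_day == tl.last_day and observed.all()
            and len(days) == tl.last_day - tl.first_day + 1):
        return replace(tl)  # already contiguous and fully observed
    rec = tl.records.set_index("day_offset")
    first = int(rec.index[0])
    if not bool(rec["observed"].iloc[0]) or rec[VALUE_COLUMNS].iloc[0].isna().any():
        raise ValueError(f"{tl.patient_id}: gap precedes the first observation; nothing to carry")
    full = rec.reindex(range(first, end_day + 1))
    full["patient_id"] = tl.patient_id
    obs = full["observed"].to_numpy()
    full["observed"] = np.where(pd.isna(obs), False, obs).astype(bool)
    # an unobserved row carries no values, so blank it before filling
    full.loc[~full["observed"], VALUE_COLUMNS] = np.nan
    full[VALUE_COLUMNS] = full[VALUE_COLUMNS].ffill()
    full = full.reset_index().rename(columns={"index": "day_offset"})
    return replace(tl, records=full[DAILY_COLUMNS])


def gap_lengths(tl: PatientTimeline) -> list[int]:
    """Lengths of maximal runs of unobserved days (missing rows included)."""
    if tl.n_days == 0:
        return []
    days = tl.values("day_offset").astype(int)
    observed = tl.records["observed"].to_numpy(dtype=bool)
    # project on the full day grid: absent rows are unobserved
    grid = np.zeros(tl.last_day - tl.first_day + 1, dtype=bool)
    grid[days - tl.first_day] = observed
    if grid.all():
        return []
    padded = np.concatenate(([True], grid, [True]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # unobserved runs
    return (ends - starts).tolist()


def apply_inclusion(cohort: Sequence[PatientTimeline],
                    max_days: int = MAX_FOLLOW_UP_DAYS,
                    gap_exclusion: int = GAP_EXCLUSION_DAYS
                    ) -> tuple[list[PatientTimeline], pd.DataFrame]:
    """Apply the cohort inclusion/exclusion rules and truncate follow-up.

    Returns the retained cohort (forward-filled, truncated at ``max_days``,
    records ending the day before any CVH) and an exclusion log with one
    primary reason per dropped patient.
    """
    retained: list[PatientTimeline] = []
    log_rows: list[dict] = []
    for tl in cohort:
        # 2-year truncation first: events past the window count as censoring
        cvh = tl.cvh_day
        censor = min(tl.censor_day, max_days)
        if cvh is not None and cvh > max_days:
            cvh, censor = None, max_days  # event beyond the window counts as censoring
        end = cvh - 1 if cvh is not None else censor
        rec = tl.records
        if tl.last_day > end:
            rec = rec[rec["day_offset"] <= end].reset_index(drop=True)
        tl = replace(tl, cvh_day=cvh, censor_day=censor, records=rec)

        observed = tl.records["observed"].to_numpy(dtype=bool)
        days = tl.values("day_offset").astype(int)
        burden = tl.values("af_burden_min")
        af_ok = bool(np.any(observed & (days >= tl.index_day)
                            & (np.nan_to_num(burden, nan=0.0) > 0))) if len(days) else False
        if not af_ok:
            log_rows.append({"patient_id": tl.patient_id, "reason": REASON_NO_AF})
            continue
        if any(g >= gap_exclusion for g in gap_lengths(tl)):
            log_rows.append({"patient_id": tl.patient_id, "reason": REASON_GAP})
            continue
        retained.append(forward_fill(tl, end_day=end))
    log = pd.DataFrame(log_rows, columns=["patient_id", "reason"])
    return retained, log


def classify_af_phenotype(tl: PatientTimeline,
                          persistent_day_min: float = PERSISTENT_DAY_MIN,
                          run_days: int = 7,
                          detection_floor_min: float = 2.0) -> str:
    """Device-based AF phenotype from records on/after the index date.

    ``persistent`` requires >= 23.5 h (1410 min) of AT/AF on >= 7 consecutive
    days; otherwise any day with >= 2 min of AT/AF makes the patient
    ``paroxysmal``.  A patient with no detected AT/AF violates the cohort
    definition and raises ``ValueError``.
    """
    rec = tl.records[tl.records["day_offset"] >= tl.index_day]
    if rec.empty or not (rec["af_burden_min"] >= detection_floor_min).any():
        raise ValueError(f"{tl.patient_id}: no AT/AF >= {detection_floor_min} min on/after index")
    heavy = (rec["af_burden_min"].to_numpy() >= persistent_day_min).astype(int)
    days = rec["day_offset"].to_numpy(dtype=int)
    run = 0
    prev_day = None
    for day, h in zip(days, heavy):
        run = run + 1 if (h and prev_day == day - 1 and run) else (1 if h else 0)
        prev_day = day
        if run >= run_days:
            return "persistent"
    return "paroxysmal"


def follow_up_summary(cohort: Sequence[PatientTimeline]) -> dict:
    """Cohort-level follow-up accounting (patient-days, means by event status, gaps)."""
    n_days = np.array([tl.n_days for tl in cohort], dtype=int)
    event = np.array([tl.had_event for tl in cohort], dtype=bool)
    gaps = [g for tl in cohort for g in gap_lengths(tl)]
    with_gap = sum(1 for tl in cohort if gap_lengths(tl))
    return {
        "n_patients": len(cohort),
        "total_patient_days": int(n_days.sum()),
        "n_events": int(event.sum()),
        "mean_follow_up_event": float(n_days[event].mean()) if event.any() else float("nan"),
        "mean_follow_up_censored": float(n_days[~event].mean()) if (~event).any() else float("nan"),
        "n_patients_with_gap": int(with_gap),
        "mean_gap_days": float(np.mean(gaps)) if gaps else float("nan"),
    }
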