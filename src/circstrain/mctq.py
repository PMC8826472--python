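"""Munich Chronotype Questionnaire (MCTQ) sleep variables, eligibility and BMI.

Derives mid-sleep on workdays/free days (MSW/MSF), sleep durations, and
social jetlag (SJL) from questionnaire clock times, applies the study's
eligibility rules (no night-shift work in the last 6 months, no alarm use on
work-free days, not underweight), and computes BMI with WHO categorization.

All clock arithmetic is circular on the 24-h clock: sleep episodes may cross
midnight and SJL is the shorter arc between the two mid-sleep points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

URBANIZATION_LEVELS = ("no_electricity", "lt5y", "gt20y", "ge30y", "urban")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

# WHO cutoffs, half-open intervals [low, high)
_BMI_CUTS = {"underweight": (0.0, 18.5), "normal": (18.5, 25.0),
             "overweight": (25.0, 30.0), "obese": (30.0, np.inf)}


class MCTQError(ValueError):
    pass


def parse_clock(value) -> float:
    """'HH:MM' (or a number of hours) -> fractional hours in [0, 24)."""
    if isinstance(value, (int, float, np.floating)):
        h = float(value)
    else:
        parts = str(value).strip().split(":")
        if len(parts) not in (2, 3):
            raise MCTQError(f"bad clock time {value!r}")
        h = int(parts[0]) + int(parts[1]) / 60.0 + (int(parts[2]) / 3600.0 if len(parts) == 3 else 0.0)
    if not np.isfinite(h):
        raise MCTQError(f"bad clock time {value!r}")
    return h % 24.0


def format_clock(hours: float) -> str:
    total = int(round((hours % 24.0) * 60))
    return f"{(total // 60) % 24:02d}:{total % 60:02d}"


def circular_diff_h(a: float, b: float) -> float:
    """Shorter-arc absolute difference between two clock hours."""
    d = abs(a - b) % 24.0
    return min(d, 24.0 - d)


@dataclass
class MCTQRecord:
    subject_id: str
    workdays_per_week: int
    sleep_onset_w: float   # clock hours
    sleep_end_w: float
    sleep_onset_f: float
    sleep_end_f: float
    alarm_workdays: bool
    alarm_free_days: bool
    night_shift_6mo: bool
    outdoor_h_work: float
    outdoor_h_free: float

    def __post_init__(self) -> None:
        for name in ("sleep_onset_w", "sleep_end_w", "sleep_onset_f", "sleep_end_f"):
            setattr(self, name, parse_clock(getattr(self, name)))
        if not 0 <= self.workdays_per_week <= 7:
            raise MCTQError("workdays_per_week must be in 0..7")
        for name in ("outdoor_h_work", "outdoor_h_free"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 24.0:
                raise MCTQError(f"{name} must be in [0, 24], got {v}")


@dataclass
class SleepMetrics:
    subject_id: str
    MSW: float        # clock hours
    MSF: float
    SD_w: float       # hours
    SD_f: float
    SJL_h: float      # absolute, shorter arc
    SJL_gt_1h: bool
    MSFsc: float | None = None   # sleep-debt-corrected MSF (optional)


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str                 # {"F", "M"}
    urbanization: str        # one of URBANIZATION_LEVELS
    height_m: float
    weight_kg: float
    bmi: float
    bmi_category: str
    self_report_flag: bool = False


@dataclass
class Eligibility:
    subject_id: str
    eligible: bool
    reasons: tuple


def _duration(onset: float, end: float) -> float:
    dur = (end - onset) % 24.0
    if dur == 0.0:
        raise MCTQError("degenerate sleep episode: onset equals end")
    return dur


def sleep_metrics(record: MCTQRecord, msf_corrected: bool = False) -> SleepMetrics:
    """MSW/MSF, sleep durations and social jetlag from one MCTQ record.

    Mid-sleep is onset + duration/2 on the circular clock; SJL is reported
    as the absolute shorter-arc difference |MSF - MSW| and additionally
    dichotomized at 1 h, the form used in the regression models.  The plain
    free-day midpoint is the chronotype marker; ``msf_corrected`` also
    fills the sleep-debt-corrected variant
    MSFsc = MSF - (SD_f - SD_week)/2 (applied only when SD_f > SD_w).
    """
    sd_w = _duration(record.sleep_onset_w, record.sleep_end_w)
    sd_f = _duration(record.sleep_onset_f, record.sleep_end_f)
    msw = (record.sleep_onset_w + sd_w / 2.0) % 24.0
    msf = (record.sleep_onset_f + sd_f / 2.0) % 24.0
    sjl = circular_diff_h(msf, msw)
    msfsc = None
    if msf_corrected:
        wd = record.workdays_per_week
        sd_week = (sd_w * wd + sd_f * (7 - wd)) / 7.0
        msfsc = (msf - (sd_f - sd_week) / 2.0) % 24.0 if sd_f > sd_w else msf
    return SleepMetrics(record.subject_id, msw, msf, sd_w, sd_f, sjl,
                        sjl > 1.0, msfsc)


def bmi_categorize(weight_kg: float, height_m: float) -> tuple[float, str]:
    """BMI = weight/height^2 (4 decimals) and its WHO category.

    Categories use half-open intervals: [18.5, 25) normal, [25, 30)
    overweight, >= 30 obese, < 18.5 underweight.
    """
    if not weight_kg > 0:
        raise MCTQError(f"weight must be positive, got {weight_kg}")
    if not 0.5 < height_m < 2.5:
        raise MCTQError(f"implausible height {height_m} m")
    bmi = round(weight_kg / height_m**2, 4)
    for cat, (lo, hi) in _BMI_CUTS.items():
        if lo <= bmi < hi:
            return bmi, cat
    raise MCTQError(f"uncategorizable BMI {bmi}")  # pragma: no cover


def make_subject_record(subject_id, age, sex, urbanization, height_m, weight_kg,
                        self_report_flag=False) -> SubjectRecord:
    if sex not in ("F", "M"):
        raise MCTQError(f"sex must be F or M, got {sex!r}")
    if urbanization not in URBANIZATION_LEVELS:
        raise MCTQError(f"unknown urbanization level {urbanization!r}")
    bmi, cat = bmi_categorize(weight_kg, height_m)
    return SubjectRecord(str(subject_id), float(age), sex, urbanization,
                         float(height_m), float(weight_kg), bmi, cat,
                         bool(self_report_flag))


def apply_exclusions(subject: SubjectRecord, record: MCTQRecord) -> Eligibility:
    """Study eligibility: night-shift work, alarm on free days, underweight."""
    reasons = []
    if record.night_shift_6mo:
        reasons.append("NIGHT_SHIFT")
    if record.alarm_free_days:
        reasons.append("ALARM_FREE")
    if subject.bmi_category == "underweight":
        reasons.append("UNDERWEIGHT")
    return Eligibility(subject.subject_id, not reasons, tuple(reasons))


# ---------------------------------------------------------------------------
# CSV interfaces

MCTQ_COLUMNS = ["subject_id", "workdays_per_week", "sleep_onset_w", "sleep_end_w",
                "alarm_w", "sleep_onset_f", "sleep_end_f", "alarm_f",
                "night_shift_6mo", "outdoor_h_w", "outdoor_h_f"]


def write_mctq_csv(records: Iterable[MCTQRecord], path) -> None:
    rows = [{
        "subject_id": r.subject_id,
        "workdays_per_week": r.workdays_per_week,
        "sleep_onset_w": format_clock(r.sleep_onset_w),
        "sleep_end_w": format_clock(r.sleep_end_w),
        "alarm_w": int(r.alarm_workdays),
        "sleep_onset_f": format_clock(r.sleep_onset_f),
        "sleep_end_f": format_clock(r.sleep_end_f),
        "alarm_f": int(r.alarm_free_days),
        "night_shift_6mo": int(r.night_shift_6mo),
        "outdoor_h_w": r.outdoor_h_work,
        "outdoor_h_f": r.outdoor_h_free,
    } for r in records]
    pd.DataFrame(rows, columns=MCTQ_COLUMNS).to_csv(path, index=False)


def read_mctq_csv(path) -> list[MCTQRecord]:
    df = pd.read_csv(path)
    return [MCTQRecord(
        subject_id=str(row.subject_id),
        workdays_per_week=int(row.workdays_per_week),
        sleep_onset_w=row.sleep_onset_w, sleep_end_w=row.sleep_end_w,
        sleep_onset_f=row.sleep_onset_f, sleep_end_f=row.sleep_end_f,
        alarm_workdays=bool(row.alarm_w), alarm_free_days=bool(row.alarm_f),
        night_shift_6mo=bool(row.night_shift_6mo),
        outdoor_h_work=float(row.outdoor_h_w), outdoor_h_free=float(row.outdoor_h_f),
    ) for row in df.itertuples()]


def sleep_table(records: Iterable[MCTQRecord], subjects: dict[str, SubjectRecord]) -> pd.DataFrame:
    """One row per subject: sleep metrics plus eligibility, for sleep.csv."""
    rows = []
    for r in records:
        m = sleep_metrics(r)
        elig = apply_exclusions(subjects[r.subject_id], r)
        rows.append({
            "subject_id": r.subject_id,
            "MSW": format_clock(m.MSW), "MSF": format_clock(m.MSF),
            "SD_w": round(m.SD_w, 4), "SD_f": round(m.SD_f, 4),
            "SJL_h": round(m.SJL_h, 4), "SJL_gt_1h": int(m.SJL_gt_1h),
            "eligible": int(elig.eligible), "reasons": ";".join(elig.reasons),
        })
    return pd.DataFrame(rows)
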