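"""Synthetic cohort generator with known ground truth.

Emulates the study's data: 7+ days of 10-min-epoch wrist actimetry
(activity counts + light in lux) with controllable rhythm fragmentation and
day-to-day stability, non-wear gaps and two device gain regimes; MCTQ sleep
records consistent with each subject's habitual active window; covariates
over five community urbanization levels; and an overweight/obese outcome
drawn from a log-link binary model with designed prevalence ratios, so every
downstream stage (QC, rhythm metrics, sleep variables, regression) has a
recovery test against known truth.

Activity is a two-state (rest/active) schedule: within-day fragmentation is
a Markov bout-toggling process whose switch probability drives intradaily
variability (IV); day-level phase jitter drives down interdaily stability
(IS).  Activity noise is multiplicative lognormal (counts are non-negative
and right-skewed).  The device effect is a pure multiplicative gain on both
channels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mctq import MCTQRecord, SubjectRecord, URBANIZATION_LEVELS, make_subject_record
from .series import EpochSeries, SeriesError

log = logging.getLogger(__name__)

# Urbanization mix of the questionnaire sample (fractions, normalized).
DEFAULT_URBANIZATION_MIX = (0.117, 0.057, 0.333, 0.398, 0.085)

_BMI_RANGES = {"normal": (18.5, 25.0), "overweight": (25.0, 30.0), "obese": (30.0, 40.0)}


@dataclass
class SeriesParams:
    """Parameters of one subject's simulated actimetry recording."""
    n_days: int = 7
    epoch_min: int = 10
    active_onset_h: float = 7.0
    active_offset_h: float = 21.0
    mean_active: float = 200.0   # counts/epoch during active bouts
    mean_rest: float = 10.0
    frag_switch_prob: float = 0.05   # per-epoch bout toggle prob (drives IV)
    phase_jitter_sd_h: float = 0.5   # SD of day-level phase shifts (drives 1-IS)
    noise_cv: float = 0.3            # CV of multiplicative lognormal noise
    light_day_lux: float = 1000.0
    light_night_lux: float = 1.0
    lan_prob: float = 0.1            # light-at-night event prob per night
    nonwear_bouts: int = 0
    nonwear_len_epochs: int = 12
    device: str = "Actiwatch2"
    device_gain: float = 2.0         # applied when device == ActTrust
    mode: str = "square"             # {"square", "cosine", "white_noise"}

    def validate(self) -> None:
        if self.n_days < 1:
            raise SeriesError("n_days must be >= 1")
        if self.epoch_min <= 0 or 1440 % self.epoch_min:
            raise SeriesError("epoch_min must divide 1440")
        if not 0.0 <= self.frag_switch_prob <= 1.0:
            raise SeriesError("frag_switch_prob must be in [0, 1]")
        if self.mean_active <= 0 or self.mean_rest <= 0:
            raise SeriesError("state means must be positive")
        if self.device_gain <= 0:
            raise SeriesError("device_gain must be positive")
        if self.mode not in ("square", "cosine", "white_noise"):
            raise SeriesError(f"unknown mode {self.mode!r}")
        if self.phase_jitter_sd_h < 0 or self.noise_cv < 0:
            raise SeriesError("jitter/noise parameters must be non-negative")


@dataclass
class CohortParams:
    n_subjects: int = 200
    urbanization_mix: tuple = DEFAULT_URBANIZATION_MIX
    true_pr_iv: float = 1.5      # PR per SD of (designed) IV
    true_pr_urban: float = 2.0   # PR for living in the urban category
    true_pr_female: float = 1.5
    baseline_prev: float = 0.10  # outcome prevalence at reference levels
    seed: int = 0
    p_female: float = 0.6
    overweight_split: float = 0.5   # P(overweight | overweight-or-obese)
    n_days: int = 8
    epoch_min: int = 10

    def validate(self) -> None:
        mix = np.asarray(self.urbanization_mix, dtype=float)
        if len(mix) != len(URBANIZATION_LEVELS) or np.any(mix < 0) or mix.sum() <= 0:
            raise ValueError("urbanization_mix must be 5 non-negative proportions")
        for pr in (self.true_pr_iv, self.true_pr_urban, self.true_pr_female):
            if pr <= 0:
                raise ValueError("prevalence ratios must be positive")
        if not 0 < self.baseline_prev < 1:
            raise ValueError("baseline_prev must be in (0, 1)")

    @property
    def mix_normalized(self) -> np.ndarray:
        mix = np.asarray(self.urbanization_mix, dtype=float)
        return mix / mix.sum()


@dataclass
class TruthRecord:
    subject_id: str
    z_iv: float                   # designed standardized IV target
    frag_switch_prob: float
    phase_jitter_sd_h: float
    active_onset_h: float
    active_offset_h: float
    outcome_prob: float
    outcome: int                  # 1 = overweight or obese
    bmi_category: str
    device: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.outcome_prob <= 1.0:
            raise ValueError("outcome probability must be in [0, 1]")


@dataclass
class Cohort:
    params: CohortParams
    subjects: list          # SubjectRecord
    series: list            # EpochSeries
    mctq: list              # MCTQRecord
    truth: list             # TruthRecord


def _lognormal_factor(rng, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size)


def _in_window(hours: np.ndarray, onset: float, offset: float) -> np.ndarray:
    onset, offset = onset % 24.0, offset % 24.0
    if onset <= offset:
        return (hours >= onset) & (hours < offset)
    return (hours >= onset) | (hours < offset)


def simulate_epoch_series(params: SeriesParams, seed: int,
                          start_time="2019-04-01 00:00:00",
                          subject_id: str = "S000") -> EpochSeries:
    """Simulate one actimetry recording; bit-reproducible given the seed."""
    params.validate()
    rng = np.random.default_rng(seed)
    ppd = 1440 // params.epoch_min
    n = params.n_days * ppd
    hours = (np.arange(n) % ppd) * (params.epoch_min / 60.0)
    day_idx = np.arange(n) // ppd

    if params.mode == "white_noise":
        # iid Gaussians offset to non-negative; the variance ratio behind IV
        # is offset-invariant, so the offset is immaterial downstream.
        sd = params.mean_active / 10.0
        activity = params.mean_active + sd * rng.standard_normal(n)
        activity = np.clip(activity, 0.0, None)
        light = params.light_day_lux * _lognormal_factor(rng, 0.5, n)
        active = np.ones(n, dtype=bool)
    else:
        shifts = rng.normal(0.0, params.phase_jitter_sd_h, params.n_days)
        if params.mode == "cosine":
            center = (params.active_onset_h +
                      ((params.active_offset_h - params.active_onset_h) % 24.0) / 2.0) % 24.0
            mesor = (params.mean_active + params.mean_rest) / 2.0
            amp = (params.mean_active - params.mean_rest) / 2.0
            phase = hours - shifts[day_idx]
            base = mesor + amp * np.cos(2.0 * np.pi * (phase - center) / 24.0)
            activity = base * _lognormal_factor(rng, params.noise_cv, n)
            active = base >= mesor
        else:
            active = _in_window(hours - shifts[day_idx], params.active_onset_h,
                                params.active_offset_h)
            # Markov bout displacement: enter a misplaced rest/active bout at
            # frag_switch_prob per epoch, leave at a fixed exit rate so bouts
            # stay short (~30 min); entries drive rest-activity transitions
            # (hence IV) without erasing the underlying daily pattern.
            if params.frag_switch_prob > 0:
                enter = rng.random(n) < params.frag_switch_prob
                exit_ = rng.random(n) < 0.3
                displaced = np.empty(n, dtype=bool)
                state = False
                for i in range(n):
                    state = (not exit_[i]) if state else enter[i]
                    displaced[i] = state
                active = active ^ displaced
            base = np.where(active, params.mean_active, params.mean_rest)
            activity = base * _lognormal_factor(rng, params.noise_cv, n)

        lmed = np.where(active, params.light_day_lux, params.light_night_lux)
        light = lmed * _lognormal_factor(rng, 0.8, n)
        # light-at-night events: brief bright exposure during the rest phase
        for d in range(params.n_days):
            if rng.random() < params.lan_prob:
                rest_idx = np.flatnonzero(~active & (day_idx == d))
                if rest_idx.size:
                    i = rng.choice(rest_idx)
                    length = rng.integers(1, 4)
                    sel = rest_idx[(rest_idx >= i) & (rest_idx < i + length)]
                    light[sel] = params.light_day_lux * _lognormal_factor(rng, 0.5, sel.size)

    wear = np.ones(n, dtype=bool)
    for _ in range(params.nonwear_bouts):
        L = min(params.nonwear_len_epochs, n)
        start = int(rng.integers(0, n - L + 1))
        activity[start:start + L] = 0.0
        light[start:start + L] = 0.0

    if params.device == "ActTrust":
        activity = activity * params.device_gain
        light = light * params.device_gain

    return EpochSeries(subject_id=subject_id, start_time=pd.Timestamp(start_time),
                       epoch_min=params.epoch_min, activity=activity, light=light,
                       wear=wear, device=params.device)


def simulate_mctq(truth: TruthRecord, seed: int, *, workdays_per_week: int = 5,
                  sjl_mean_h: float = 0.75, sjl_sd_h: float = 0.5,
                  alarm_free_rate: float = 0.05, night_shift_rate: float = 0.03,
                  jitter_sd_h: float = 0.3) -> MCTQRecord:
    """MCTQ record consistent with the subject's habitual active window.

    Workday sleep runs from about the active offset to the active onset;
    free-day sleep is shifted later by a subject-level social-jetlag offset.
    Setting ``sjl_mean_h = sjl_sd_h = jitter_sd_h = 0`` yields identical
    work/free schedules and hence SJL = 0 downstream.
    """
    rng = np.random.default_rng(seed)
    onset_w = (truth.active_offset_h + 1.0 + rng.normal(0, jitter_sd_h)) % 24.0
    end_w = (truth.active_onset_h + rng.normal(0, jitter_sd_h)) % 24.0
    shift = rng.normal(sjl_mean_h, sjl_sd_h)
    onset_f = (onset_w + shift) % 24.0
    end_f = (end_w + shift) % 24.0
    return MCTQRecord(
        subject_id=truth.subject_id,
        workdays_per_week=workdays_per_week,
        sleep_onset_w=onset_w, sleep_end_w=end_w,
        sleep_onset_f=onset_f, sleep_end_f=end_f,
        alarm_workdays=bool(rng.random() < 0.7),
        alarm_free_days=bool(rng.random() < alarm_free_rate),
        night_shift_6mo=bool(rng.random() < night_shift_rate),
        outdoor_h_work=float(np.clip(rng.gamma(4.0, 1.0), 0, 16)),
        outdoor_h_free=float(np.clip(rng.gamma(3.0, 1.0), 0, 16)),
    )


def _draw_bmi(rng, category: str) -> tuple[float, float]:
    """(height_m, weight_kg) pair consistent with a BMI category."""
    lo, hi = _BMI_RANGES[category]
    h = float(np.clip(rng.normal(1.65, 0.08), 1.40, 2.00))
    bmi = rng.uniform(lo, hi)
    return h, round(bmi * h * h, 1)


def simulate_cohort(cparams: CohortParams, with_series: bool = True) -> Cohort:
    """Draw a full cohort: covariates, outcome, actimetry, MCTQ, truth.

    Outcome probability follows the log-link model
    ``baseline_prev * pr_iv**z_iv * pr_urban**urban * pr_female**female``
    clipped to [0, 1]; a clipping rate above 5% is logged as a warning.
    Each subject's randomness flows from seed = cohort seed + index, so
    subjects are independently reproducible.  ``with_series=False`` skips
    the (comparatively expensive) actimetry simulation; covariates, truth
    and MCTQ records are unchanged, which keeps large parameter-recovery
    simulations cheap.
    """
    cparams.validate()
    mix = cparams.mix_normalized
    master = np.random.default_rng(cparams.seed)
    subjects, series, mctq_records, truths = [], [], [], []
    n_clipped = 0

    for i in range(cparams.n_subjects):
        sid = f"S{i:04d}"
        srng = np.random.default_rng(cparams.seed + i)
        urb = URBANIZATION_LEVELS[srng.choice(len(mix), p=mix)]
        sex = "F" if srng.random() < cparams.p_female else "M"
        age = float(np.clip(srng.normal(45, 16), 16, 92))
        z_iv = float(srng.standard_normal())
        frag = float(np.clip(0.05 * math.exp(0.4 * z_iv), 0.001, 0.5))
        jitter = float(abs(srng.normal(0.5, 0.3)))

        p = (cparams.baseline_prev
             * cparams.true_pr_iv ** z_iv
             * cparams.true_pr_urban ** (urb == "urban")
             * cparams.true_pr_female ** (sex == "F"))
        if p > 1.0 or p < 0.0:
            n_clipped += 1
        p = float(np.clip(p, 0.0, 1.0))
        y = int(srng.random() < p)
        if y:
            cat = "overweight" if srng.random() < cparams.overweight_split else "obese"
        else:
            cat = "normal"
        height, weight = _draw_bmi(srng, cat)
        # ActTrust was used in the least and most urbanized communities
        device = "ActTrust" if urb in ("no_electricity", "urban") else "Actiwatch2"

        onset = float(srng.normal(7.0, 0.8) % 24.0)
        offset = float(srng.normal(21.0, 0.8) % 24.0)
        truth = TruthRecord(sid, z_iv, frag, jitter, onset, offset, p, y, cat, device)
        sp = SeriesParams(n_days=cparams.n_days, epoch_min=cparams.epoch_min,
                          active_onset_h=onset, active_offset_h=offset,
                          frag_switch_prob=frag, phase_jitter_sd_h=jitter,
                          nonwear_bouts=int(srng.integers(0, 3)), device=device)
        subjects.append(make_subject_record(sid, age, sex, urb, height, weight,
                                            self_report_flag=srng.random() < 0.05))
        if with_series:
            series.append(simulate_epoch_series(sp, cparams.seed + i, subject_id=sid))
        mctq_records.append(simulate_mctq(truth, cparams.seed + i))
        truths.append(truth)

    clip_rate = n_clipped / cparams.n_subjects
    if clip_rate > 0.05:
        log.warning("outcome probability clipped for %.1f%% of subjects", 100 * clip_rate)
    return Cohort(cparams, subjects, series, mctq_records, truths)


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write subjects.csv, mctq.csv, truth.csv and per-subject actimetry CSVs."""
    from .mctq import write_mctq_csv

    outdir = Path(outdir)
    (outdir / "actimetry").mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "subject_id": s.subject_id, "age": round(s.age, 1), "sex": s.sex,
        "urbanization": s.urbanization, "height_m": round(s.height_m, 3),
        "weight_kg": s.weight_kg, "self_report_flag": int(s.self_report_flag),
    } for s in cohort.subjects]).to_csv(outdir / "subjects.csv", index=False)
    write_mctq_csv(cohort.mctq, outdir / "mctq.csv")
    pd.DataFrame([{
        "subject_id": t.subject_id, "z_iv": t.z_iv,
        "frag_switch_prob": t.frag_switch_prob,
        "phase_jitter_sd_h": t.phase_jitter_sd_h,
        "outcome_prob": t.outcome_prob, "outcome": t.outcome,
        "bmi_category": t.bmi_category, "device": t.device,
    } for t in cohort.truth]).to_csv(outdir / "truth.csv", index=False)
    for s in cohort.series:
        s.write_csv(outdir / "actimetry" / f"{s.subject_id}.csv")
    return outdir
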