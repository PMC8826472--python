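"""Cosinor rhythmometry and non-parametric circadian rhythm analysis (NPCRA).

Per subject and channel (activity counts or light), this module computes:

* a single-component 24-h cosinor fit — mesor, amplitude and acrophase
  (clock hour of the fitted peak) via the linear cos/sin parameterization;
* individual and group daily profiles (mean or median per within-day bin);
* the classical non-parametric metrics:

  - IS, interdaily stability: the fraction of total variance explained by
    the average 24-h pattern,
        IS = [N * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2],
    where p is the number of within-day bins, xbar_h the across-day mean of
    bin h and N the number of non-missing epochs; ranges 0-1, with 1 for a
    signal that repeats identically every 24 h;
  - IV, intradaily variability: the normalized mean-square successive
    difference,
        IV = [N * sum (x_i - x_{i-1})^2] / [(N - 1) * sum (x_i - xbar)^2],
    near 0 for a smooth sinusoid and about 2 for white noise; differences
    are taken only across consecutive non-missing pairs and N counts those
    pairs plus one;
  - M10 / L5: the mean over the 10 consecutive highest / 5 consecutive
    lowest hours of the 24-h mean profile, windows wrapping across
    midnight, ties resolved to the earliest onset clock time;
  - RA, relative amplitude: (M10 - L5) / (M10 + L5);
  - for light only, a log-compressed RA
    (log10(M10+10) - log10(L5+10)) / (log10(M10+10) + log10(L5+10)),
    useful because light L5 is often near zero.

IS and IV are invariant under positive affine transforms of the channel, so
they are unaffected by multiplicative device-gain normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .series import EpochSeries

CHANNELS = ("activity", "light")


class MetricError(ValueError):
    """Raised when a rhythm metric is undefined for the given data."""


@dataclass
class CosinorFit:
    channel: str
    mesor: float
    amplitude: float
    acrophase_h: float   # clock hour of the fitted peak, [0, 24)
    goodness: float      # fraction of variance explained (R^2)


@dataclass
class DailyProfile:
    channel: str
    epoch_min: int
    values: np.ndarray           # one per within-day bin; NaN = undefined
    stat: str                    # {"mean", "median"}
    n_days_contributing: np.ndarray
    sem: Optional[np.ndarray] = None   # bin-wise standard error (group mean profiles)

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.epoch_min

    def bin_hours(self) -> np.ndarray:
        return np.arange(self.bins_per_day) * self.epoch_min / 60.0


@dataclass
class NPCRAResult:
    channel: str
    IS: float
    IV: float
    M10: float
    M10_onset_h: float
    L5: float
    L5_onset_h: float
    RA: float
    RA_log: Optional[float] = None   # light channel only


def _clean(series: EpochSeries, channel: str) -> np.ndarray:
    x = series.channel(channel).copy()
    x[~series.wear] = np.nan
    return x


def fit_cosinor(series: EpochSeries, channel: str = "activity",
                period_h: float = 24.0) -> CosinorFit:
    """Least-squares fit of value = M + A*cos(2*pi*(t - phi)/period).

    Fitted over wear epochs only, via the linear parameterization
    y = M + b_c*cos(wt) + b_s*sin(wt) with t the clock time of each epoch.
    The acrophase is reported as the clock hour of the fitted maximum.
    """
    x = _clean(series, channel)
    obs = ~np.isnan(x)
    t = np.arange(len(x)) * series.epoch_min / 60.0 + (
        series.start_time.hour + series.start_time.minute / 60.0)
    if obs.sum() < 3 or len(np.unique(t[obs])) < 2:
        raise MetricError(f"too few observations to fit cosinor on {channel}")
    w = 2.0 * math.pi / period_h
    X = np.column_stack([np.ones(obs.sum()), np.cos(w * t[obs]), np.sin(w * t[obs])])
    beta, *_ = np.linalg.lstsq(X, x[obs], rcond=None)
    mesor, bc, bs = beta
    amp = math.hypot(bc, bs)
    acro = (math.atan2(bs, bc) / w) % period_h
    resid = x[obs] - X @ beta
    sst = float(((x[obs] - x[obs].mean()) ** 2).sum())
    r2 = 0.0 if sst == 0 else max(0.0, 1.0 - float((resid ** 2).sum()) / sst)
    return CosinorFit(channel, float(mesor), float(amp), float(acro), r2)


def daily_profile(series: EpochSeries, channel: str = "activity",
                  stat: str = "mean") -> DailyProfile:
    """Per within-day-bin mean (or median) across days; empty bins are NaN."""
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be mean or median, got {stat!r}")
    x = _clean(series, channel)
    ppd = series.epochs_per_day
    start_bin = (series.start_time.hour * 60 + series.start_time.minute) // series.epoch_min
    bins = (start_bin + np.arange(len(x))) % ppd
    values = np.full(ppd, np.nan)
    counts = np.zeros(ppd, dtype=int)
    for b in range(ppd):
        v = x[bins == b]
        v = v[~np.isnan(v)]
        counts[b] = v.size
        if v.size:
            values[b] = np.mean(v) if stat == "mean" else np.median(v)
    return DailyProfile(channel, series.epoch_min, values, stat, counts)


def group_profile(profiles: Iterable[DailyProfile], stat: str = "median") -> DailyProfile:
    """Bin-wise stat across subjects' individual profiles.

    Mean group profiles also carry the bin-wise standard error across
    subjects, used for the shaded band in group-profile plots.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    epoch_min = profiles[0].epoch_min
    channel = profiles[0].channel
    if any(p.epoch_min != epoch_min or p.channel != channel for p in profiles):
        raise ValueError("profiles must share epoch_min and channel")
    mat = np.vstack([p.values for p in profiles])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # bins with n=1
        vals = np.nanmean(mat, axis=0) if stat == "mean" else np.nanmedian(mat, axis=0)
        n = (~np.isnan(mat)).sum(axis=0)
        sem = None
        if stat == "mean":
            sd = np.nanstd(mat, axis=0, ddof=1)
            sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return DailyProfile(channel, epoch_min, vals, stat, n, sem)


def interdaily_stability(series: EpochSeries, channel: str = "activity",
                         min_coverage: float = 0.8) -> float:
    x = _clean(series, channel)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < len(x) * min_coverage:
        raise MetricError(f"IS needs >= {min_coverage:.0%} coverage, have {n}/{len(x)}")
    if len(x) < 2 * series.epochs_per_day:
        raise MetricError("IS needs at least 2 days of data")
    xbar = x[obs].mean()
    sst = float(((x[obs] - xbar) ** 2).sum())
    if sst == 0:
        raise MetricError("IS undefined for a constant series")
    prof = daily_profile(series, channel, stat="mean").values
    p = series.epochs_per_day
    hour_term = float(np.nansum((prof - xbar) ** 2))
    return n * hour_term / (p * sst)


def intradaily_variability(series: EpochSeries, channel: str = "activity",
                           min_coverage: float = 0.8) -> float:
    x = _clean(series, channel)
    obs = ~np.isnan(x)
    if obs.sum() < len(x) * min_coverage:
        raise MetricError("IV needs >= 80% coverage")
    pair = obs[1:] & obs[:-1]
    n_pairs = int(pair.sum())
    if n_pairs < 1:
        raise MetricError("IV needs at least one consecutive non-missing pair")
    diffs = (x[1:] - x[:-1])[pair]
    xbar = x[obs].mean()
    sst = float(((x[obs] - xbar) ** 2).sum())
    if sst == 0:
        raise MetricError("IV undefined for a constant series")
    n = n_pairs + 1   # epochs entering the successive-difference chain
    return n * float((diffs ** 2).sum()) / ((n - 1) * sst)


def m10_l5(profile: DailyProfile) -> tuple[float, float, float, float]:
    """(M10, M10 onset hour, L5, L5 onset hour) from a mean daily profile.

    Exhaustive scan over all circular windows of 10 h (resp. 5 h) at
    profile resolution; undefined bins are imputed with the profile mean
    (the caller is expected to log this); ties go to the earliest onset.
    """
    if profile.stat != "mean":
        raise ValueError("M10/L5 are defined on the 24-h mean profile")
    vals = profile.values.copy()
    if np.all(np.isnan(vals)):
        raise MetricError("profile fully undefined")
    if np.any(np.isnan(vals)):
        vals[np.isnan(vals)] = np.nanmean(vals)
    ppd = profile.bins_per_day
    w10 = int(round(10 * 60 / profile.epoch_min))
    w5 = int(round(5 * 60 / profile.epoch_min))
    ext = np.concatenate([vals, vals])

    def window_means(w):
        return np.array([ext[i:i + w].mean() for i in range(ppd)])

    m10_means = window_means(w10)
    l5_means = window_means(w5)
    i10 = int(np.argmax(m10_means))        # argmax/argmin take first = earliest onset
    i5 = int(np.argmin(l5_means))
    hrs = profile.epoch_min / 60.0
    return (float(m10_means[i10]), i10 * hrs, float(l5_means[i5]), i5 * hrs)


def relative_amplitude(m10: float, l5: float) -> float:
    if m10 + l5 == 0:
        raise MetricError("RA undefined: M10 + L5 = 0")
    return (m10 - l5) / (m10 + l5)


def log_light_ra(m10: float, l5: float) -> float:
    """Log-compressed relative amplitude for the light channel.

    (log10(M10+10) - log10(L5+10)) / (log10(M10+10) + log10(L5+10));
    defined even at L5 = 0 thanks to the +10 lux offset.
    """
    if m10 < 0 or l5 < 0:
        raise MetricError("M10 and L5 must be non-negative")
    a = math.log10(m10 + 10.0)
    b = math.log10(l5 + 10.0)
    return (a - b) / (a + b)


def npcra(series: EpochSeries, channel: str = "activity",
          hourly: bool = False) -> NPCRAResult:
    """All non-parametric metrics for one channel of one subject.

    ``hourly=True`` rebins to 60-min epochs first, for comparability with
    the classical hourly IS/IV definitions; the default works at the
    analysis resolution (10 min), where IV in particular is systematically
    different.
    """
    if hourly and series.epoch_min != 60:
        from .actio import rebin
        series = rebin(series, 60)
    is_ = interdaily_stability(series, channel)
    iv = intradaily_variability(series, channel)
    prof = daily_profile(series, channel, stat="mean")
    m10, m10_on, l5, l5_on = m10_l5(prof)
    ra = relative_amplitude(m10, l5)
    ra_log = log_light_ra(m10, l5) if channel == "light" else None
    return NPCRAResult(channel, is_, iv, m10, m10_on, l5, l5_on, ra, ra_log)


def subject_rhythms(series: EpochSeries, hourly: bool = False) -> pd.DataFrame:
    """One row per channel: NPCRA metrics plus the cosinor parameters."""
    rows = []
    for channel in CHANNELS:
        r = npcra(series, channel, hourly=hourly)
        c = fit_cosinor(series, channel)
        rows.append({
            "subject_id": series.subject_id, "channel": channel,
            "IS": r.IS, "IV": r.IV, "M10": r.M10, "M10_onset": r.M10_onset_h,
            "L5": r.L5, "L5_onset": r.L5_onset_h, "RA": r.RA,
            "RA_log": r.RA_log if r.RA_log is not None else np.nan,
            "mesor": c.mesor, "amplitude": c.amplitude,
            "acrophase_h": c.acrophase_h, "cosinor_r2": c.goodness,
        })
    return pd.DataFrame(rows)
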