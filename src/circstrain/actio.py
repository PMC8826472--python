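"""Actimetry ingestion and quality control.

Reads raw recordings in two device dialects, rebins to the analysis epoch
(10 min), masks non-wear as runs of consecutive zero-activity epochs,
selects the 7-day analysis window (max 4 h missing per calendar day), and
normalizes the ActTrust channel scale to the Actiwatch-2 reference pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .series import EpochSeries, SeriesError, from_frame


class FormatError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class QCReport:
    subject_id: str
    accepted: bool
    rejection_reason: Optional[str]
    window_start: Optional[pd.Timestamp]
    days_retained: int
    missing_min_per_day: list
    nonwear_runs: int
    nonwear_epochs: int


# ---------------------------------------------------------------------------
# Reading

_DIALECTS = {"acttrust": "ActTrust", "actiwatch2": "Actiwatch2"}


def read_actimetry_csv(path, dialect: str, subject_id: Optional[str] = None) -> EpochSeries:
    """Read a raw device CSV into a contiguous EpochSeries.

    ActTrust files carry DATE/TIME (DD/MM/YYYY HH:MM:SS), PIM and LIGHT
    columns; Actiwatch-2 files carry ISO-8601 timestamp, activity and
    white_light.  Gaps in the timestamp grid are filled with missing epochs.
    """
    key = str(dialect).lower().replace("-", "").replace("_", "")
    if key not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    device = _DIALECTS[key]
    df = pd.read_csv(path)
    try:
        if device == "ActTrust":
            ts = pd.to_datetime(df["DATE/TIME"], format="%d/%m/%Y %H:%M:%S")
            activity = df["PIM"].to_numpy(dtype=float)
            light = df["LIGHT"].to_numpy(dtype=float)
        else:
            ts = pd.to_datetime(df["timestamp"])
            activity = df["activity"].to_numpy(dtype=float)
            light = df["white_light"].to_numpy(dtype=float)
    except KeyError as e:
        raise FormatError(f"missing column {e} for dialect {device}") from e

    deltas = ts.diff().dropna()
    if (deltas <= pd.Timedelta(0)).any():
        row = int(np.flatnonzero((deltas <= pd.Timedelta(0)).to_numpy())[0]) + 1
        raise FormatError(f"non-monotone timestamps at row {row}")
    for name, arr in (("activity", activity), ("light", light)):
        with np.errstate(invalid="ignore"):
            bad = np.flatnonzero(arr < 0)
        if bad.size:
            raise FormatError(f"negative {name} value at row {bad[0]}")

    epoch_min = int(round(deltas.min().total_seconds() / 60.0)) if len(deltas) else 10
    if epoch_min <= 0 or 1440 % epoch_min:
        raise FormatError(f"inferred epoch of {epoch_min} min does not divide a day")
    full = pd.date_range(ts.iloc[0], ts.iloc[-1], freq=f"{epoch_min}min")
    frame = pd.DataFrame({"activity": activity, "light": light}, index=ts).reindex(full)
    sid = subject_id or str(df["subject_id"].iloc[0]) if "subject_id" in df else (subject_id or "unknown")
    return EpochSeries(subject_id=sid, start_time=full[0], epoch_min=epoch_min,
                       activity=frame["activity"].to_numpy(),
                       light=frame["light"].to_numpy(),
                       wear=np.ones(len(full), dtype=bool), device=device)


# ---------------------------------------------------------------------------
# Rebinning

def rebin(series: EpochSeries, target_epoch_min: int) -> EpochSeries:
    """Aggregate to a coarser epoch: activity by sum, light by mean.

    A target bin is missing when more than half of its source epochs are
    missing; otherwise it aggregates the present epochs.
    """
    if target_epoch_min % series.epoch_min:
        raise SeriesError(
            f"target epoch {target_epoch_min} not a multiple of {series.epoch_min}")
    k = target_epoch_min // series.epoch_min
    if k == 1:
        return series.copy()
    n_out = len(series) // k
    act = series.activity[:n_out * k].reshape(n_out, k)
    lig = series.light[:n_out * k].reshape(n_out, k)
    wear = series.wear[:n_out * k].reshape(n_out, k)
    miss = np.isnan(act) | ~wear
    bad = miss.sum(axis=1) > k / 2.0
    with np.errstate(invalid="ignore"):
        act_out = np.nansum(np.where(miss, np.nan, act), axis=1)
        lig_out = np.nanmean(np.where(miss, np.nan, lig), axis=1)
    act_out[bad] = np.nan
    lig_out[bad] = np.nan
    return EpochSeries(series.subject_id, series.start_time, target_epoch_min,
                       act_out, lig_out, ~bad, series.device)


# ---------------------------------------------------------------------------
# Non-wear detection

def zero_runs(activity: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [start, stop) of exactly-zero activity epochs."""
    iszero = np.concatenate(([False], activity == 0.0, [False]))
    d = np.diff(iszero.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_nonwear(series: EpochSeries, min_run: int = 10) -> tuple[EpochSeries, int, int]:
    """Mask runs of >= min_run consecutive zero-activity epochs as non-wear.

    Both channels are set missing across the run (lux from an off-wrist
    device is as invalid as counts).  Returns the masked series plus the
    number of runs and epochs masked.
    """
    out = series.copy()
    n_runs = n_epochs = 0
    for start, stop in zero_runs(out.activity):
        if stop - start >= min_run:
            out.wear[start:stop] = False
            out.activity[start:stop] = np.nan
            out.light[start:stop] = np.nan
            n_runs += 1
            n_epochs += stop - start
    return out, n_runs, n_epochs


# ---------------------------------------------------------------------------
# Analysis-window selection

def select_analysis_window(series: EpochSeries, n_days: int = 7,
                           max_missing_h_per_day: float = 4.0):
    """Earliest run of n_days complete calendar days, each with at most
    ``max_missing_h_per_day`` hours missing.  Day boundaries are local
    midnight.  Returns (EpochSeries, QCReport); the series is None when no
    qualifying window exists.
    """
    ppd = series.epochs_per_day
    t0 = series.start_time
    # first local-midnight-aligned epoch
    first_midnight = t0.normalize() if t0 == t0.normalize() else t0.normalize() + pd.Timedelta(days=1)
    offset = int((first_midnight - t0).total_seconds() // 60) // series.epoch_min
    n_full_days = (len(series) - offset) // ppd

    missing = series.missing()
    miss_min = []
    for d in range(n_full_days):
        sl = slice(offset + d * ppd, offset + (d + 1) * ppd)
        miss_min.append(int(missing[sl].sum()) * series.epoch_min)

    runs = zero_runs(np.nan_to_num(series.activity, nan=1.0))  # informational only
    max_missing_min = max_missing_h_per_day * 60.0
    ok = [m <= max_missing_min for m in miss_min]
    for d0 in range(0, n_full_days - n_days + 1):
        if all(ok[d0:d0 + n_days]):
            sl = slice(offset + d0 * ppd, offset + (d0 + n_days) * ppd)
            win = EpochSeries(series.subject_id, first_midnight + pd.Timedelta(days=d0),
                              series.epoch_min, series.activity[sl].copy(),
                              series.light[sl].copy(), series.wear[sl].copy(),
                              series.device)
            report = QCReport(series.subject_id, True, None, win.start_time, n_days,
                              miss_min[d0:d0 + n_days], len(runs), 0)
            return win, report
    reason = ("TOO_SHORT" if n_full_days < n_days else "NO_QUALIFYING_WINDOW")
    return None, QCReport(series.subject_id, False, reason, None, 0, miss_min,
                          len(runs), 0)


# ---------------------------------------------------------------------------
# Brand normalization

@dataclass
class ChannelReference:
    """Pooled wear-epoch location/scale (and optionally the sorted pool
    values, for quantile mapping) of the reference device pool."""
    mean_activity: float
    sd_activity: float
    mean_light: float
    sd_light: float
    pool_activity: Optional[np.ndarray] = None
    pool_light: Optional[np.ndarray] = None


def reference_stats(series_list: Iterable[EpochSeries],
                    reference_device: str = "Actiwatch2",
                    keep_pool: bool = False) -> ChannelReference:
    acts, ligs = [], []
    for s in series_list:
        if s.device == reference_device:
            acts.append(s.activity[s.wear & ~np.isnan(s.activity)])
            ligs.append(s.light[s.wear & ~np.isnan(s.light)])
    if not acts:
        raise NormalizationError(f"no {reference_device} series to build reference pool")
    a = np.concatenate(acts)
    l = np.concatenate(ligs)
    ref = ChannelReference(float(a.mean()), float(a.std()), float(l.mean()), float(l.std()))
    if ref.sd_activity == 0 or ref.sd_light == 0:
        raise NormalizationError("zero-variance reference channel")
    if keep_pool:
        ref.pool_activity = np.sort(a)
        ref.pool_light = np.sort(l)
    return ref


def normalize_brand(series: EpochSeries, reference: ChannelReference,
                    reference_device: str = "Actiwatch2",
                    mode: str = "mean_sd") -> EpochSeries:
    """Rescale non-reference devices onto the reference pool's scale;
    reference-device series pass through unchanged.

    mode="mean_sd" matches pooled wear-epoch mean and SD linearly (negative
    rescaled values clipped to 0); mode="quantile" maps each value through
    its within-series quantile onto the reference pool's quantile function.
    """
    if series.device == reference_device:
        return series.copy()
    if mode not in ("mean_sd", "quantile"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = series.copy()
    pools = {"activity": reference.pool_activity, "light": reference.pool_light}
    for chan, m_ref, s_ref in (("activity", reference.mean_activity, reference.sd_activity),
                               ("light", reference.mean_light, reference.sd_light)):
        x = out.channel(chan)
        obs = out.wear & ~np.isnan(x)
        if mode == "quantile":
            pool = pools[chan]
            if pool is None:
                raise NormalizationError(
                    "quantile mode needs reference_stats(..., keep_pool=True)")
            q = (rankdata(x[obs]) - 0.5) / obs.sum()
            x[obs] = np.quantile(pool, q)
            continue
        m, s = x[obs].mean(), x[obs].std()
        if s == 0:
            raise NormalizationError(f"zero-variance {chan} channel in {series.subject_id}")
        x[obs] = (x[obs] - m) / s * s_ref + m_ref
        np.clip(x, 0.0, None, out=x)
    return out


def preprocess(series: EpochSeries, epoch_min: int = 10, nonwear_min_run: int = 10,
               n_days: int = 7, max_missing_h: float = 4.0):
    """Full per-subject QC chain: rebin -> non-wear -> window selection."""
    s = rebin(series, epoch_min) if series.epoch_min != epoch_min else series
    s, n_runs, n_masked = detect_nonwear(s, min_run=nonwear_min_run)
    win, report = select_analysis_window(s, n_days=n_days,
                                         max_missing_h_per_day=max_missing_h)
    report.nonwear_runs = n_runs
    report.nonwear_epochs = n_masked
    return win, report
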