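"""Epoch-level actimetry series container and canonical CSV round-trip.

An :class:`EpochSeries` holds one subject's wrist-worn recording: activity
counts and light (lux) on a fixed epoch grid (10 min by default), together
with a wear mask and a device tag.  Missing epochs are NaN in both channels;
``wear=False`` epochs are always missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEVICES = ("ActTrust", "Actiwatch2")


class SeriesError(ValueError):
    """Raised for malformed epoch series or invalid series parameters."""


@dataclass
class EpochSeries:
    subject_id: str
    start_time: pd.Timestamp
    epoch_min: int
    activity: np.ndarray  # float, NaN = missing
    light: np.ndarray     # float lux, NaN = missing
    wear: np.ndarray      # bool
    device: str = "Actiwatch2"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.light = np.asarray(self.light, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if not (len(self.activity) == len(self.light) == len(self.wear)):
            raise SeriesError("activity, light and wear must have equal length")
        if self.epoch_min <= 0 or 1440 % self.epoch_min:
            raise SeriesError(f"epoch_min must divide 1440, got {self.epoch_min}")
        if self.device not in DEVICES:
            raise SeriesError(f"unknown device {self.device!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.activity < 0) or np.any(self.light < 0):
                raise SeriesError("negative activity or light values")
        # wear=False implies both channels missing
        self.activity[~self.wear] = np.nan
        self.light[~self.wear] = np.nan

    def __len__(self) -> int:
        return len(self.activity)

    @property
    def epochs_per_day(self) -> int:
        return 1440 // self.epoch_min

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq=f"{self.epoch_min}min")

    @property
    def clock_hours(self) -> np.ndarray:
        """Hour-of-day (fractional) of each epoch start, in [0, 24)."""
        t = self.times
        return (t.hour + t.minute / 60.0 + t.second / 3600.0).to_numpy()

    def missing(self) -> np.ndarray:
        return np.isnan(self.activity) | ~self.wear

    def copy(self) -> "EpochSeries":
        return replace(
            self,
            activity=self.activity.copy(),
            light=self.light.copy(),
            wear=self.wear.copy(),
        )

    def channel(self, name: str) -> np.ndarray:
        if name == "activity":
            return self.activity
        if name == "light":
            return self.light
        raise SeriesError(f"unknown channel {name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "timestamp": self.times,
                "epoch_min": self.epoch_min,
                "activity": self.activity,
                "light_lux": self.light,
                "wear": self.wear.astype(int),
                "device": self.device,
            }
        )

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(path, index=False)


def from_frame(df: pd.DataFrame) -> EpochSeries:
    """Build an EpochSeries from the canonical internal CSV layout."""
    ts = pd.to_datetime(df["timestamp"])
    epoch_min = int(df["epoch_min"].iloc[0])
    return EpochSeries(
        subject_id=str(df["subject_id"].iloc[0]),
        start_time=ts.iloc[0],
        epoch_min=epoch_min,
        activity=df["activity"].to_numpy(dtype=float),
        light=df["light_lux"].to_numpy(dtype=float),
        wear=df["wear"].to_numpy().astype(bool),
        device=str(df["device"].iloc[0]),
    )


def read_csv(path) -> EpochSeries:
    return from_frame(pd.read_csv(path))
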