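"""In-memory containers for raw traces and labeled epochs, plus their
plain-text (CSV) serializations.

The raw-trace dialect keeps the essential columns of the ActiGraph raw-CSV
export: ISO-8601 timestamp plus x/y/z acceleration in g.  Epoch containers
live on a contiguous 2.5 s grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .kinds import ActivityKind

#: device measurement range in g
DEVICE_RANGE_G = 6.0
#: default sampling rate in Hz
DEFAULT_RATE_HZ = 30.0
#: epoch (frame) length in seconds
EPOCH_SECONDS = 2.5


@dataclass
class AccelTrace:
    """A timestamped triaxial acceleration record.

    Parameters
    ----------
    child_id : str
        Participant identifier.
    start_time : pd.Timestamp
        Time of the first sample.
    samples : ndarray of shape (n, 3)
        Acceleration in g, columns x/y/z, clipped to the device range
        of +/- 6 g.  Samples are equally spaced at ``1/rate`` seconds.
    rate : float
        Sampling rate in Hz (30 by default).
    """

    child_id: str
    start_time: pd.Timestamp
    samples: np.ndarray
    rate: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def timestamps(self) -> pd.DatetimeIndex:
        step = pd.to_timedelta(1.0 / self.rate, unit="s")
        return pd.DatetimeIndex(self.start_time + step * np.arange(self.n_samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps(),
                "x": self.samples[:, 0],
                "y": self.samples[:, 1],
                "z": self.samples[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path, child_id: str = "unknown", rate: float | None = None) -> AccelTrace:
    """Read a raw trace CSV (``timestamp,x,y,z``); infers the rate from the
    first two timestamps unless given."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if rate is None:
        if len(df) < 2:
            rate = DEFAULT_RATE_HZ
        else:
            dt = (df["timestamp"].iloc[1] - df["timestamp"].iloc[0]).total_seconds()
            rate = 1.0 / dt
            # ISO timestamps truncate to microseconds; snap to an
            # integer rate when within rounding distance
            if abs(rate - round(rate)) < 0.01:
                rate = float(round(rate))
    return AccelTrace(
        child_id=child_id,
        start_time=df["timestamp"].iloc[0],
        samples=df[["x", "y", "z"]].to_numpy(float),
        rate=rate,
    )


class EpochFlag(IntEnum):
    """Provenance of an epoch after cleaning."""

    original = 0
    reclassified_to_nonwear = 1
    reclassified_to_sedentary = 2
    outside_wake_window = 3


@dataclass
class LabeledEpochs:
    """One activity label per contiguous 2.5 s epoch."""

    child_id: str
    start_time: pd.Timestamp
    labels: np.ndarray  # int codes of ActivityKind
    epoch_s: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return self.labels.size

    def epoch_starts(self) -> pd.DatetimeIndex:
        step = pd.to_timedelta(self.epoch_s, unit="s")
        return pd.DatetimeIndex(self.start_time + step * np.arange(len(self)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "child_id": self.child_id,
                "epoch_start": self.epoch_starts(),
                "label": [ActivityKind(c).name for c in self.labels],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_epochs_csv(path) -> list[LabeledEpochs]:
    """Read a label CSV (``child_id,epoch_start,label``) into one
    :class:`LabeledEpochs` per child-day (a ``flag`` column, when
    present, yields :class:`CleanedEpochs`)."""
    df = pd.read_csv(path, parse_dates=["epoch_start"])
    has_flags = "flag" in df.columns
    out = []
    for (child, _), grp in df.groupby(
        ["child_id", df["epoch_start"].dt.date], sort=True
    ):
        grp = grp.sort_values("epoch_start")
        codes = np.array([ActivityKind[s].value for s in grp["label"]], dtype=np.int8)
        start = grp["epoch_start"].iloc[0]
        if has_flags:
            flags = np.array([EpochFlag[s].value for s in grp["flag"]], dtype=np.int8)
            out.append(CleanedEpochs(str(child), start, codes, flags=flags))
        else:
            out.append(LabeledEpochs(str(child), start, codes))
    return out


@dataclass
class CleanedEpochs(LabeledEpochs):
    """Labeled epochs plus a per-epoch provenance flag.

    Epochs flagged ``outside_wake_window`` are excluded from every
    downstream duration sum; reclassified epochs keep their new label and
    carry the flag recording the change.
    """

    flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int8))

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.size(self.flags) == 0:
            self.flags = np.zeros(len(self), dtype=np.int8)
        self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.size != self.labels.size:
            raise ValueError("flags and labels must have the same length")

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of epochs inside the wake window."""
        return self.flags != EpochFlag.outside_wake_window

    def to_frame(self) -> pd.DataFrame:
        df = super().to_frame()
        df["flag"] = [EpochFlag(f).name for f in self.flags]
        return df

    @classmethod
    def from_labeled(cls, epochs: LabeledEpochs) -> "CleanedEpochs":
        return cls(
            child_id=epochs.child_id,
            start_time=epochs.start_time,
            labels=epochs.labels.copy(),
            epoch_s=epochs.epoch_s,
            flags=np.zeros(len(epochs), dtype=np.int8),
        )
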