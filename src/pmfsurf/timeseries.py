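"""Per-configuration sampling series: reading, equilibration trimming, block averages.

Each restrained-crystal configuration (x, θz) is sampled by a long MD run
that logs instantaneous observables — at minimum the force component fx and
torque component Tz on the crystal, often also temperature and potential
energy. This module turns one such columnar file into a mean with a block-
averaged standard error, after discarding the equilibration transient.

Block averaging is used because successive MD samples are strongly
correlated; the naive σ/√n underestimates the uncertainty of the mean.
Non-overlapping blocks of ``block_size`` samples are averaged first and the
standard error is computed from the scatter of the block means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, PmfsurfError
from .units import convert_units, dimension_of

__all__ = [
    "TimeSeries",
    "MeanEstimate",
    "Dialect",
    "read_timeseries",
    "trim_equilibration",
    "mean_and_sem",
    "convert_units",
]


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a sampling file.

    ``channels`` maps internal channel names ("fx", "Tz", ...) to column
    headers in the file; ``units`` gives the unit tag of each channel as
    stored on disk.
    """

    time_column: str = "t"
    channels: dict[str, str] = field(
        default_factory=lambda: {"fx": "fx", "Tz": "Tz"}
    )
    units: dict[str, str] = field(
        default_factory=lambda: {"fx": "kcal/mol/A", "Tz": "kcal/mol/rad"}
    )
    time_unit: str = "ps"


@dataclass
class TimeSeries:
    """Named channels sampled on a common, strictly increasing time axis (ps)."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1:
            raise PmfsurfError("time must be one-dimensional")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise PmfsurfError("time must be strictly increasing")
        for name, values in self.channels.items():
            values = np.asarray(values, dtype=float)
            self.channels[name] = values
            if values.shape != self.time.shape:
                raise PmfsurfError(
                    f"channel {name!r} has length {values.size}, time has {self.time.size}"
                )
            if name not in self.units:
                raise PmfsurfError(f"channel {name!r} has no unit tag")
        for name, tag in self.units.items():
            dimension_of(tag)  # raises UnitError on unsupported tags

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class MeanEstimate:
    """Mean of a channel with its block-averaged standard error.

    ``sem`` is NaN when fewer than two complete blocks were available
    (uncertainty undefined; the mean is still meaningful).
    """

    mean: float
    sem: float
    n_samples: int
    block_size: int


def read_timeseries(path, dialect: Dialect | None = None) -> TimeSeries:
    """Read a whitespace/comma separated sampling file with a header row.

    Lines starting with '#' are comments. Column order is irrelevant; the
    ``dialect`` names the time column and maps channel names to headers.
    Rows containing non-numeric fields in any mapped column are dropped.
    """
    import csv as _csv

    dialect = dialect or Dialect()
    try:
        frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, _csv.Error):
        # empty files also defeat the delimiter sniffer
        raise EmptyInputError(f"{path}: no data") from None
    wanted = {dialect.time_column: "time"}
    wanted.update({col: name for name, col in dialect.channels.items()})
    missing = [col for col in wanted if col not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing!r}")
    frame = frame[list(wanted)].apply(pd.to_numeric, errors="coerce").dropna()
    if frame.empty:
        raise EmptyInputError(f"{path}: no numeric rows")
    time = convert_units(1.0, dialect.time_unit, "ps") * frame[dialect.time_column].to_numpy()
    channels = {
        name: frame[col].to_numpy(dtype=float) for name, col in dialect.channels.items()
    }
    return TimeSeries(time=time, channels=channels, units=dict(dialect.units))


def trim_equilibration(ts: TimeSeries, t_start: float) -> TimeSeries:
    """Drop the equilibration transient: keep samples with time >= t_start (ps)."""
    if ts.time.size and t_start > ts.time[-1]:
        raise EmptyInputError(
            f"t_start={t_start} ps is beyond the last sample at {ts.time[-1]} ps"
        )
    keep = ts.time >= t_start
    return TimeSeries(
        time=ts.time[keep],
        channels={name: values[keep] for name, values in ts.channels.items()},
        units=dict(ts.units),
    )


def mean_and_sem(ts: TimeSeries, channel: str, block_size: int = 100) -> MeanEstimate:
    """Arithmetic mean of a channel plus block-averaged standard error.

    The mean is over all samples. For ``block_size > 1`` the samples are cut
    into non-overlapping blocks (trailing partial block discarded) and
    sem = std(block means, ddof=1)/sqrt(n_blocks). ``block_size == 1``
    reduces to the plain σ/√n of the sample.
    """
    if channel not in ts.channels:
        raise PmfsurfError(f"no channel {channel!r}; have {sorted(ts.channels)}")
    if block_size < 1:
        raise PmfsurfError("block_size must be >= 1")
    values = ts.channels[channel]
    n = values.size
    if n == 0:
        raise EmptyInputError("empty series")
    mean = float(np.mean(values))
    if block_size == 1:
        sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return MeanEstimate(mean=mean, sem=sem, n_samples=n, block_size=1)
    n_blocks = n // block_size
    if n_blocks < 2:
        warnings.warn(
            f"only {n_blocks} complete block(s) of {block_size}; "
            "uncertainty undefined, sem reported as NaN",
            stacklevel=2,
        )
        return MeanEstimate(mean=mean, sem=float("nan"), n_samples=n, block_size=block_size)
    blocks = values[: n_blocks * block_size].reshape(n_blocks, block_size)
    block_means = blocks.mean(axis=1)
    sem = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    return MeanEstimate(mean=mean, sem=sem, n_samples=n, block_size=block_size)


def to_internal(estimate: MeanEstimate, unit: str, kind: str) -> MeanEstimate:
    """Convert a MeanEstimate to internal units (kcal/mol/Å or kcal/mol/rad).

    ``kind`` is 'force' or 'torque' and selects the internal target tag.
    """
    target = {"force": "kcal/mol/A", "torque": "kcal/mol/rad"}[kind]
    factor = convert_units(1.0, unit, target)
    return replace(estimate, mean=estimate.mean * factor, sem=estimate.sem * abs(factor))
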