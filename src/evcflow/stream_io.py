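"""Data model, configuration and file I/O for gas-sensor concentration streams.

An online infrared CH4/CO2 analyzer emits one reading per second on each
channel.  Internally every concentration is held in %vol (1 %vol = 10000 ppm)
and snapped to the instrument resolution (default 0.05 %vol = 500 ppm).
Streams travel as delimited text with columns ``t,ch4,co2``; reference
(gas-chromatography) tables as ``sample_id,gas,gc_value``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "CH4",
    "CO2",
    "GASES",
    "AnalyzerConfig",
    "SensorRecord",
    "DataStream",
    "ReferenceTable",
    "StreamFormatError",
    "quantize",
    "read_stream",
    "write_stream",
    "read_references",
    "write_results",
]

CH4 = "CH4"
CO2 = "CO2"
GASES = (CH4, CO2)


class StreamFormatError(ValueError):
    """Raised when an input file violates the stream/reference contract."""


class AnalyzerConfig(BaseModel):
    """Operating parameters of the analyzer and the effective-value model.

    Parameters
    ----------
    c_t:
        Threshold concentration in %vol separating background readings from
        test readings.  The window detector and the value-domain binning are
        both anchored at this level.
    resolution:
        Sensor quantization step in %vol (500 ppm = 0.05 %vol).
    max_multiple:
        Largest bin-width multiple of the resolution tried during the
        optimal-segmentation search.
    min_peak_count:
        The modal bin must contain strictly more than this many readings for
        a segmentation to be accepted.
    quiet_count:
        Number of consecutive sub-threshold readings required immediately
        before a window may open.
    min_window_size:
        Minimum number of records in a valid Data Analysis Window.
    timestamp_offset:
        Seconds added to the window's initial-datum time to produce the
        reported result time (the middle of the sealed test stage).
    vd_max:
        Upper bound on the value-dispersion statistic for a result to pass
        review; contiguous non-empty bins give a dispersion of ~1.
    secondary_min_size:
        Minimum number of above-threshold readings required on the CO2
        channel (which inherits the CH4-detected window) for that channel's
        dataset to be usable.
    """

    c_t: float = Field(default=0.50, gt=0)
    resolution: float = Field(default=0.05, gt=0)
    max_multiple: int = Field(default=20, ge=1)
    min_peak_count: int = Field(default=6, ge=1)
    quiet_count: int = Field(default=100, ge=1)
    min_window_size: int = Field(default=150, ge=1)
    timestamp_offset: float = 135.0
    vd_max: float = Field(default=1.5, gt=0)
    secondary_min_size: int = Field(default=50, ge=1)

    model_config = {"frozen": True}


class SensorRecord(NamedTuple):
    """One timestamped two-channel reading (seconds, %vol, %vol)."""

    t: float
    ch4: float
    co2: float


@dataclass(frozen=True)
class DataStream:
    """An ordered two-channel concentration series (the dynamic dataflow).

    Timestamps must be strictly increasing; concentrations are non-negative
    and, after :func:`quantize`, integer multiples of the resolution.
    """

    t: np.ndarray
    ch4: np.ndarray
    co2: np.ndarray
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ch4 = np.asarray(self.ch4, dtype=float)
        co2 = np.asarray(self.co2, dtype=float)
        if not (len(t) == len(ch4) == len(co2)):
            raise ValueError("channel arrays must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise StreamFormatError(f"non-monotone timestamp at row {bad}")
        if np.any(ch4 < 0) or np.any(co2 < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ch4", ch4)
        object.__setattr__(self, "co2", co2)

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[SensorRecord]:
        for row in zip(self.t, self.ch4, self.co2):
            yield SensorRecord(*row)

    def channel(self, gas: str) -> np.ndarray:
        if gas == CH4:
            return self.ch4
        if gas == CO2:
            return self.co2
        raise ValueError(f"unknown gas {gas!r}")

    def slice(self, start: int, stop: int) -> "DataStream":
        return DataStream(
            self.t[start:stop],
            self.ch4[start:stop],
            self.co2[start:stop],
            self.sample_interval,
        )

    @classmethod
    def from_records(
        cls, records: Iterable[SensorRecord], sample_interval: float = 1.0
    ) -> "DataStream":
        rows = list(records)
        if not rows:
            return cls(np.empty(0), np.empty(0), np.empty(0), sample_interval)
        t, ch4, co2 = (np.array(col, dtype=float) for col in zip(*rows))
        return cls(t, ch4, co2, sample_interval)


@dataclass(frozen=True)
class ReferenceTable:
    """Reference concentrations (e.g. from gas chromatography) per sample/gas."""

    entries: tuple  # of (sample_id, gas, gc_value)

    def __post_init__(self) -> None:
        for sample_id, gas, value in self.entries:
            if gas not in GASES:
                raise ValueError(f"unknown gas {gas!r} for sample {sample_id!r}")
            if not value > 0:
                raise ValueError(
                    f"reference value must be positive (sample {sample_id!r})"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["sample_id", "gas", "gc_value"])


def quantize(values, resolution: float):
    """Snap concentrations to the nearest resolution multiple, half up.

    Scalar in, scalar out; array in, array out.  The tiny epsilon keeps
    exact halves (e.g. 0.075 at a 0.05 step) rounding upward despite binary
    float representation.
    """
    arr = np.asarray(values, dtype=float)
    k = np.floor(arr / resolution + 0.5 + 1e-9)
    out = np.round(k * resolution, 9)
    if np.isscalar(values) or getattr(values, "ndim", 1) == 0:
        return float(out)
    return out


def read_stream(
    path, config: AnalyzerConfig, delimiter: str = ","
) -> DataStream:
    """Read a ``t,ch4,co2`` delimited file into a quantized :class:`DataStream`.

    Rows with missing, non-numeric or negative values and non-monotone
    timestamps fail loudly with the offending row named; silent skipping
    would hide instrument faults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("t", "ch4", "co2"):
        if col not in df.columns:
            raise StreamFormatError(f"missing column {col!r} in {path}")
    parsed = df[["t", "ch4", "co2"]].apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise StreamFormatError(f"non-numeric value at data row {row} of {path}")
    neg = (parsed[["ch4", "co2"]] < 0).any(axis=1)
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise StreamFormatError(f"negative concentration at data row {row} of {path}")
    t = parsed["t"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise StreamFormatError(f"non-monotone timestamp at data row {row} of {path}")
    return DataStream(
        t,
        quantize(parsed["ch4"].to_numpy(), config.resolution),
        quantize(parsed["co2"].to_numpy(), config.resolution),
    )


def write_stream(stream: DataStream, path, delimiter: str = ",") -> None:
    """Write a stream as ``t,ch4,co2`` delimited text."""
    df = pd.DataFrame({"t": stream.t, "ch4": stream.ch4, "co2": stream.co2})
    df.to_csv(path, sep=delimiter, index=False)


def read_references(path, delimiter: str = ",") -> ReferenceTable:
    """Read a ``sample_id,gas,gc_value`` reference table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample_id", "gas", "gc_value"):
        if col not in df.columns:
            raise StreamFormatError(f"missing column {col!r} in {path}")
    entries = tuple(
        (row.sample_id, str(row.gas).upper(), float(row.gc_value))
        for row in df.itertuples()
    )
    return ReferenceTable(entries)


def write_results(results: Sequence, path, delimiter: str = ",") -> None:
    """Write effective-value results as delimited text.

    Columns are ``window_timestamp,gas,effective_value,vd,status`` with a
    bit-stable row order (timestamp, then CH4 before CO2) so repeated runs
    diff cleanly.
    """
    rows = [
        {
            "window_timestamp": r.result_time,
            "gas": r.gas,
            "effective_value": r.value if r.value is not None else math.nan,
            "vd": r.vd if r.vd is not None else math.nan,
            "status": r.status,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows, columns=["window_timestamp", "gas", "effective_value", "vd", "status"]
    )
    if len(df):
        df = df.sort_values(
            ["window_timestamp", "gas"], kind="stable", ignore_index=True
        )
    df.to_csv(path, sep=delimiter, index=False)
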