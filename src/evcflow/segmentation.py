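"""Value-domain segmentation of a window dataset and the OSS statistics.

A window's de-timestamped, ascending value vector ``V1..Vm`` is divided from
the threshold ``c_t`` up to its maximum ``c_max`` into equal-width bins whose
width ``s_i`` is an integer multiple ``i`` of the sensor resolution.  The
search raises ``i`` from 1 until exactly one bin holds the most readings and
that count exceeds ``min_peak_count``; a unique but small mode does not stop
the search.  At the chosen width ``s_0`` each non-empty bin contributes one
entry — its arithmetic mean ``m_c`` and its count ``f_c`` — to the Optimal
Segmentation Statistical Set (OSS), the reduced representation from which the
effective value is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stream_io import AnalyzerConfig

__all__ = [
    "DAWDataset",
    "Segmentation",
    "OSSEntry",
    "OSS",
    "UnresolvableWindowError",
    "partition",
    "find_optimal_segmentation",
    "build_oss",
]

# bin-index arithmetic tolerance: values are resolution multiples with
# magnitudes << 1e6, so 1e-9 never moves a genuinely interior value
_EDGE_EPS = 1e-9


class UnresolvableWindowError(ValueError):
    """No segmentation (or no OSS entry) satisfies the selection rules."""


@dataclass(frozen=True)
class DAWDataset:
    """Sorted above-threshold values of one window on one channel.

    ``values`` ascend, all exceed ``c_t``, and ``c_max`` equals the last
    value.  ``channel_valid`` is False when the channel (CO2, which inherits
    the CH4-detected window) has too few above-threshold readings to analyze.
    """

    values: np.ndarray
    gas: str
    c_t: float
    channel_valid: bool = True

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(vals) and np.any(np.diff(vals) < 0):
            raise ValueError("dataset values must ascend")
        if len(vals) and vals[0] <= self.c_t:
            raise ValueError("dataset values must exceed c_t")
        object.__setattr__(self, "values", vals)

    @property
    def m(self) -> int:
        return len(self.values)

    @property
    def c_max(self) -> float:
        return float(self.values[-1]) if len(self.values) else math.nan


@dataclass(frozen=True)
class Segmentation:
    """Equal-width binning of a dataset at width ``s_i = multiple_i * resolution``.

    Bin ``b`` (0-based) spans ``[c_t + b*s_i, c_t + (b+1)*s_i)``; the final
    bin is closed above so ``c_max`` is always counted.  ``counts`` holds
    ``SN_b`` for every bin including empty ones; their sum equals ``m``.
    """

    multiple_i: int
    s_i: float
    n: int
    c_t: float
    counts: np.ndarray

    @property
    def edges(self) -> np.ndarray:
        return self.c_t + self.s_i * np.arange(self.n + 1)

    @property
    def bins(self) -> list:
        e = self.edges
        return [
            (float(e[b]), float(e[b + 1]), int(c)) for b, c in enumerate(self.counts)
        ]

    @property
    def max_count(self) -> int:
        return int(self.counts.max())

    @property
    def unique_max(self) -> bool:
        return int(np.sum(self.counts == self.counts.max())) == 1


@dataclass(frozen=True)
class OSSEntry:
    """One non-empty bin: arithmetic mean ``m_c``, count ``f_c``, bin index."""

    m_c: float
    f_c: int
    bin_index: int


@dataclass(frozen=True)
class OSS:
    """Optimal Segmentation Statistical Set: non-empty bins at width ``s_0``.

    Entries ascend strictly in ``m_c``; empty bins are absent; counts sum to
    the dataset size.
    """

    entries: tuple
    s_0: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def means(self) -> np.ndarray:
        return np.array([e.m_c for e in self.entries])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.f_c for e in self.entries], dtype=int)


def _bin_indices(values: np.ndarray, c_t: float, s_i: float, n: int) -> np.ndarray:
    idx = np.floor((values - c_t) / s_i + _EDGE_EPS).astype(int)
    # closed final bin: c_max (and only boundary floats) may land on edge n
    return np.minimum(idx, n - 1)


def partition(
    dataset: DAWDataset, multiple_i: int, config: AnalyzerConfig
) -> Segmentation:
    """Bin a dataset at width ``multiple_i * resolution`` anchored at ``c_t``.

    The number of bins is ``ceil((c_max - c_t) / s_i)`` with a floor of 1;
    anchoring at ``c_t`` rather than zero avoids a band of bins below the
    threshold that could never hold data.
    """
    if dataset.m == 0 or not dataset.channel_valid:
        raise ValueError("cannot partition an empty or invalid dataset")
    if not 1 <= multiple_i <= config.max_multiple:
        raise ValueError(f"multiple_i must be in 1..{config.max_multiple}")
    s_i = multiple_i * config.resolution
    span = dataset.c_max - dataset.c_t
    n = max(1, math.ceil(span / s_i - _EDGE_EPS))
    idx = _bin_indices(dataset.values, dataset.c_t, s_i, n)
    counts = np.bincount(idx, minlength=n)
    return Segmentation(multiple_i, s_i, n, dataset.c_t, counts)


def find_optimal_segmentation(
    dataset: DAWDataset, config: AnalyzerConfig
) -> Segmentation:
    """Smallest width whose histogram has a unique mode above ``min_peak_count``.

    Tries ``i = 1 .. max_multiple`` in order and returns the first
    segmentation where exactly one bin attains the maximum count and that
    count strictly exceeds ``config.min_peak_count``.  A unique maximum at or
    below the bound does not stop the search.

    Raises
    ------
    UnresolvableWindowError
        If no width up to ``max_multiple`` qualifies.
    """
    for i in range(1, config.max_multiple + 1):
        seg = partition(dataset, i, config)
        if seg.unique_max and seg.max_count > config.min_peak_count:
            return seg
    raise UnresolvableWindowError(
        f"no segmentation width up to {config.max_multiple}x resolution yields "
        f"a unique mode greater than {config.min_peak_count} "
        f"({dataset.gas}, m={dataset.m})"
    )


def build_oss(dataset: DAWDataset, seg: Segmentation) -> OSS:
    """Collapse each non-empty bin to its (mean, count) OSS entry.

    Works on the sorted value vector: members of one bin occupy a contiguous
    index range ``b_min..b_max``, so ``m_c`` is their running-sum mean and
    ``f_c = b_max - b_min + 1``.  Empty bins contribute nothing.
    """
    idx = _bin_indices(dataset.values, seg.c_t, seg.s_i, seg.n)
    entries = []
    start = 0
    while start < len(idx):
        stop = start
        while stop < len(idx) and idx[stop] == idx[start]:
            stop += 1
        members = dataset.values[start:stop]
        entries.append(
            OSSEntry(
                m_c=float(members.mean()),
                f_c=stop - start,
                bin_index=int(idx[start]),
            )
        )
        start = stop
    return OSS(entries=tuple(entries), s_0=seg.s_i)
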