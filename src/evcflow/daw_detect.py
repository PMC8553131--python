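"""Detection of Data Analysis Windows (DAWs) in the dynamic dataflow.

One gas test produces a characteristic three-stage excursion of the CH4
channel above the background threshold ``c_t``: injection rise, sealed
plateau, flush decay.  A window opens at the first reading above ``c_t``
that is preceded by ``quiet_count`` consecutive readings at or below the
threshold, and closes (exclusively) at the first subsequent reading at or
below ``c_t``.
Candidates shorter than ``min_window_size`` records, and candidates still
open when the stream ends, are discarded.  Detection always runs on the CH4
channel; CO2 is tested simultaneously by the instrument and inherits the
window span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .segmentation import DAWDataset
from .stream_io import CH4, CO2, AnalyzerConfig, DataStream

__all__ = ["DAW", "detect_windows", "extract_channel_dataset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DAW:
    """One detected Data Analysis Window.

    ``start_index`` points at the initial datum (first CH4 reading above
    ``c_t``); ``end_index`` is one past the last in-window record.  The
    reported ``result_time`` is the initial-datum time plus the configured
    offset, which lands in the sealed-test stage where the reading is
    meaningful.
    """

    start_index: int
    end_index: int
    t0: float
    result_time: float
    records: DataStream

    def __len__(self) -> int:
        return self.end_index - self.start_index


def detect_windows(stream: DataStream, config: AnalyzerConfig) -> list:
    """Scan the CH4 channel and return all valid windows, in time order.

    Returns a possibly-empty list of disjoint :class:`DAW`.  Discarded
    candidates (too short, or truncated by the end of the stream) are logged
    with the reason; the quiet-period rule means a rejected candidate cannot
    immediately retrigger on its own tail.
    """
    ch4 = stream.ch4
    c_t = config.c_t
    windows: list = []
    quiet_run = 0
    i = 0
    n = len(ch4)
    while i < n:
        v = ch4[i]
        if v > c_t and quiet_run >= config.quiet_count:
            # candidate opens here; close at first reading back at/below c_t
            below = np.flatnonzero(ch4[i + 1 :] <= c_t)
            if len(below) == 0:
                logger.info(
                    "candidate window at t=%s discarded: stream ended before "
                    "the signal returned below threshold",
                    stream.t[i],
                )
                break
            end = i + 1 + int(below[0])
            size = end - i
            if size >= config.min_window_size:
                windows.append(
                    DAW(
                        start_index=i,
                        end_index=end,
                        t0=float(stream.t[i]),
                        result_time=float(stream.t[i]) + config.timestamp_offset,
                        records=stream.slice(i, end),
                    )
                )
            else:
                logger.info(
                    "candidate window at t=%s discarded: %d records < "
                    "minimum window size %d",
                    stream.t[i],
                    size,
                    config.min_window_size,
                )
            # resume after the closing record; it is at/below threshold
            quiet_run = 1
            i = end + 1
            continue
        # readings at or below the threshold are background: with a
        # quantized sensor a reading can land exactly on c_t, and treating
        # it as a disturbance would discard the whole following test
        quiet_run = quiet_run + 1 if v <= c_t else 0
        i += 1
    return windows


def extract_channel_dataset(
    window: DAW, gas: str, config: AnalyzerConfig
) -> DAWDataset:
    """Build the sorted above-threshold value vector of one window channel.

    Timestamps are dropped and the channel's readings above ``c_t`` are
    sorted ascending (``V1..Vm``).  The CO2 channel inherits the CH4 window,
    so it may hold few or no above-threshold readings; below
    ``secondary_min_size`` of them the dataset is flagged channel-invalid.
    """
    raw = window.records.channel(gas)
    values = np.sort(raw[raw > config.c_t])
    valid = True
    if gas == CO2 and len(values) < config.secondary_min_size:
        valid = False
        logger.info(
            "window at t=%s: CO2 channel has %d above-threshold readings "
            "(< %d); channel flagged invalid",
            window.t0,
            len(values),
            config.secondary_min_size,
        )
    return DAWDataset(values=values, gas=gas, c_t=config.c_t, channel_valid=valid)
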