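"""Effective-value selection, value-dispersion review, and window analysis.

The effective concentration of a test is the mean of the modal OSS entry:
the entry with the unique maximum frequency, provided it is not the largest
entry (the window maximum belongs to transient data, never to the settled
plateau).  A review statistic — the value dispersion
``VD_b = (m_c[b+1] - m_c[b-1]) / (2 s_0)`` — checks that the selected entry
sits in a run of contiguous non-empty bins (VD close to 1), i.e. on the flat
part of the curve; a large VD betrays gaps from dropped empty bins and flags
the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .daw_detect import DAW, extract_channel_dataset
from .segmentation import (
    OSS,
    UnresolvableWindowError,
    build_oss,
    find_optimal_segmentation,
)
from .stream_io import CH4, CO2, AnalyzerConfig, DataStream

__all__ = [
    "STATUS_OK",
    "STATUS_REVIEW_FAILED",
    "STATUS_UNRESOLVABLE",
    "STATUS_CHANNEL_INVALID",
    "EffectiveValue",
    "select_effective",
    "value_dispersion",
    "review",
    "analyze_window",
    "analyze_stream",
]

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_REVIEW_FAILED = "review_failed"
STATUS_UNRESOLVABLE = "unresolvable"
STATUS_CHANNEL_INVALID = "channel_invalid"


@dataclass(frozen=True)
class EffectiveValue:
    """One gas concentration result for one window channel.

    ``value`` is the selected OSS mean in %vol (None when no value could be
    produced); ``vd`` is the review statistic (None when undefined, e.g. the
    selected entry has no lower neighbour).  ``detail`` carries the chosen
    segmentation width and mode count for decision logging.
    """

    gas: str
    value: Optional[float]
    result_time: float
    vd: Optional[float]
    status: str
    window_ref: float  # t0 of the source window
    detail: dict = field(default_factory=dict, compare=False)

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def select_effective(oss: OSS, config: AnalyzerConfig) -> int:
    """Index of the OSS entry holding the effective value.

    Two conditions must hold simultaneously: the entry has the unique
    maximum frequency, and it is not the largest (last) entry.  When the
    unique-frequency maximum *is* the last entry, the next-largest entry
    that is not last still qualifies if its frequency exceeds
    ``min_peak_count`` and is itself unique among the remaining entries.

    Raises
    ------
    UnresolvableWindowError
        Fewer than two entries, no unique maximum, or no qualifying
        fallback entry.
    """
    if len(oss) < 2:
        raise UnresolvableWindowError(
            "OSS has fewer than 2 entries; the effective value cannot be "
            "distinguished from the window maximum"
        )
    freqs = oss.frequencies
    top = freqs.max()
    holders = np.flatnonzero(freqs == top)
    if len(holders) != 1:
        raise UnresolvableWindowError(
            f"no unique maximum frequency (count {top} attained by "
            f"{len(holders)} entries)"
        )
    b = int(holders[0])
    if b < len(oss) - 1:
        return b
    # the modal entry is the largest value: fall back to the runner-up
    rest = freqs[:-1]
    runner = rest.max()
    candidates = np.flatnonzero(rest == runner)
    if runner > config.min_peak_count and len(candidates) == 1:
        return int(candidates[0])
    raise UnresolvableWindowError(
        "maximum-frequency entry is the largest OSS value and no qualifying "
        "runner-up exists"
    )


def value_dispersion(oss: OSS, b: int, s_0: Optional[float] = None) -> float:
    """Value dispersion of entry ``b`` (0-based): ``(m_c[b+1]-m_c[b-1])/(2 s_0)``.

    Defined only when both neighbours exist.  Equals 1 exactly when the
    neighbours each sit one bin width away, i.e. the local bins are
    contiguous and the curve is flat.
    """
    if not 1 <= b <= len(oss) - 2:
        raise ValueError("value dispersion requires both neighbouring entries")
    s = oss.s_0 if s_0 is None else s_0
    means = oss.means
    return float((means[b + 1] - means[b - 1]) / (2.0 * s))


def review(oss: OSS, selected: int, config: AnalyzerConfig):
    """Review the selected entry; returns ``(status, vd_or_None)``.

    A defined dispersion in ``(0, vd_max]`` passes; above ``vd_max`` the
    result is flagged ``review_failed`` (the value is still reported).  When
    the selected entry is the first OSS entry the dispersion is undefined
    and the review is skipped with status ``ok``.
    """
    if selected == 0:
        return STATUS_OK, None
    vd = value_dispersion(oss, selected)
    if 0 < vd <= config.vd_max:
        return STATUS_OK, vd
    return STATUS_REVIEW_FAILED, vd


def _analyze_channel(window: DAW, gas: str, config: AnalyzerConfig) -> EffectiveValue:
    dataset = extract_channel_dataset(window, gas, config)
    if not dataset.channel_valid:
        return EffectiveValue(
            gas, None, window.result_time, None, STATUS_CHANNEL_INVALID, window.t0
        )
    try:
        seg = find_optimal_segmentation(dataset, config)
        oss = build_oss(dataset, seg)
        b = select_effective(oss, config)
    except UnresolvableWindowError as exc:
        logger.info("window at t=%s, %s: %s", window.t0, gas, exc)
        return EffectiveValue(
            gas, None, window.result_time, None, STATUS_UNRESOLVABLE, window.t0
        )
    status, vd = review(oss, b, config)
    return EffectiveValue(
        gas=gas,
        value=oss.entries[b].m_c,
        result_time=window.result_time,
        vd=vd,
        status=status,
        window_ref=window.t0,
        detail={
            "multiple_i": seg.multiple_i,
            "s_0": seg.s_i,
            "mode_count": int(oss.entries[b].f_c),
            "oss_size": len(oss),
        },
    )


def analyze_window(window: DAW, config: AnalyzerConfig):
    """Run the full per-window pipeline on both channels.

    Extraction, optimal segmentation, OSS building, selection and review run
    independently per gas; any failure becomes a status on that channel's
    result without affecting the other.  Returns ``(CH4 result, CO2 result)``
    sharing the window's result time.
    """
    return (
        _analyze_channel(window, CH4, config),
        _analyze_channel(window, CO2, config),
    )


def analyze_stream(stream: DataStream, config: AnalyzerConfig) -> list:
    """Detect every window in a stream and analyze both channels of each.

    Convenience composition used by the CLI; returns a flat list of
    :class:`EffectiveValue` ordered by window, CH4 before CO2.
    """
    from .daw_detect import detect_windows

    results: list = []
    for window in detect_windows(stream, config):
        results.extend(analyze_window(window, config))
    return results
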