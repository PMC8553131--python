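"""Synthetic dynamic dataflows with known ground-truth concentrations.

Emulates the three-stage signal of one analyzer test at 1 Hz:

* stage I  — 45 s sample injection: saturating exponential rise from the
  background toward the true concentration;
* stage II — 90 s sealed test: the true concentration plus zero-mean
  Gaussian fluctuation whose standard deviation decays in time, mirroring a
  sensor settling toward its final reading;
* stage III — 60 s N2 flush then 165 s dried-air flush: a brief
  over-pressure bump above the plateau followed by exponential decay back to
  background.

Both channels share the stage timing (the instrument tests CH4 and CO2
simultaneously); fluctuations are drawn independently per channel.  All
samples are quantized to the sensor resolution and clipped at zero, so a
noiseless plateau reproduces ``quantize(c_star)`` exactly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .stream_io import CH4, CO2, AnalyzerConfig, DataStream, ReferenceTable, quantize

__all__ = ["WindowParams", "simulate_window", "simulate_stream"]


class WindowParams(BaseModel):
    """Ground truth and shape parameters for one simulated test window.

    Durations are seconds at 1 Hz; concentrations are %vol.  The defaults
    reproduce the analyzer schedule (45 s injection, 90 s sealed test, 60 s
    N2 flush, 165 s air flush) with plateau fluctuation starting at
    0.3 %vol — several resolution steps — and decaying with a 30 s time
    constant to about one step by the end of the test.
    """

    c_star_ch4: float = Field(gt=0)
    c_star_co2: float = Field(gt=0)
    background: float = Field(default=0.10, ge=0)
    tau_rise: float = Field(default=10.0, gt=0)
    injection_s: int = Field(default=45, gt=0)
    test_s: int = Field(default=90, gt=0)
    n2_flush_s: int = Field(default=60, gt=0)
    air_flush_s: int = Field(default=165, gt=0)
    noise_sigma0: float = Field(default=0.3, ge=0)
    noise_decay_tau: float = Field(default=30.0, gt=0)
    bump_amp: float = Field(default=0.5, ge=0)
    bump_width: int = Field(default=5, gt=0)
    flush_decay_tau: float = Field(default=30.0, gt=0)
    seed: Optional[int] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_levels(self) -> "WindowParams":
        # the background must stay quiescent and the plateau must clear it,
        # otherwise the window structure the schedule implies cannot exist
        if self.background >= min(self.c_star_ch4, self.c_star_co2):
            raise ValueError("background must lie below both true concentrations")
        return self

    @property
    def duration_s(self) -> int:
        return self.injection_s + self.test_s + self.n2_flush_s + self.air_flush_s

    def truth(self) -> dict:
        return {CH4: self.c_star_ch4, CO2: self.c_star_co2}


def _channel_trace(
    params: WindowParams, c_star: float, rng: np.random.Generator
) -> np.ndarray:
    p = params
    t1 = np.arange(1, p.injection_s + 1, dtype=float)
    rise = p.background + (c_star - p.background) * (1.0 - np.exp(-t1 / p.tau_rise))

    t2 = np.arange(p.test_s, dtype=float)
    sigma = p.noise_sigma0 * np.exp(-t2 / p.noise_decay_tau)
    plateau = c_star + rng.standard_normal(p.test_s) * sigma

    flush_s = p.n2_flush_s + p.air_flush_s
    t3 = np.arange(flush_s, dtype=float)
    peak = c_star + p.bump_amp
    bump = c_star + p.bump_amp * (t3[: p.bump_width] + 1.0) / p.bump_width
    decay = p.background + (peak - p.background) * np.exp(
        -(t3[p.bump_width :] - p.bump_width + 1.0) / p.flush_decay_tau
    )
    return np.concatenate([rise, plateau, bump, decay])


def simulate_window(params: WindowParams, rng=None):
    """Simulate one test window; returns ``(stream segment, truth dict)``.

    The segment covers the full schedule at 1 Hz starting at t = 0; the
    truth dict maps gas label to the true concentration.  With ``rng`` None
    the window's own ``seed`` initializes the generator, so identical
    parameters give bit-identical segments.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    config_res = AnalyzerConfig().resolution
    ch4 = _channel_trace(params, params.c_star_ch4, rng)
    co2 = _channel_trace(params, params.c_star_co2, rng)
    ch4 = quantize(np.clip(ch4, 0.0, None), config_res)
    co2 = quantize(np.clip(co2, 0.0, None), config_res)
    t = np.arange(params.duration_s, dtype=float)
    return DataStream(t, ch4, co2), params.truth()


def simulate_stream(
    schedule: Sequence[WindowParams],
    gap_s: int = 150,
    rng=None,
    config: Optional[AnalyzerConfig] = None,
):
    """Concatenate test windows separated by quiet background gaps.

    Returns ``(DataStream, ReferenceTable)`` where the truth table assigns
    sequential sample ids (0, 1, ...) to the windows in order — directly
    usable as the reference side of :func:`evcflow.evaluation.evaluate`.
    The gap before each window (and after the last) sits at the window's
    background level, so it must be at least ``quiet_count`` samples long
    for the detector's quiet-period rule to be satisfiable.
    """
    config = config or AnalyzerConfig()
    if gap_s < config.quiet_count:
        raise ValueError(
            f"gap_s={gap_s} is shorter than quiet_count={config.quiet_count}; "
            "windows would never satisfy the quiet-period rule"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)

    pieces_ch4: list = []
    pieces_co2: list = []
    truth_entries: list = []
    for k, params in enumerate(schedule):
        bg = quantize(params.background, config.resolution)
        gap = np.full(gap_s, bg)
        segment, truth = simulate_window(params, rng)
        pieces_ch4 += [gap, segment.ch4]
        pieces_co2 += [gap, segment.co2]
        truth_entries += [(k, CH4, truth[CH4]), (k, CO2, truth[CO2])]
    tail_bg = quantize(schedule[-1].background, config.resolution) if schedule else 0.0
    pieces_ch4.append(np.full(gap_s, tail_bg))
    pieces_co2.append(np.full(gap_s, tail_bg))

    ch4 = np.concatenate(pieces_ch4)
    co2 = np.concatenate(pieces_co2)
    t = np.arange(len(ch4), dtype=float)
    return DataStream(t, ch4, co2), ReferenceTable(tuple(truth_entries))
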