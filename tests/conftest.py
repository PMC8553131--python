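"""Shared fixtures and independent brute-force oracles.

The oracle functions re-derive binning, OSS statistics and the
optimal-width search by per-value scanning and plain Python loops, sharing
no code with the package, so tests can compare the two routes.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from evcflow import AnalyzerConfig, DataStream, quantize

EPS = 1e-9


@pytest.fixture
def config() -> AnalyzerConfig:
    return AnalyzerConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def stream_from_ch4(ch4_values, co2_values=None) -> DataStream:
    """Build a 1 Hz stream from a CH4 value sequence (CO2 defaults to zero)."""
    ch4 = np.asarray(ch4_values, dtype=float)
    co2 = np.zeros_like(ch4) if co2_values is None else np.asarray(co2_values, float)
    return DataStream(np.arange(len(ch4), dtype=float), ch4, co2)


def random_dataset_values(
    rng: np.random.Generator, config: AnalyzerConfig, max_m: int = 300
) -> np.ndarray:
    """Sorted quantized values above c_t, clustered so a mode usually exists."""
    m = int(rng.integers(2, max_m + 1))
    center = rng.uniform(1.0, 50.0)
    spread = rng.uniform(0.05, 2.0)
    vals = center + rng.standard_normal(m) * spread
    vals = quantize(np.clip(vals, config.c_t + config.resolution, None),
                    config.resolution)
    return np.sort(vals)


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_bin_edges(values, c_t: float, s: float):
    n = max(1, math.ceil((max(values) - c_t) / s - EPS))
    return [(c_t + b * s, c_t + (b + 1) * s) for b in range(n)]


def oracle_assign_bin(v: float, edges) -> int:
    """Scan bins for one value: half-open everywhere, last bin closed above."""
    last = len(edges) - 1
    for b, (lo, hi) in enumerate(edges):
        if b == last:
            if lo - EPS <= v <= hi + EPS:
                return b
        elif lo - EPS <= v < hi - EPS:
            return b
    raise AssertionError(f"value {v} falls in no bin")


def oracle_counts(values, c_t: float, s: float):
    edges = oracle_bin_edges(values, c_t, s)
    counts = [0] * len(edges)
    for v in values:
        counts[oracle_assign_bin(v, edges)] += 1
    return counts


def oracle_oss(values, c_t: float, s: float):
    """(mean, count, bin index) of each non-empty bin, by dict grouping."""
    edges = oracle_bin_edges(values, c_t, s)
    groups: dict = {}
    for v in values:
        groups.setdefault(oracle_assign_bin(v, edges), []).append(v)
    return [
        (sum(vs) / len(vs), len(vs), b) for b, vs in sorted(groups.items())
    ]


def oracle_optimal_multiple(values, config: AnalyzerConfig):
    """First width multiple with a unique mode above min_peak_count, or None."""
    for i in range(1, config.max_multiple + 1):
        counts = oracle_counts(values, config.c_t, i * config.resolution)
        top = max(counts)
        if counts.count(top) == 1 and top > config.min_peak_count:
            return i
    return None
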