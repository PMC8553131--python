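"""Effective-value selection, value-dispersion review, window pipeline."""

import numpy as np
import pytest

from evcflow import (
    CH4,
    CO2,
    OSS,
    AnalyzerConfig,
    DataStream,
    OSSEntry,
    UnresolvableWindowError,
    WindowParams,
    analyze_window,
    detect_windows,
    quantize,
    review,
    select_effective,
    simulate_stream,
    value_dispersion,
)
from evcflow.daw_detect import DAW
from evcflow.effective_value import (
    STATUS_CHANNEL_INVALID,
    STATUS_OK,
    STATUS_REVIEW_FAILED,
    STATUS_UNRESOLVABLE,
)

from conftest import stream_from_ch4


def oss_from(freqs, means=None, s_0=0.05) -> OSS:
    if means is None:
        means = [1.0 + i * s_0 for i in range(len(freqs))]
    entries = tuple(
        OSSEntry(m_c=m, f_c=f, bin_index=i) for i, (m, f) in enumerate(zip(means, freqs))
    )
    return OSS(entries=entries, s_0=s_0)


class TestSelection:
    def test_unique_maximum_not_last_is_selected(self, config):
        assert select_effective(oss_from([2, 7, 3]), config) == 1

    def test_tied_maximum_is_unresolvable(self, config):
        with pytest.raises(UnresolvableWindowError):
            select_effective(oss_from([2, 7, 7]), config)

    def test_maximum_on_largest_entry_with_weak_runner_up_is_unresolvable(
        self, config
    ):
        # the mode sits on the window maximum; the runner-up (3) does not
        # exceed the minimum peak count, so nothing qualifies
        with pytest.raises(UnresolvableWindowError):
            select_effective(oss_from([2, 3, 9]), config)

    def test_maximum_on_largest_entry_falls_back_to_strong_runner_up(self, config):
        assert select_effective(oss_from([2, 8, 12]), config) == 1

    def test_single_entry_is_unresolvable(self, config):
        with pytest.raises(UnresolvableWindowError):
            select_effective(oss_from([10]), config)


class TestValueDispersion:
    def test_contiguous_neighbours_give_dispersion_one(self):
        oss = oss_from([1, 9, 1], means=[1.00, 1.05, 1.10])
        assert value_dispersion(oss, 1) == pytest.approx(1.0)

    def test_gap_from_dropped_empty_bins_inflates_dispersion(self):
        # neighbours four bin widths apart -> VD = 2
        oss = oss_from([1, 9, 1], means=[1.00, 1.05, 1.20])
        assert value_dispersion(oss, 1) == pytest.approx(2.0)

    def test_boundary_entries_have_no_dispersion(self):
        oss = oss_from([1, 9, 1])
        for b in (0, 2):
            with pytest.raises(ValueError):
                value_dispersion(oss, b)


class TestReview:
    def test_dispersion_within_bound_passes(self, config):
        oss = oss_from([1, 9, 1], means=[1.00, 1.05, 1.10])
        status, vd = review(oss, 1, config)
        assert status == STATUS_OK
        assert vd == pytest.approx(1.0)

    def test_dispersion_beyond_bound_is_flagged(self, config):
        oss = oss_from([1, 9, 1], means=[1.00, 1.05, 1.35])
        status, vd = review(oss, 1, config)
        assert status == STATUS_REVIEW_FAILED
        assert vd == pytest.approx(3.5)

    def test_first_entry_selection_skips_review(self, config):
        oss = oss_from([9, 1, 1])
        status, vd = review(oss, 0, config)
        assert status == STATUS_OK
        assert vd is None


def simulated_single_window(c_ch4=30.0, c_co2=15.0, seed=7, **kw):
    params = WindowParams(c_star_ch4=c_ch4, c_star_co2=c_co2, **kw)
    stream, _ = simulate_stream([params], gap_s=150, rng=np.random.default_rng(seed))
    return stream


class TestAnalyzeWindow:
    def test_recovers_true_concentration_within_allowable_error(self, config):
        stream = simulated_single_window()
        (window,) = detect_windows(stream, config)
        ch4_res, co2_res = analyze_window(window, config)
        assert ch4_res.status == STATUS_OK
        assert abs(ch4_res.value - 30.0) / 30.0 <= 0.025
        assert co2_res.status == STATUS_OK
        assert abs(co2_res.value - 15.0) / 15.0 <= 0.025
        assert ch4_res.result_time == co2_res.result_time == window.result_time

    def test_quiet_co2_channel_is_invalid_without_affecting_ch4(self, config):
        # CO2 truth below the threshold: the CH4-triggered window holds no
        # usable CO2 signal
        stream = simulated_single_window(c_co2=0.4)
        (window,) = detect_windows(stream, config)
        ch4_res, co2_res = analyze_window(window, config)
        assert ch4_res.status == STATUS_OK
        assert co2_res.status == STATUS_CHANNEL_INVALID
        assert co2_res.value is None

    def test_constant_window_is_unresolvable(self, config):
        # a window with no transient data collapses to a single OSS entry,
        # which can never satisfy the not-the-largest-entry condition
        stream = stream_from_ch4([30.0] * 200, [30.0] * 200)
        window = DAW(0, 200, 0.0, 135.0, stream)
        ch4_res, co2_res = analyze_window(window, config)
        assert ch4_res.status == STATUS_UNRESOLVABLE
        assert co2_res.status == STATUS_UNRESOLVABLE
        assert ch4_res.value is None

    def test_effective_value_below_window_maximum(self, config):
        stream = simulated_single_window(seed=11)
        (window,) = detect_windows(stream, config)
        for res, gas in zip(analyze_window(window, config), (CH4, CO2)):
            assert res.status == STATUS_OK
            assert res.value < window.records.channel(gas).max()

    def test_analysis_is_deterministic(self, config):
        stream = simulated_single_window(seed=3)
        (window,) = detect_windows(stream, config)
        first = analyze_window(window, config)
        second = analyze_window(window, config)
        assert first == second

    def test_dispersion_smallest_near_the_effective_value(self, config):
        """The plateau region has contiguous bins; transients have gaps."""
        from evcflow import build_oss, extract_channel_dataset, find_optimal_segmentation

        stream = simulated_single_window(seed=5)
        (window,) = detect_windows(stream, config)
        ds = extract_channel_dataset(window, CH4, config)
        oss = build_oss(ds, find_optimal_segmentation(ds, config))
        b = select_effective(oss, config)
        vd_selected = value_dispersion(oss, b)
        others = [
            value_dispersion(oss, j)
            for j in range(1, len(oss) - 1)
            if abs(j - b) > 2
        ]
        assert vd_selected < np.mean(others)
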