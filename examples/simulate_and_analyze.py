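"""Simulate a small monitoring campaign and compute effective values.

Builds a synthetic 1 Hz dataflow with five test windows of known true
CH4/CO2 concentrations, detects the Data Analysis Windows, and prints the
effective value found for each channel next to the truth.  The effective
value is the mean of the modal bin of the window's value histogram — not
the window maximum and not the overall mean, both of which are biased by
injection/flush transients.
"""

import numpy as np

from evcflow import (
    AnalyzerConfig,
    WindowParams,
    analyze_window,
    detect_windows,
    simulate_stream,
)

rng = np.random.default_rng(2026)
schedule = [
    WindowParams(
        c_star_ch4=float(rng.uniform(10.0, 60.0)),
        c_star_co2=float(rng.uniform(5.0, 40.0)),
    )
    for _ in range(5)
]
stream, truth = simulate_stream(schedule, gap_s=150, rng=rng)
config = AnalyzerConfig()

windows = detect_windows(stream, config)
print(f"stream: {len(stream)} samples, {len(windows)} windows detected\n")
print(f"{'t_result':>9} {'gas':>4} {'truth':>7} {'effective':>9} "
      f"{'rel.err%':>8} {'VD':>5} status")
truth_map = {(sid, gas): v for sid, gas, v in truth.entries}
for k, window in enumerate(windows):
    for res in analyze_window(window, config):
        true_c = truth_map[(k, res.gas)]
        rel = 100 * abs(res.value - true_c) / true_c
        vd = f"{res.vd:.2f}" if res.vd is not None else "  —"
        print(f"{res.result_time:9.0f} {res.gas:>4} {true_c:7.2f} "
              f"{res.value:9.3f} {rel:8.3f} {vd:>5} {res.status}")

print("\nEach row is one test: the effective value tracks the truth to a")
print("fraction of a percent, and VD ≈ 1 confirms the value sits on the")
print("settled plateau (contiguous histogram bins).")
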