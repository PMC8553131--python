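# Methods

## Signal model

One test of an online infrared CH₄/CO₂ analyzer produces a three-stage
excursion of the concentration signal above the instrument background:

- **Stage I — injection (~45 s).** The sample displaces the chamber
  atmosphere; the reading rises with decreasing slope toward the sample
  concentration.
- **Stage II — sealed test (~90 s).** The reading fluctuates around the
  true concentration, with fluctuation amplitude shrinking toward the end
  of the stage as the sensor settles.
- **Stage III — flush (~60 s N₂ + ~165 s dried air).** A check valve at
  the chamber outlet causes a brief over-pressure bump above the plateau,
  after which the reading decays back to background.

At 1 Hz most readings are transients. The effective value — what the test
should report — is the value the signal dwells on at the end of stage II.
Two distributional facts make it recoverable by counting alone: each value
visited during stages I/III has low frequency (the signal passes through
it once or twice), while the settled plateau revisits a narrow band of
values many times. The effective value is therefore the mean of the modal
region of the window's value histogram.

## Pipeline

### Window detection

Detection runs on the CH₄ channel (the instrument tests both gases
simultaneously, so CO₂ inherits the window span). A window opens at the
first reading strictly above the threshold `c_t` preceded by `quiet_count`
consecutive readings at or below `c_t`, closes exclusively at the first
later reading at or below `c_t`, and is kept only if it holds at least
`min_window_size` records. Candidates truncated by the end of the stream
are discarded. The reported result time is the opening time plus
`timestamp_offset`, which lands inside the sealed stage.

Readings exactly equal to `c_t` are treated as background: they neither
open a window nor interrupt the quiet run. With a quantized sensor the
injection rise regularly emits a sample exactly on the threshold level,
and treating it as a disturbance would discard the entire following test —
the quiet rule exists to reject abnormal fluctuations, and a boundary
reading is not one. The closure rule (first return to `c_t`) follows the
shape of stage III; the alternative of a fixed cycle length would make the
detector depend on scheduling information the stream itself does not carry.

### Channel datasets

Per channel, the window's readings strictly above `c_t` are de-timestamped
and sorted ascending (`V1..Vm`). Bin counts are order-invariant; sorting
is kept because it makes every bin a contiguous index range, which is what
allows the OSS statistics to be computed with running sums on an embedded
target. The CO₂ channel may sit near or below the threshold inside a
CH₄-triggered window; with fewer than `secondary_min_size` usable readings
it is flagged channel-invalid rather than analyzed.

### Adaptive segmentation and the OSS

The value domain from `c_t` to the window maximum `c_max` is divided into
`n = ceil((c_max − c_t)/s_i)` equal bins of width `s_i = i × resolution`.
Bins are half-open `[lo, hi)` with the final bin closed so `c_max` is
counted; boundary values belong to the upper bin. Anchoring at `c_t`
rather than zero avoids a band of structurally empty bins below the
threshold (the dataset contains no values there by construction).

The width search tries `i = 1 … max_multiple` and accepts the first width
at which (a) exactly one bin attains the maximum count and (b) that count
strictly exceeds `min_peak_count`. Both conditions are required: at fine
widths the plateau splits across bins and ties are common, while a unique
maximum of only a handful of readings is indistinguishable from a
transient coincidence. If no width qualifies, the window is flagged
unresolvable and produces a null result instead of aborting the stream
run.

At the accepted width each non-empty bin collapses to one OSS entry
`(m_c, f_c)`: the arithmetic mean and count of its members. Empty bins are
dropped, so gaps in the OSS mean gaps in the occupied value domain.

### Selection and review

The effective value is the `m_c` of the entry with the unique maximum
`f_c`, subject to the constraint that it is not the last (largest) entry —
the window maximum belongs to the stage-III bump, never to the plateau.
When the unique maximum does fall on the last entry, the runner-up is
taken instead if its frequency strictly exceeds `min_peak_count` and is
itself unique among the remaining entries (the uniqueness requirement is
applied consistently; the selection rule gives no basis for breaking a
runner-up tie). Otherwise the window is unresolvable. A consequence worth
knowing: a perfectly constant window yields a single OSS entry and is
unresolvable by design — the model needs the transient stages to bracket
the plateau from above.

The review statistic is the value dispersion
`VD_b = (m_c[b+1] − m_c[b−1]) / (2 s_0)`. Where consecutive non-empty bins
are contiguous — the flat part of the curve — VD equals 1; a dropped empty
neighbour doubles it. Results with `0 < VD ≤ vd_max` pass; larger VD flags
the result `review_failed`, but the value is still reported (a monitoring
pipeline prefers flagged data to gaps). When the selected entry is the
first OSS entry the lower neighbour does not exist, VD is undefined, and
the review is recorded as skipped with status ok.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `c_t` | 0.50 | %vol | background/test threshold; binning anchor |
| `resolution` | 0.05 | %vol | sensor quantization step (500 ppm) |
| `max_multiple` | 20 | — | largest bin-width multiple tried |
| `min_peak_count` | 6 | — | modal count must strictly exceed this |
| `quiet_count` | 100 | samples | background run required before a window |
| `min_window_size` | 150 | samples | minimum window length |
| `timestamp_offset` | 135 | s | window start → reported result time |
| `vd_max` | 1.5 | — | review bound on the value dispersion |
| `secondary_min_size` | 50 | samples | minimum usable CO₂ readings |

`vd_max = 1.5` operationalizes "VD close to 1": contiguous bins give
VD ≈ 1 and a single dropped neighbour already gives ≈ 2, so 1.5 separates
the two regimes with margin for bin-mean jitter. `secondary_min_size` has
no counterpart in the window rules (which constrain only the window
itself); 50 readings — a third of a minimum window — is enough for a
meaningful histogram on the inherited channel. Both are configurable.

Quantization uses round-half-up to the nearest resolution multiple; the
instrument specification fixes the step but not the rounding rule, and
half-up is the convention that keeps `quantize` idempotent and symmetric
around bin centres. Timestamps are relative seconds; elapsed time never
enters the rules (only sample counts do), so streams with gaps are
accepted.

## Simulator

The simulator emulates exactly the three-stage shape above: exponential
saturating rise (`tau_rise` = 10 s reaches ≈ 99 % of the plateau by the
end of a 45 s injection), Gaussian plateau fluctuation with standard
deviation `noise_sigma0 · exp(−t/noise_decay_tau)` (defaults 0.3 %vol and
30 s: several resolution steps early, about one step late — the frequency
structure the model exploits), and a flush modelled as a `bump_amp`
(0.5 %vol) over-pressure ramp of `bump_width` (5 s) followed by
exponential decay (`flush_decay_tau` = 30 s) to a background of 0.10 %vol.
All samples are quantized and clipped at zero; a fixed seed reproduces the
stream bit for bit.

What it does **not** model: cross-sensitivity between channels, baseline
drift, temperature effects, autocorrelated or non-Gaussian plateau noise,
and irregular sampling. Passing tests on simulated streams therefore
demonstrate that the algorithm recovers a settled value from the assumed
three-stage dynamics; they do not certify behaviour under sensor faults
the simulator cannot produce.

## Numerical choices

- Bin assignment is `floor((v − c_t)/s_i)` with a 1e-9 epsilon so that
  quantized values landing exactly on a bin edge go to the upper bin
  regardless of binary-float representation; the same epsilon guards the
  `ceil` in the bin count. Concentrations are bounded (≤ 100 %vol), so the
  epsilon can never move a genuinely interior value.
- The width search is a plain exhaustive scan over `i`; with at most 20
  candidate widths and `m` a few hundred, nothing faster is warranted, and
  the scan is trivially deterministic.
- Degenerate inputs: empty datasets refuse to partition; a dataset whose
  values are all equal occupies one bin at every width (unique mode, but
  unresolvable at selection); unresolvable and channel-invalid windows
  yield flagged null results, never exceptions, so one bad window cannot
  abort a stream run.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on simulated data:
campaigns of 200 windows (tests) and 50 windows (acceptance script) with
true concentrations uniform in 2–60 %vol per gas under default noise, and
500 randomly generated small datasets (m ≤ 300) cross-checked against a
per-value brute-force implementation of binning, OSS statistics and the
width search. A 50-window campaign mirrors the scale of a typical
validation set for this kind of instrument model.

## Known limitations

- Detection is single-point: mapping windows of a multiplexed tube-bundle
  stream back to monitoring points is the caller's job.
- The CO₂ channel reuses the CH₄ threshold; an instrument with very
  different CO₂ background levels would need its own `c_t`.
- A review failure reports a flagged value; no re-segmentation at another
  width is attempted (the selection rule defines no such escalation).
- Reference matching is by `(sample_id, gas)`; aligning result times to
  an external sampling log is out of scope.
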