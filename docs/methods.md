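# Methods

This note documents the models, defaults and design choices behind the
package, in the order the pipeline runs. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Time and data model

Timestamps are trace-relative seconds (real-valued); there is no wall-clock
or timezone handling anywhere. All segment intervals are half-open
`[start, end)`, so adjacent segments compose without double-counting and
slicing commutes with sub-slicing. The series container holds one ordered
`(t, v)` array pair per channel; the five channels are fixed —
temperature (°C), relative humidity (%RH), eCO2 (ppm), TVOC (ppb), sound
(uncalibrated dB). The nominal sampling interval defaults to 1 s (the
source deployment never states its rate; 1 s is typical of consumer
air-quality sensors and is a declared choice). Slice bounds outside the
trace are clamped with a logged warning, because device-event latency can
overrun the trace edges.

## Synthetic smart-home simulator

The simulator is the package's study condition, not a physical model. Each
activity has a per-channel first-order response: during an episode the
channel moves toward `baseline + A` with time constant `tau_r`
(`A·(1 − e^{−(t−s)/tau_r})`), and relaxes exponentially with `tau_d`
afterwards. Episode effects are additive across overlaps, and independent
Gaussian noise is added per channel. This shape was chosen because it is
the simplest one reproducing what ambient sensing actually shows — fast
perturbation after a person enters, slow relaxation after they leave —
and because it keeps a closed-form oracle: the noise-free trace is exactly
the sum of analytic curves, which the tests evaluate independently.

What it does *not* emulate: air-exchange physics, cross-room transport,
multiple simultaneous occupants, sensor drift, and diurnal baselines.
Passing tests therefore demonstrate the pipeline's correctness and its
separability under these conditions, not field accuracy on real homes.

Default baselines are 22 °C, 40 %RH, 420 ppm, 50 ppb, 35 dB; default noise
SDs 0.05 °C, 0.3 %RH, 8 ppm, 6 ppb, 1 dB (consumer-sensor magnitudes).
The published deployment gives no response amplitudes for any activity, so
the catalogue (five kitchen ADLs + fire, four bathroom ADLs) is a synthetic
design, chosen once: amplitudes scale with the intensity of the activity
(dinner > lunch > breakfast; shower dominates bathroom humidity), each
activity gets a distinctive per-channel *time-constant fingerprint* (a
bowel movement drives TVOC fast but humidity slowly; a shower saturates
humidity within a minute), ventilation has negative amplitudes, and fire
is constrained to have strictly the largest temperature amplitude and
strictly the smallest temperature rise constant of any kitchen heat
source. Those orderings are hard invariants checked in tests.

Device events carry latency: entrance detection delays are drawn from a
Gaussian with the deployment's measured mean of 5.67 s (activity
assessment 2.11 s), SD 1.0 s (SD unpublished — a declared choice),
truncated at zero. Ground-truth labels record the script verbatim and
never depend on the latency model. One `numpy` generator seeded from the
scenario drives all randomness, so identical scripts give byte-identical
outputs.

The bundled day scripts space episodes a few decay constants apart so one
activity's tail does not contaminate the next segment's fingerprint; this
is a property of the scripted study conditions, stated here because real
days do not guarantee it.

## Segmentation

Flat, never nested: the source gives no nesting semantics, and flat
segments keep evaluation well-defined. A start while open closes at the
new event and immediately reopens (back-to-back behaviours). The
stop-in-idle case is a logged warning, not an error, since a hub can
legitimately observe an exit it never saw the entry for. The timeout
boundary is inclusive (`now − opened_at ≥ max_len` closes). The default
maximum segment length is 1800 s — comfortably above the longest
catalogued activity (a dinner). Which device/payload pairs mean
start/stop/point is a configurable role map; the default treats an
infrared "out" as a stop for any open segment, including ones opened by
appliance tags — the least surprising flat-segmentation rule, flagged as a
choice because the source does not specify it.

## Streaming features

Per channel: count, first/last timestamp, Welford mean, min/max, the
timestamp at which the maximum was last raised (the pre-check's
rise-to-peak), and the four OLS sums with timestamps re-based to the
window's first sample (otherwise `Σt²` at ~10⁵ s costs ~10 digits of
conditioning). Equal timestamps are tolerated on update but make the slope
undefined (reported as an error object, not a crash). A `merge` of two
consecutive disjoint windows re-bases the second window's sums in closed
form; streaming, merged and batch results agree to 1e−9 relative
tolerance in property tests. "Peak" means both the channel max (high) and
min (low): the low peak is what distinguishes ventilation, the only
catalogued activity that *lowers* channels.

## Emergency screening

The watch computes the regression slope over 60 s tumbling windows. The
60 s window length is the "recent history" the watch sees; the source
describes a short start-of-queue region without quantifying it, so 60 s
(one window per minute, ~12 s of fire rise visible within it) is a
declared default. Comparisons are strict (`>` the bound), documented
because a boundary rule had to be picked. Undefined slopes are normal.

The pre-check flags a segment iff some channel's `peak_high` exceeds its
bound **and** the rise to that peak completed within the rise-duration
bound. Defaults (temperature: 30 °C peak within 600 s, slope 0.05 °C/s;
eCO2 1200 ppm / 30 ppm·s⁻¹; TVOC 1400 ppb / 40 ppb·s⁻¹) were calibrated
once against the simulator's fire and cooking profiles — the hottest
cooking profile peaks near 26 °C at ~0.011 °C/s, fire tops 30 °C within
its first minutes at ~0.2 °C/s — since the source quantifies no threshold.
Humidity and sound are not screened.

A note on monotonicity: "raising every threshold only turns emergencies
into passes" holds for the peak and slope bounds but is inverted for the
rise-duration bound (a *larger* allowed rise window makes the emergency
condition easier). The tested property is therefore: tightening the
emergency definition — raising peak/slope bounds, shrinking the rise
window — never creates a new emergency.

## PWFMA scoring

Normalisation is min-max with clamping to [0, 1]; the four features have
incomparable units and must be combined unit-free. Reference ranges span
the simulator's operating envelope (e.g. temperature mean 18–30 °C,
humidity peak-high 30–80 %RH, duration 0–1800 s).

The deployment's weights were set empirically and never published. The
default table is produced the same way, by a transparent calibration:
simulate one noise-free episode of each ADL at its typical duration,
extract and normalise its features, and use the L2-normalised 20-vector as
that ADL's weight row. With unit-norm rows, `score(a | x) ∝ cos(µ_a, x)`,
so each prototype is its own argmax and separation degrades gracefully
under noise. Weights are non-negative by construction and ship as editable
YAML.

The device base weight is applied multiplicatively (a neutral weight of 1
is the identity); an additive variant (`raw + (d − 1)`) is available via
the table's `device_mode` since the source does not specify the
composition. Default device weights are the neutral 1.0. Ties break
lexicographically with a flag — determinism over hidden randomness. An
optional score floor reports "unknown" below it, off by default, since a
reject outcome is plausible but unspecified.

## DTW reference matching

References are plain pointwise means of linearly resampled instances
(barycenter averaging is deliberately out of scope). The resampling grid
spans each instance's own sample support with `grid_len` (default 100)
evenly spaced points, so duration is normalised away and shape carries the
signal. Local cost is absolute difference; the step set is
{(i−1,j), (i,j−1), (i−1,j−1)}, which makes the distance symmetric and
zero on identical sequences, and any Sakoe–Chiba band at least as wide as
the length difference is feasible. Each DP row is vectorised by
telescoping the in-row recurrence into a running minimum over prefix sums.

Channels are z-normalised before matching by default (constant channels
map to zeros), so large-unit channels do not dominate the summed
multichannel cost; a raw-amplitude mode is exposed because whether the
original evaluation normalised is unstated. Per-channel costs are summed
rather than doing vector-valued DTW — simpler, and checkable against a
brute-force path enumeration per channel.

## Evaluation protocol

Greedy one-to-one matching in truth time order; each truth entry takes the
unmatched prediction with the largest overlap among those covering at
least `overlap_frac` (default 0.5 — the matching criterion is unstated in
the source) of the truth duration, ties to the earliest prediction, which
makes the result independent of prediction order. Every truth entry is
exactly one of correct/false/miss (a tested invariant). Unmatched
predictions with untargeted labels land in the generic "activity" tally.

`accuracy = 100·correct/(correct+false+miss)` is not stated as a formula
in the source but is the unique simple ratio reconciling all nine printed
accuracy cells of its two evaluation tables with their printed counts.
The printed cells mix round-half-up and truncation (95.45 → 95.4,
86.57 → 86.5), so reproduction is asserted at ±0.15 percentage points
rather than guessing the rounding; this package rounds half-even to one
decimal.

## Problem sizes

The bundled day scripts cover a full 86 400 s day at 1 Hz (432 000
samples per trace); the end-to-end checks run one noise-free day and 20
noisy seeded days per classifier mode, the oracle-equivalence suites use
200 seeded trials each, and the streaming-equals-batch check uses 500
random segments. `scripts/acceptance.py` uses ten noisy days. These sizes
were chosen to exercise every code path at full-day scale while keeping a
complete run in the tens of seconds on one CPU.

## Known limitations

* The simulator's additive, first-order world is far kinder than a real
  home; the 100 % noise-free recovery says the pipeline is correct, not
  that it would reach the reference deployment's field accuracies.
* PWFMA's cosine calibration assumes segment features resemble some
  prototype; heavily overlapping episodes or un-catalogued behaviours
  produce confident nonsense unless the score floor is enabled.
* Z-normalised DTW discards amplitude, the strongest discriminator between
  scaled variants of the same shape (the meals); it survives here because
  the catalogue gives each activity a distinct time-constant fingerprint.
* Segmentation is single-resident and single-space; there is no cross-hub
  stitching or multi-occupancy disambiguation.
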