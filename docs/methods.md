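# Methods

## Calibration model

The device controls a digital amplification `A` in dB: `A = 0` is exact
digital silence, `A = 100` full scale, and the emitted amplitude is
`10^((A-100)/20)` for `A > 0`. The packaged table stores, per frequency, the
reference amplification `A0` producing 0 dB HL and the RETSPL (the coupler
SPL of 0 dB HL), so

    amplification(f, L) = A0(f) + L        [dB]
    expected_spl(f, L)  = RETSPL(f) + L    [dB SPL]

Amplification is restricted to the 5-dB grid in [5, 100]; requests off the
grid or out of bounds raise a range error naming the violated bound. The
measurable range per frequency is `[5 - A0, 100 - A0 + 5]` dB HL — the upper
bound includes the +5 dB "ceiling" value recorded when a listener fails to
respond at the loudest presentable tone.

Three table rows (125 Hz, 14 kHz, 16 kHz) saturate before the usual 70 dB HL
calibration point; their RETSPLs are extrapolated from the SPL measured at
full scale: `RETSPL = SPL_at_max - (100 - A0)`. These rows carry an
`extrapolated` flag.

Two documented conventions:

* **Amplitude reference.** The amplitude produced by the dB map is applied
  as the sine's peak scale factor. Whether the original digital convention
  meant peak or RMS is absorbed entirely by the calibration constants (a
  fixed 3.01 dB convention difference that never changes any HL value), so
  the choice is cosmetic; peak keeps full-scale sines unclipped.
* **8 kHz range.** The 8 kHz row's reference amplification (15 dB) implies
  the range [-10, 90] dB HL. A published version of this table prints
  [-15, 90] for that row, which is inconsistent with its own reference
  amplification; ranges here are always derived from the formula, never
  hard-coded, so the 8 kHz interval is [-10, 90].

Post-hoc recalibration (`adjust_calibration`) shifts each frequency's
reference amplification by its mean inter-device threshold difference
rounded to the nearest multiple of 5 dB (the amplification step). Ties round
away from zero so positive and negative biases are treated symmetrically.
The caller supplies the differences in the orientation to be applied.

## Stimulus

Five beeps of 50/200/50 ms fade-in/plateau/fade-out plus a 100 ms pause:
400 ms per beep, 2000 ms per train, rendered at 48 kHz. Fades are
raised-cosine (Hann flanks) by default — standard audiometric gating with
bounded spectral splatter — with linear fades available via
`StimulusSpec(fade_shape="linear")`. The sine phase restarts at zero at each
beep onset, making renders bit-reproducible; segment sample counts are
rounded independently, so the cumulative length error is bounded by the
number of segments. Pauses are exact zeros. WAV export is mono 32-bit
IEEE-float PCM.

## Staircase

The track is a pure state machine (no audio, no wall clock). Start level
40 dB HL, -10 dB after a detection, +5 dB after a miss, clipped to the
presentable bounds. A press later than the 2000 ms stimulus is scored as a
miss with its latency logged ("too late" rule). Inter-trial pauses are drawn
uniformly from [2000, 4000] ms with the session's single seeded generator,
which also drives listener noise; one seed therefore reproduces a session
bit-for-bit.

Validation counts inversions (direction flips) after the first trial fixes
the start type. Descending start: two inversions (omission then detection),
both variants. Ascending start: one inversion (first detection) for the
ELIOS variant, three for the AUPIOMETER variant. The recorded threshold is
the level of the detection completing the required count — the ascending
detection level, the conventional Hughson–Westlake choice; the source
procedure does not state which level is recorded, so this is a design
decision. Because inversions alternate between omissions and detections, the
required count always terminates on a detection for a deterministic
listener; for stochastic listeners the detection requirement is enforced
explicitly.

Terminal cases beyond validation:

* **Ceiling** — a miss at the loudest presentable level ends the track with
  threshold = that level + 5 dB.
* **Floor** (design decision; the source defines only the ceiling) — a
  second consecutive detection pinned at the quietest presentable level ends
  the track with threshold = that level and a `floor` flag, since nothing
  below it can be presented to generate the validating omission.
* **Abort** — a 50-trial safety cap (no cap exists in the source procedure);
  the threshold is reported as missing.

`stop_on_press` (ELIOS truncates the stimulus on a press; AUPIOMETER plays
it out) affects only simulated trial duration and logging, never level
sequencing; the two variants produce identical level sequences whenever the
first trial is a detection.

## Simulated listeners

Detection probability is `guess + (1 - guess - lapse) * F((L - T)/sigma)`
with `F` the cumulative normal (logistic available). Defaults: `sigma = 4`
dB — chosen so near-threshold trials are genuinely probabilistic, as in real
audiometry — `guess = 0.01`, `lapse = 0.02`. Press latency is log-normal
(median 600 ms, log-sigma 0.35); late presses arise from this distribution
rather than a separate parameter. `sigma = 0` with zero guess/lapse gives
the deterministic step observer used as the staircase oracle.

The panel generator emulates the validation study's population: 16
participants, two ears each, 7 young / 9 elderly. Per-ear thresholds are
N(5, 5) dB HL drawn on the 5-dB grid, resampled until every 250 Hz – 8 kHz
threshold is below 25 dB HL (the normal-hearing inclusion criterion). Elderly
ears add an extended-high-frequency loss ramp: a per-ear magnitude drawn
uniformly from [20, 65] dB applied fully at 16 kHz and at fractions
0.8/0.5/0.2 at 14/12.5/10 kHz — a presbycusis-like profile producing
thresholds up to 65 dB HL at 14–16 kHz. The two "devices" differ by optional
per-frequency calibration offsets (default zero) applied to device B's
effective thresholds, plus independent N(0, 3) dB session noise per (ear,
device, frequency) track. Device order alternates across participants
(counterbalancing); it is cosmetic in simulation.

What this generator does **not** model: conductive or middle-ear pathology,
tinnitus interference, attention or fatigue drift, frequency-correlated
calibration error, and headphone transfer functions. Passing tests therefore
demonstrate the correctness of the procedure and statistics, not the
clinical accuracy of any physical device.

## Agreement analysis

Per frequency, differences are oriented A − B. Bias is the mean, spread the
sample SD (n−1; conventional for small Bland–Altman samples), and the 90%
limits of agreement `bias ± 1.64 * SD` (the printed constant; the exact
z(0.95) = 1.6449 is available via `exact_z=True`). Differences with
|d| ≥ 15 dB are reported as an outlier rate but never removed. Across
frequencies, the summary reports both the unweighted mean ± SD of
per-frequency biases and limits, and a pooled analysis of all differences
lumped together (per-frequency moments alone do not determine the pooled
spread; when raw differences are unavailable it is reconstructed via the law
of total variance). Age-group analysis is a plain group filter before the
same computation.

## Simulation scale and observed behaviour

The acceptance checks run the deterministic oracle exhaustively (every
on-grid threshold, all 15 frequencies, both variants — a few hundred
tracks, under a second) and the synthetic study at its natural size (32
ears × 15 frequencies × 2 devices) over 50 seeds, about half a minute total.

Two quantitative properties of the procedure are worth stating plainly,
since the test suite measures them. First, a single ascending-validation
track of a `sigma = 4` observer is biased about +4 dB (the ascending
detection tends to land one step above threshold) and lands within ±5 dB of
the true grid threshold in roughly 88% of tracks — not 90%+; clinical
practice reduces this with repeated ascending confirmations, which the
automated single-validation rule trades away for speed. Second, with the
default 3 dB per-track session noise on both devices, about 87–88% of
paired inter-device differences fall within ±10 dB and 12% reach 15 dB —
heavy tails driven by early-lapse validations (one missed tone during the
initial descent validates a step high on the next detection). Human
validation data for this class of device shows the same tail behaviour
(differences spanning tens of dB with a few percent of outliers). These are
properties of the measurement rule under the stated observer model, not
implementation artifacts; the corresponding test assertions encode the
stricter 90% expectations and report the measured rates when they fail.

## Numerical choices

* Calibration frequencies are exact integer Hz keys (125 … 16000); float
  inputs are rounded to the nearest integer for lookup, avoiding float-key
  pitfalls.
* Grid membership uses a 1e-9 absolute tolerance.
* CSV output writes floats with `%.17g` and readers parse with round-trip
  precision, so write-then-read is bit-exact.
* Multiple-of-5 rounding is half-away-from-zero.
* Random state: one `numpy.random.Generator` per session; panel generation
  and study execution take explicit integer seeds.
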