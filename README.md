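# aupiometry

Automated pure-tone audiometry without hardware: calibrated tone-burst
synthesis, a Hughson–Westlake adaptive staircase covering standard and
extended high frequencies (125 Hz – 16 kHz), simulated psychometric
listeners, and Bland–Altman agreement analysis between paired audiograms.

The package is written for hearing researchers and engineers who build or
validate self-administered audiometers. It reproduces the software core of a
touchscreen audiometer — the dB HL ↔ digital-amplification ↔ dB SPL
calibration mapping, the beep-train stimulus, and the automated threshold
track with its device-specific validation rules — and pairs it with a
simulated-listener harness so the whole measurement chain can be exercised
and statistically validated on a desk, with no audio hardware and no
participants.

## The procedure

A pure-tone threshold at frequency *f* is tracked with the Hughson–Westlake
limits method. The stimulus is a train of five gated beeps (50 ms fade-in,
200 ms plateau, 50 ms fade-out, 100 ms pause; 2000 ms total). The track
starts at 40 dB HL; a detected tone lowers the next level by 10 dB, a miss
raises it by 5 dB. A change of direction is an inversion. When the track
opens descending (first tone heard), the threshold is validated after two
inversions — an omission then a correct detection. When it opens ascending,
the ELIOS variant validates on the first correct detection (one inversion)
while the AUPIOMETER variant requires three inversions (a second ascending
detection). A miss at the loudest presentable level records that level
plus 5 dB with `ceiling` status.

Levels map to the digital domain through a per-frequency calibration table:
the amplification presenting *L* dB HL is `A0(f) + L`, where `A0(f)` is the
reference amplification for 0 dB HL, and the expected coupler SPL is
`RETSPL(f) + L`. Amplification spans 5–100 dB in 5-dB steps (0 dB is exact
digital silence, 100 dB full scale), which fixes the measurable range per
frequency.

Agreement between two devices measured on the same ears is summarized per
frequency with Bland–Altman statistics: bias *d̄* (mean of paired
differences), sample SD *s*, and 90% limits of agreement *d̄ ± 1.64 s*.

## Worked example

Measure a simulated mildly presbycusic ear (flat 10 dB HL, rising above
8 kHz) with the default AUPIOMETER procedure:

```python
from aupiometry import (ListenerModel, ProcedureConfig, default_table,
                        run_session)

table = default_table()
true_thresholds = {f: 10.0 for f in table.frequencies_hz}
true_thresholds.update({10000: 30.0, 12500: 40.0, 14000: 50.0, 16000: 60.0})

listener = ListenerModel(true_threshold_hl=true_thresholds)  # sigma = 4 dB
audiogram = run_session(listener, ProcedureConfig(), table, rng=7)
for f in sorted(audiogram):
    r = audiogram[f]
    print(f"{f:>6} Hz  {r.threshold_hl:>5.0f} dB HL  {r.status.value:<9} "
          f"({r.n_trials} trials)")
```

```
   125 Hz     15 dB HL  validated (5 trials)
   250 Hz     15 dB HL  validated (5 trials)
   500 Hz     15 dB HL  validated (5 trials)
   750 Hz     15 dB HL  validated (5 trials)
  1000 Hz     15 dB HL  validated (8 trials)
  1500 Hz     15 dB HL  validated (5 trials)
  2000 Hz     15 dB HL  validated (5 trials)
  3000 Hz     20 dB HL  validated (9 trials)
  4000 Hz     15 dB HL  validated (5 trials)
  6000 Hz     15 dB HL  validated (5 trials)
  8000 Hz     15 dB HL  validated (5 trials)
 10000 Hz     35 dB HL  validated (3 trials)
 12500 Hz     45 dB HL  validated (5 trials)
 14000 Hz     45 dB HL  validated (5 trials)
 16000 Hz     55 dB HL  ceiling   (3 trials)
```

The stochastic observer (psychometric spread 4 dB, 1% guesses, 2% lapses)
lands on or one 5-dB step above its true thresholds — the expected behaviour
of a single ascending-validation track. At 16 kHz the true threshold (60 dB
HL) exceeds the loudest presentable level (50 dB HL, set by the 50 dB
reference amplification), so the device records the ceiling value 55 dB HL.

The same pipeline from the shell:

```bash
aupiometry table --default                 # print the packaged calibration table
aupiometry stimulus --freq 1000 --level-hl 40 --out tone.wav
aupiometry run-sim --seed 1 --out session/ # one simulated session, both ears
aupiometry study --seed 1 --out study/     # 16 participants x 2 ears x 2 devices
aupiometry agreement study/ --out study/analysis --plot
```

`study` writes `paired_audiograms.csv` (long format); `agreement` reports
per-frequency bias, SD and 90% limits of agreement, an across-frequency
summary, and the fraction of differences ≥ 15 dB in magnitude.

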