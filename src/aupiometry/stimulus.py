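"""Tone-burst train synthesis.

The audiometric stimulus is a train of five gated sine beeps. Each beep has a
50 ms fade-in, a 200 ms plateau, a 50 ms fade-out, and a 100 ms silent pause,
giving 400 ms per beep and 2000 ms for the default five-beep train. Fades use
raised-cosine (Hann-flank) gating by default — the standard audiometric
choice, which bounds spectral splatter — with linear fades available via the
spec. The sine phase restarts at 0 at each beep onset so renders are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["StimulusSpec", "StimulusWaveform", "total_duration_ms", "render", "write_wav"]


@dataclass(frozen=True)
class StimulusSpec:
    """Timing and level parameters of a beep train."""

    frequency_hz: float
    amplitude: float = 1.0
    n_beeps: int = 5
    fade_in_ms: float = 50.0
    plateau_ms: float = 200.0
    fade_out_ms: float = 50.0
    pause_ms: float = 100.0
    sample_rate_hz: int = 48000
    fade_shape: str = "raised_cosine"  # or "linear"

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")
        if self.n_beeps < 0:
            raise ValueError("n_beeps must be non-negative")
        for name in ("fade_in_ms", "plateau_ms", "fade_out_ms", "pause_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fade_shape not in ("raised_cosine", "linear"):
            raise ValueError(f"unknown fade shape {self.fade_shape!r}")


@dataclass(frozen=True)
class StimulusWaveform:
    """A rendered stimulus: samples in [-1, 1] plus its provenance."""

    samples: np.ndarray
    sample_rate_hz: int
    spec: StimulusSpec

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate_hz


def total_duration_ms(spec: StimulusSpec) -> float:
    """Nominal train duration: n_beeps x (fade_in + plateau + fade_out + pause)."""
    return spec.n_beeps * (
        spec.fade_in_ms + spec.plateau_ms + spec.fade_out_ms + spec.pause_ms
    )


def _n_samples(duration_ms: float, rate: int) -> int:
    return int(round(duration_ms * rate / 1000.0))


def _fade(n: int, shape: str, rising: bool) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    t = np.arange(n) / n  # 0 ... just below 1; never reaches full scale mid-fade
    if shape == "linear":
        ramp = t
    else:
        ramp = 0.5 * (1.0 - np.cos(np.pi * t))
    return ramp if rising else ramp[::-1]


def render(spec: StimulusSpec) -> StimulusWaveform:
    """Render the beep train as a sampled waveform.

    Each beep is a zero-phase sine at ``spec.frequency_hz`` scaled by
    ``spec.amplitude`` and multiplied by the gating envelope; pauses are
    exact zeros. Sample counts are rounded per segment.
    """
    if spec.frequency_hz >= spec.sample_rate_hz / 2:
        raise ValueError(
            f"frequency {spec.frequency_hz} Hz is at or above Nyquist "
            f"({spec.sample_rate_hz / 2} Hz)"
        )
    rate = spec.sample_rate_hz
    n_in = _n_samples(spec.fade_in_ms, rate)
    n_plateau = _n_samples(spec.plateau_ms, rate)
    n_out = _n_samples(spec.fade_out_ms, rate)
    n_pause = _n_samples(spec.pause_ms, rate)

    envelope = np.concatenate(
        [
            _fade(n_in, spec.fade_shape, rising=True),
            np.ones(n_plateau),
            _fade(n_out, spec.fade_shape, rising=False),
        ]
    )
    n_tone = len(envelope)
    t = np.arange(n_tone) / rate
    beep = spec.amplitude * np.sin(2 * np.pi * spec.frequency_hz * t) * envelope
    one_cycle = np.concatenate([beep, np.zeros(n_pause)])
    samples = np.tile(one_cycle, spec.n_beeps)
    return StimulusWaveform(samples=samples, sample_rate_hz=rate, spec=spec)


def write_wav(waveform: StimulusWaveform, path: str | Path) -> None:
    """Export mono 32-bit IEEE-float PCM WAV."""
    from scipy.io import wavfile

    wavfile.write(
        str(path), waveform.sample_rate_hz, waveform.samples.astype(np.float32)
    )
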