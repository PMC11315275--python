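"""Simulated psychometric observers and a two-device study emulator.

A :class:`ListenerModel` answers each presentation stochastically through a
psychometric function

    P(press) = guess + (1 - guess - lapse) * F((L - T) / sigma)

where ``T`` is the true threshold at the test frequency, ``sigma`` the
psychometric spread in dB, and ``F`` the cumulative normal (default) or
logistic. Press latencies are log-normal; a press later than the stimulus
duration is scored downstream as a miss ("too late"), so late-press behaviour
emerges from the latency distribution rather than a separate parameter.
``sigma = 0`` with zero guess/lapse gives the deterministic step observer
(press iff level >= threshold) used as the staircase oracle.

:func:`generate_panel` emulates the validation study's population: a panel of
participants (two ears each) split into a young group with flat near-0 dB HL
hearing and an elderly group adding high-frequency loss that ramps above
10 kHz up to ~65 dB HL at 16 kHz. Normal-hearing ears are resampled until
all 250 Hz - 8 kHz thresholds are below 25 dB HL, the study's inclusion
criterion. :func:`run_two_device_study` then measures every ear on two
simulated devices that differ by per-frequency calibration offsets plus
independent per-session noise, producing the paired audiograms the agreement
analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import CalibrationTable
from .staircase import DEFAULT_FREQUENCY_ORDER_HZ, ProcedureConfig, run_session

__all__ = [
    "ListenerModel",
    "PanelSpec",
    "PanelMember",
    "deterministic_listener",
    "generate_panel",
    "run_two_device_study",
]


@dataclass(frozen=True)
class ListenerModel:
    """Psychometric-function observer.

    Parameters
    ----------
    true_threshold_hl : mapping frequency (Hz) -> threshold (dB HL)
    slope_db : psychometric spread sigma in dB; 0 means a step function.
    guess_rate, lapse_rate : floor and 1-ceiling of the psychometric curve.
    latency_median_ms, latency_sigma_log : log-normal press-latency
        parameters (median and log-space sigma).
    shape : "normal" (cumulative Gaussian) or "logistic".
    """

    true_threshold_hl: Mapping[float, float]
    slope_db: float = 4.0
    guess_rate: float = 0.01
    lapse_rate: float = 0.02
    latency_median_ms: float = 600.0
    latency_sigma_log: float = 0.35
    shape: str = "normal"

    def __post_init__(self) -> None:
        if self.slope_db < 0:
            raise ValueError("slope_db must be non-negative")
        if not (0 <= self.guess_rate < 1 and 0 <= self.lapse_rate < 1):
            raise ValueError("guess and lapse rates must lie in [0, 1)")
        if self.guess_rate + self.lapse_rate >= 1:
            raise ValueError("guess_rate + lapse_rate must be < 1")
        if self.shape not in ("normal", "logistic"):
            raise ValueError(f"unknown psychometric shape {self.shape!r}")

    def threshold_at(self, frequency_hz: float) -> float:
        key = int(round(frequency_hz))
        for f, t in self.true_threshold_hl.items():
            if int(round(f)) == key:
                return float(t)
        raise KeyError(f"listener has no threshold at {frequency_hz} Hz")

    def detection_probability(self, level_hl: float, frequency_hz: float) -> float:
        """P(press) at a level, before the late-press window is applied."""
        t = self.threshold_at(frequency_hz)
        if self.slope_db == 0:
            core = 1.0 if level_hl >= t else 0.0
        else:
            x = (level_hl - t) / self.slope_db
            if self.shape == "normal":
                core = float(norm.cdf(x))
            else:
                core = float(1.0 / (1.0 + np.exp(-x)))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core

    def respond(
        self, level_hl: float, frequency_hz: float, rng: np.random.Generator
    ) -> tuple[bool, float]:
        """Simulate one trial: (pressed, latency_ms).

        The caller scores a press later than the stimulus duration as a miss.
        """
        p = self.detection_probability(level_hl, frequency_hz)
        pressed = bool(rng.uniform() < p)
        latency = float(
            self.latency_median_ms
            * np.exp(self.latency_sigma_log * rng.standard_normal())
        )
        return pressed, latency

    # run_track expects a plain callable
    __call__ = respond

    def shifted(self, offsets_db: Mapping[float, float]) -> "ListenerModel":
        """Copy with per-frequency offsets added to the true thresholds."""
        new = {
            f: t + float(offsets_db.get(int(round(f)), offsets_db.get(f, 0.0)))
            for f, t in self.true_threshold_hl.items()
        }
        return ListenerModel(
            true_threshold_hl=new,
            slope_db=self.slope_db,
            guess_rate=self.guess_rate,
            lapse_rate=self.lapse_rate,
            latency_median_ms=self.latency_median_ms,
            latency_sigma_log=self.latency_sigma_log,
            shape=self.shape,
        )


def deterministic_listener(
    true_threshold_hl: Mapping[float, float] | float,
    frequencies_hz: Sequence[float] = DEFAULT_FREQUENCY_ORDER_HZ,
    latency_ms: float = 500.0,
) -> ListenerModel:
    """Step-function observer: presses iff level >= threshold, fixed latency."""
    if not isinstance(true_threshold_hl, Mapping):
        true_threshold_hl = {f: float(true_threshold_hl) for f in frequencies_hz}
    return ListenerModel(
        true_threshold_hl=dict(true_threshold_hl),
        slope_db=0.0,
        guess_rate=0.0,
        lapse_rate=0.0,
        latency_median_ms=latency_ms,
        latency_sigma_log=0.0,
    )


#: Frequencies the normal-hearing inclusion criterion applies to.
NORMAL_HEARING_BAND_HZ: tuple[int, ...] = (
    250, 500, 750, 1000, 1500, 2000, 3000, 4000, 6000, 8000,
)


@dataclass(frozen=True)
class PanelSpec:
    """Study-panel generator settings.

    Defaults emulate the validation study: 16 participants (32 ears) split
    into young and elderly groups (7 / 9), all clinically normal-hearing from
    250 Hz to 8 kHz, the elderly adding extended-high-frequency loss of up to
    65 dB HL at 14-16 kHz. Device B differs from device A by per-frequency
    calibration offsets plus i.i.d. per-track session noise.
    """

    n_participants: int = 16
    n_young: int = 7
    frequencies_hz: tuple[int, ...] = DEFAULT_FREQUENCY_ORDER_HZ
    normal_mean_hl: float = 5.0
    normal_sd_hl: float = 5.0
    normal_max_hl: float = 25.0
    ehf_loss_min_hl: float = 20.0
    ehf_loss_max_hl: float = 65.0
    device_offset_db: Mapping[int, float] = field(default_factory=dict)
    session_noise_sd_db: float = 3.0
    listener_slope_db: float = 4.0
    listener_guess_rate: float = 0.01
    listener_lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.n_young <= self.n_participants:
            raise ValueError("n_young must lie in [0, n_participants]")


#: Fraction of the elderly ear's 16 kHz loss applied at each ramp frequency.
_EHF_RAMP: dict[int, float] = {10000: 0.2, 12500: 0.5, 14000: 0.8, 16000: 1.0}


@dataclass(frozen=True)
class PanelMember:
    participant_id: int
    ear: str  # "left" | "right"
    group: str  # "young" | "elderly"
    listener: ListenerModel
    device_order: tuple[str, str]  # counterbalanced ("A","B") or ("B","A")


def _sample_ear_thresholds(
    spec: PanelSpec, group: str, rng: np.random.Generator
) -> dict[int, float]:
    band = [f for f in spec.frequencies_hz if f in NORMAL_HEARING_BAND_HZ]
    for _ in range(1000):
        base = {
            f: float(
                5.0 * np.round(rng.normal(spec.normal_mean_hl, spec.normal_sd_hl) / 5.0)
            )
            for f in spec.frequencies_hz
        }
        if all(base[f] < spec.normal_max_hl for f in band):
            break
    else:  # pragma: no cover - astronomically unlikely with defaults
        raise RuntimeError("could not sample a normal-hearing ear")
    if group == "elderly":
        loss_16k = float(rng.uniform(spec.ehf_loss_min_hl, spec.ehf_loss_max_hl))
        for f, frac in _EHF_RAMP.items():
            if f in base:
                base[f] = float(
                    5.0 * np.round((base[f] + frac * loss_16k) / 5.0)
                )
    return base


def generate_panel(spec: PanelSpec, seed: int) -> list[PanelMember]:
    """Sample the study panel reproducibly: 2 ears per participant.

    True thresholds are drawn on the 5-dB grid; device order alternates
    across participants (counterbalancing).
    """
    rng = np.random.default_rng(seed)
    members: list[PanelMember] = []
    for pid in range(spec.n_participants):
        group = "young" if pid < spec.n_young else "elderly"
        order = ("A", "B") if pid % 2 == 0 else ("B", "A")
        for ear in ("left", "right"):
            thresholds = _sample_ear_thresholds(spec, group, rng)
            listener = ListenerModel(
                true_threshold_hl=thresholds,
                slope_db=spec.listener_slope_db,
                guess_rate=spec.listener_guess_rate,
                lapse_rate=spec.listener_lapse_rate,
            )
            members.append(
                PanelMember(
                    participant_id=pid,
                    ear=ear,
                    group=group,
                    listener=listener,
                    device_order=order,
                )
            )
    return members


def run_two_device_study(
    panel: Sequence[PanelMember],
    config_a: ProcedureConfig,
    config_b: ProcedureConfig,
    table: CalibrationTable,
    seed: int,
    spec: PanelSpec | None = None,
) -> pd.DataFrame:
    """Measure every ear with both devices; return long-format audiograms.

    Device B applies ``spec.device_offset_db`` to each ear's effective
    thresholds; both devices add independent N(0, session_noise_sd) noise per
    (ear, device, frequency) track. Columns: participant, ear, group, device,
    frequency_hz, threshold_hl, status, n_trials.
    """
    spec = spec if spec is not None else PanelSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for member in panel:
        for device, config in (("A", config_a), ("B", config_b)):
            offsets = dict(spec.device_offset_db) if device == "B" else {}
            effective = member.listener
            if offsets:
                effective = effective.shifted(offsets)
            if spec.session_noise_sd_db > 0:
                noise = {
                    f: float(rng.normal(0.0, spec.session_noise_sd_db))
                    for f in effective.true_threshold_hl
                }
                effective = effective.shifted(noise)
            session = run_session(effective, config, table, rng)
            for freq, result in session.items():
                rows.append(
                    {
                        "participant": member.participant_id,
                        "ear": member.ear,
                        "group": member.group,
                        "device": device,
                        "frequency_hz": freq,
                        "threshold_hl": result.threshold_hl,
                        "status": result.status.value,
                        "n_trials": result.n_trials,
                    }
                )
    return pd.DataFrame(rows)
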