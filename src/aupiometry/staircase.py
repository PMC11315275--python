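"""Automated Hughson-Westlake threshold tracking.

The track starts at 40 dB HL. A detected tone lowers the next presentation by
10 dB; a miss (no press, or a press after the stimulus ends) raises it by
5 dB. A change of direction is an inversion. How many inversions validate the
threshold depends on how the track opens and on the device variant:

* first trial detected (level starts descending): two inversions — an
  omission then a correct detection — validate, for both variants;
* first trial missed (level starts ascending): the ELIOS variant validates on
  the first correct detection (one inversion), while the AUPIOMETER variant
  requires three inversions, i.e. a second ascending detection, to
  double-validate.

The validated threshold is the level of the detection that completes the
required inversion count — the ascending detection level, per standard
Hughson-Westlake practice. A miss at the loudest presentable level terminates
the track at the ceiling (recorded as that level plus the 5 dB bonus); a
repeated detection pinned at the quietest presentable level terminates at the
floor. Trials are separated by a uniformly random 2000-4000 ms pause.

The state machine is pure: it never touches audio or wall-clock time, so the
same logic drives simulated listeners and (in principle) live hardware.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .calibration import (
    CalibrationTable,
    LevelRange,
    hl_to_amplification,
    measurable_range,
)
from .stimulus import StimulusSpec, total_duration_ms

__all__ = [
    "Variant",
    "Direction",
    "TrackStatus",
    "ProcedureConfig",
    "TrialRecord",
    "StaircaseState",
    "ThresholdResult",
    "next_level",
    "update",
    "run_track",
    "run_session",
]

#: Standard and extended-high-frequency test order: 1 kHz first, ascending
#: through the high frequencies, then the low frequencies descending.
DEFAULT_FREQUENCY_ORDER_HZ: tuple[int, ...] = (
    1000, 1500, 2000, 3000, 4000, 6000, 8000,
    10000, 12500, 14000, 16000, 750, 500, 250, 125,
)


class Variant(enum.Enum):
    """Device procedure variant."""

    AUPIOMETER = "aupiometer"
    ELIOS = "elios"


class Direction(enum.Enum):
    NONE = "none"
    DOWN = "down"
    UP = "up"


class TrackStatus(enum.Enum):
    RUNNING = "running"
    VALIDATED = "validated"
    CEILING = "ceiling"
    FLOOR = "floor"
    ABORTED = "aborted"


class StaircaseStateError(RuntimeError):
    """Raised on an update after the track reached a terminal status."""


@dataclass(frozen=True)
class ProcedureConfig:
    """Parameters of the adaptive procedure.

    ``inversions_ascending_start`` defaults per variant (3 for AUPIOMETER,
    1 for ELIOS) when left as None. ``stop_on_press`` mirrors whether the
    device truncates the stimulus on a button press (ELIOS) or plays it out
    (AUPIOMETER); it affects simulated trial timing only, never the level
    sequencing.
    """

    variant: Variant = Variant.AUPIOMETER
    start_level_hl: float = 40.0
    step_down_db: float = 10.0
    step_up_db: float = 5.0
    iti_min_ms: float = 2000.0
    iti_max_ms: float = 4000.0
    inversions_descending_start: int = 2
    inversions_ascending_start: int | None = None
    stop_on_press: bool | None = None
    max_trials: int = 50
    frequency_order_hz: tuple[int, ...] = DEFAULT_FREQUENCY_ORDER_HZ

    def __post_init__(self) -> None:
        if self.step_down_db <= 0 or self.step_up_db <= 0:
            raise ValueError("step sizes must be positive")
        if self.iti_min_ms > self.iti_max_ms:
            raise ValueError("iti_min_ms must not exceed iti_max_ms")
        if self.inversions_descending_start < 1:
            raise ValueError("inversion counts must be >= 1")
        if self.inversions_ascending_start is None:
            object.__setattr__(
                self,
                "inversions_ascending_start",
                3 if self.variant is Variant.AUPIOMETER else 1,
            )
        if self.inversions_ascending_start < 1:
            raise ValueError("inversion counts must be >= 1")
        if self.stop_on_press is None:
            object.__setattr__(
                self, "stop_on_press", self.variant is Variant.ELIOS
            )


class FirstTrialOutcome(enum.Enum):
    UNSET = "unset"
    DETECTED = "detected"
    MISSED = "missed"


@dataclass(frozen=True)
class TrialRecord:
    """One presentation and its outcome.

    ``response`` is the scored outcome: a press after the stimulus ends is
    scored False (a "late press") but keeps its latency for the log.
    """

    trial_index: int
    level_hl: float
    response: bool
    latency_ms: float | None = None
    iti_ms: float = 0.0
    presented: bool = True


@dataclass
class StaircaseState:
    """Mutable track state; one-way transitions out of RUNNING."""

    level_range: LevelRange
    ceiling_bonus_db: float = 5.0
    current_level_hl: float = 40.0
    direction: Direction = Direction.NONE
    inversion_count: int = 0
    first_trial_outcome: FirstTrialOutcome = FirstTrialOutcome.UNSET
    status: TrackStatus = TrackStatus.RUNNING
    threshold_hl: float | None = None
    history: list[TrialRecord] = field(default_factory=list)
    _min_detections: int = 0  # consecutive detections pinned at the floor

    @property
    def presentable_max_hl(self) -> float:
        return self.level_range.max_hl - self.ceiling_bonus_db

    @property
    def presentable_min_hl(self) -> float:
        return self.level_range.min_hl


def _clip(level: float, state: StaircaseState) -> float:
    return min(max(level, state.presentable_min_hl), state.presentable_max_hl)


def next_level(state: StaircaseState, config: ProcedureConfig) -> float:
    """Level for the next presentation given the last scored response.

    Down 10 dB after a detection, up 5 dB after a miss, clipped to the
    presentable bounds. Before any trial, returns the (clipped) start level.
    """
    if state.status is not TrackStatus.RUNNING:
        raise StaircaseStateError(f"track already terminal: {state.status}")
    if not state.history:
        return _clip(config.start_level_hl, state)
    last = state.history[-1]
    if last.response:
        proposed = last.level_hl - config.step_down_db
    else:
        proposed = last.level_hl + config.step_up_db
    return _clip(proposed, state)


def _required_inversions(state: StaircaseState, config: ProcedureConfig) -> int:
    if state.first_trial_outcome is FirstTrialOutcome.DETECTED:
        return config.inversions_descending_start
    return config.inversions_ascending_start


def update(
    state: StaircaseState, trial: TrialRecord, config: ProcedureConfig
) -> StaircaseState:
    """Record a trial and advance the track state (mutates and returns it)."""
    if state.status is not TrackStatus.RUNNING:
        raise StaircaseStateError(f"update after terminal status {state.status}")

    state.history.append(trial)
    state.current_level_hl = trial.level_hl

    if state.first_trial_outcome is FirstTrialOutcome.UNSET:
        state.first_trial_outcome = (
            FirstTrialOutcome.DETECTED if trial.response else FirstTrialOutcome.MISSED
        )

    new_direction = Direction.DOWN if trial.response else Direction.UP
    inverted = (
        state.direction is not Direction.NONE and new_direction is not state.direction
    )
    if inverted:
        state.inversion_count += 1
    state.direction = new_direction

    # Terminal checks, in priority order.
    if trial.response and state.inversion_count >= _required_inversions(state, config):
        state.status = TrackStatus.VALIDATED
        state.threshold_hl = trial.level_hl
        return state
    if not trial.response and trial.level_hl >= state.presentable_max_hl:
        state.status = TrackStatus.CEILING
        state.threshold_hl = state.level_range.max_hl
        return state
    if trial.response and trial.level_hl <= state.presentable_min_hl:
        state._min_detections += 1
        if state._min_detections >= 2:
            state.status = TrackStatus.FLOOR
            state.threshold_hl = state.level_range.min_hl
            return state
    else:
        state._min_detections = 0
    if len(state.history) >= config.max_trials:
        state.status = TrackStatus.ABORTED
        state.threshold_hl = None
    return state


@dataclass(frozen=True)
class ThresholdResult:
    """Validated (or terminated) threshold for one frequency."""

    frequency_hz: int
    threshold_hl: float | None
    status: TrackStatus
    n_trials: int


def run_track(
    listener: Callable[[float, float, np.random.Generator], tuple[bool, float]],
    frequency_hz: int,
    config: ProcedureConfig,
    table: CalibrationTable,
    rng: np.random.Generator,
    collect_trials: list | None = None,
) -> ThresholdResult:
    """Drive one adaptive track against a listener callback.

    ``listener(level_hl, frequency_hz, rng) -> (pressed, latency_ms)``; a
    press with latency beyond the stimulus duration is scored as a miss (the
    "too late" rule) with the latency kept in the log. Inter-trial intervals
    are drawn uniformly from [iti_min, iti_max] with the session generator.
    ``collect_trials``, if given, receives (frequency_hz, TrialRecord,
    amplification_db) tuples for trial-log export.
    """
    rng_range = measurable_range(table, frequency_hz)
    state = StaircaseState(level_range=rng_range, ceiling_bonus_db=table.ceiling_bonus_db)
    window_ms = total_duration_ms(StimulusSpec(frequency_hz=float(frequency_hz)))

    while state.status is TrackStatus.RUNNING:
        level = next_level(state, config)
        amplification = hl_to_amplification(table, frequency_hz, level)
        pressed, latency_ms = listener(level, float(frequency_hz), rng)
        scored = bool(pressed) and latency_ms <= window_ms
        iti = float(rng.uniform(config.iti_min_ms, config.iti_max_ms))
        trial = TrialRecord(
            trial_index=len(state.history),
            level_hl=level,
            response=scored,
            latency_ms=float(latency_ms) if pressed else None,
            iti_ms=iti,
        )
        update(state, trial, config)
        if collect_trials is not None:
            collect_trials.append((frequency_hz, trial, amplification))

    return ThresholdResult(
        frequency_hz=int(frequency_hz),
        threshold_hl=state.threshold_hl,
        status=state.status,
        n_trials=len(state.history),
    )


def run_session(
    listener: Callable[[float, float, np.random.Generator], tuple[bool, float]],
    config: ProcedureConfig,
    table: CalibrationTable,
    rng: np.random.Generator | int,
    collect_trials: list | None = None,
) -> dict[int, ThresholdResult]:
    """Run tracks over the configured frequency order; deterministic per seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    results: dict[int, ThresholdResult] = {}
    for freq in config.frequency_order_hz:
        results[freq] = run_track(
            listener, freq, config, table, rng, collect_trials=collect_trials
        )
    return results
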