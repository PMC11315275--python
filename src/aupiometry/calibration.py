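"""Audiometric calibration: RETSPL table and level conversions.

An audiometer presents tones at a nominal hearing level (dB HL). Internally
the device only controls a digital amplification ``A`` in dB, where ``A = 0``
is digital silence and ``A = 100`` is full scale. The calibration table links
the two: for each test frequency it stores

* the reference amplification ``A0`` that produces 0 dB HL, so that a level
  of ``L`` dB HL is presented at amplification ``A0 + L``;
* the RETSPL (Reference Equivalent Threshold Sound Pressure Level), the
  coupler SPL corresponding to 0 dB HL, so the expected SPL at ``L`` dB HL
  is ``RETSPL + L``.

The packaged default table covers 15 frequencies from 125 Hz to 16 kHz for a
circumaural headphone. Three high/low-frequency rows (125 Hz, 14 kHz, 16 kHz)
could not be driven to the usual 70 dB HL calibration point before digital
saturation; their RETSPLs are extrapolated from the SPL measured at maximum
amplification and carry ``extrapolated=True``.

The measurable range in dB HL follows from the amplification limits: the
quietest presentable tone uses the minimum non-zero amplification (5 dB by
default) and the loudest uses the maximum (100 dB). When a listener fails to
respond at the loudest presentable level the recorded threshold is that level
plus a 5 dB ceiling bonus, so the recordable maximum exceeds the presentable
maximum by 5 dB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd

__all__ = [
    "CalibrationEntry",
    "CalibrationTable",
    "LevelRange",
    "UnknownFrequencyError",
    "LevelRangeError",
    "default_table",
    "hl_to_amplification",
    "amplification_to_hl",
    "hl_to_spl",
    "amplification_to_amplitude",
    "measurable_range",
    "estimate_retspl_from_ceiling",
    "adjust_calibration",
    "round_to_multiple_of_5",
]


class UnknownFrequencyError(KeyError):
    """Raised when a frequency is not present in the calibration table."""


class LevelRangeError(ValueError):
    """Raised when a requested level maps outside the amplification grid."""


@dataclass(frozen=True)
class CalibrationEntry:
    """Calibration constants for one test frequency.

    Parameters
    ----------
    frequency_hz : int
        Test frequency in Hz (exact integer key, e.g. 125 ... 16000).
    retspl_db_spl : float
        Coupler SPL corresponding to 0 dB HL.
    ref_amplification_db : float
        Digital amplification (dB) that presents 0 dB HL.
    extrapolated : bool
        True when the RETSPL was extrapolated from the output at maximum
        amplification because 70 dB HL was unreachable before saturation.
    """

    frequency_hz: int
    retspl_db_spl: float
    ref_amplification_db: float
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency_hz}")
        if not 5.0 <= self.ref_amplification_db <= 100.0:
            raise ValueError(
                "reference amplification must lie in [5, 100] dB, got "
                f"{self.ref_amplification_db}"
            )


@dataclass(frozen=True)
class LevelRange:
    """Measurable hearing-level interval in dB HL.

    ``max_hl`` includes the +5 dB ceiling recording bonus, so the loudest
    *presentable* level is ``max_hl - ceiling_bonus``.
    """

    min_hl: float
    max_hl: float

    def __post_init__(self) -> None:
        if not self.min_hl < self.max_hl:
            raise ValueError(f"empty level range [{self.min_hl}, {self.max_hl}]")

    def contains(self, level_hl: float) -> bool:
        return self.min_hl <= level_hl <= self.max_hl


# Packaged default: per-frequency RETSPL (dB SPL), reference amplification
# for 0 dB HL (dB), extrapolation flag. Rows 125/14000/16000 saturate before
# the 70 dB HL calibration point.
_DEFAULT_ROWS: tuple[tuple[int, float, float, bool], ...] = (
    (125, 37.2, 35.0, True),
    (250, 19.6, 30.0, False),
    (500, 12.5, 20.0, False),
    (750, 7.4, 15.0, False),
    (1000, 7.5, 15.0, False),
    (1500, 6.1, 15.0, False),
    (2000, 7.9, 15.0, False),
    (3000, 6.3, 15.0, False),
    (4000, -3.9, 15.0, False),
    (6000, 22.8, 20.0, False),
    (8000, 23.0, 15.0, False),
    (10000, 27.5, 25.0, False),
    (12500, 26.7, 25.0, False),
    (14000, 33.3, 35.0, True),
    (16000, 52.8, 50.0, True),
)


@dataclass(frozen=True)
class CalibrationTable:
    """Ordered per-frequency calibration entries plus amplification limits."""

    entries: tuple[CalibrationEntry, ...]
    amp_min_db: float = 5.0
    amp_max_db: float = 100.0
    amp_step_db: float = 5.0
    ceiling_bonus_db: float = 5.0
    _by_freq: Mapping[int, CalibrationEntry] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if self.amp_min_db <= 0:
            raise ValueError("amp_min_db must be positive")
        if self.amp_max_db <= self.amp_min_db:
            raise ValueError("amp_max_db must exceed amp_min_db")
        span = self.amp_max_db - self.amp_min_db
        if abs(span / self.amp_step_db - round(span / self.amp_step_db)) > 1e-9:
            raise ValueError("amp_step_db must divide amp_max_db - amp_min_db")
        by_freq = {e.frequency_hz: e for e in self.entries}
        if len(by_freq) != len(self.entries):
            raise ValueError("duplicate frequencies in calibration table")
        object.__setattr__(self, "_by_freq", by_freq)

    @property
    def frequencies_hz(self) -> tuple[int, ...]:
        return tuple(e.frequency_hz for e in self.entries)

    def entry(self, frequency_hz: float) -> CalibrationEntry:
        key = int(round(frequency_hz))
        try:
            return self._by_freq[key]
        except KeyError:
            raise UnknownFrequencyError(
                f"{frequency_hz} Hz is not in the calibration table "
                f"(known: {sorted(self._by_freq)})"
            ) from None

    def __contains__(self, frequency_hz: float) -> bool:
        return int(round(frequency_hz)) in self._by_freq

    # -- serialization -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": [e.frequency_hz for e in self.entries],
                "retspl_db_spl": [e.retspl_db_spl for e in self.entries],
                "ref_amplification_db": [e.ref_amplification_db for e in self.entries],
                "extrapolated_flag": [e.extrapolated for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **limits) -> "CalibrationTable":
        required = {
            "frequency_hz",
            "retspl_db_spl",
            "ref_amplification_db",
            "extrapolated_flag",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
        entries = tuple(
            CalibrationEntry(
                frequency_hz=int(row.frequency_hz),
                retspl_db_spl=float(row.retspl_db_spl),
                ref_amplification_db=float(row.ref_amplification_db),
                extrapolated=bool(row.extrapolated_flag),
            )
            for row in df.itertuples()
        )
        return cls(entries=entries, **limits)

    @classmethod
    def from_csv(cls, path, **limits) -> "CalibrationTable":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"), **limits)


def default_table() -> CalibrationTable:
    """Return the packaged 15-frequency default calibration table."""
    return CalibrationTable(
        entries=tuple(CalibrationEntry(f, r, a, x) for f, r, a, x in _DEFAULT_ROWS)
    )


def _on_grid(value: float, origin: float, step: float) -> bool:
    k = (value - origin) / step
    return abs(k - round(k)) < 1e-9


def hl_to_amplification(
    table: CalibrationTable, frequency_hz: float, level_hl: float
) -> float:
    """Digital amplification (dB) presenting ``level_hl`` at ``frequency_hz``.

    ``amplification = ref_amplification + level_hl``. The result must land on
    the amplification grid within [amp_min, amp_max]; otherwise a
    :class:`LevelRangeError` names the violated bound.
    """
    entry = table.entry(frequency_hz)
    amp = entry.ref_amplification_db + level_hl
    if amp < table.amp_min_db - 1e-9:
        raise LevelRangeError(
            f"{level_hl} dB HL at {entry.frequency_hz} Hz needs amplification "
            f"{amp} dB below the minimum {table.amp_min_db} dB"
        )
    if amp > table.amp_max_db + 1e-9:
        raise LevelRangeError(
            f"{level_hl} dB HL at {entry.frequency_hz} Hz needs amplification "
            f"{amp} dB above the maximum {table.amp_max_db} dB"
        )
    if not _on_grid(amp, table.amp_min_db, table.amp_step_db):
        raise LevelRangeError(
            f"amplification {amp} dB is off the {table.amp_step_db}-dB grid"
        )
    return float(amp)


def amplification_to_hl(
    table: CalibrationTable, frequency_hz: float, amplification_db: float
) -> float:
    """Inverse of :func:`hl_to_amplification`."""
    entry = table.entry(frequency_hz)
    return float(amplification_db - entry.ref_amplification_db)


def hl_to_spl(table: CalibrationTable, frequency_hz: float, level_hl: float) -> float:
    """Expected coupler SPL for a nominal hearing level: ``RETSPL + HL``."""
    entry = table.entry(frequency_hz)
    return float(entry.retspl_db_spl + level_hl)


def amplification_to_amplitude(
    amplification_db: float, amp_max_db: float = 100.0
) -> float:
    """Map digital amplification in dB to a linear digital amplitude.

    ``amp_max_db`` (full scale) maps to exactly 1 and 0 dB is special-cased
    to exact digital silence — the log map alone would give 1e-5, not 0.
    Between those, ``10 ** ((A - amp_max) / 20)``.
    """
    if amplification_db < 0:
        raise LevelRangeError(f"negative amplification {amplification_db} dB")
    if amplification_db > amp_max_db:
        raise LevelRangeError(
            f"amplification {amplification_db} dB exceeds full scale {amp_max_db} dB"
        )
    if amplification_db == 0:
        return 0.0
    return float(10.0 ** ((amplification_db - amp_max_db) / 20.0))


def measurable_range(table: CalibrationTable, frequency_hz: float) -> LevelRange:
    """Recordable hearing-level interval at a frequency.

    The minimum is the level presented at the minimum non-zero amplification;
    the maximum is the level at maximum amplification plus the ceiling bonus
    recorded when a listener fails to respond at the loudest presentable tone.
    Both bounds land on the amplification grid by construction.
    """
    entry = table.entry(frequency_hz)
    return LevelRange(
        min_hl=float(table.amp_min_db - entry.ref_amplification_db),
        max_hl=float(
            table.amp_max_db - entry.ref_amplification_db + table.ceiling_bonus_db
        ),
    )


def estimate_retspl_from_ceiling(
    measured_spl_at_max: float,
    ref_amplification_db: float,
    amp_max_db: float = 100.0,
) -> float:
    """Extrapolate a RETSPL from the SPL measured at maximum amplification.

    Used for frequencies where the usual 70 dB HL calibration point exceeds
    full scale: the hearing level reachable at ``amp_max`` is
    ``amp_max - ref_amplification``, and subtracting it from the measured SPL
    recovers the SPL of 0 dB HL.
    """
    if not 5.0 <= ref_amplification_db <= amp_max_db:
        raise ValueError(
            f"reference amplification {ref_amplification_db} dB out of bounds"
        )
    return float(measured_spl_at_max - (amp_max_db - ref_amplification_db))


def round_to_multiple_of_5(value: float) -> float:
    """Nearest multiple of 5, ties rounded away from zero."""
    return math.copysign(5.0 * math.floor(abs(value) / 5.0 + 0.5), value)


def adjust_calibration(
    table: CalibrationTable, per_frequency_mean_diff_db: Mapping[int, float]
) -> CalibrationTable:
    """Shift reference amplifications by per-frequency mean differences.

    Each frequency's mean inter-device threshold difference is rounded to the
    nearest multiple of 5 dB (the amplification step) and added to that
    frequency's reference amplification; differences rounding to 0 leave the
    entry untouched. The caller chooses the orientation of the differences —
    pass the shift that should be *applied* (negate measured deviations if the
    correction must oppose them). Returns a new table; the original is
    unchanged.
    """
    diffs = {int(round(f)): float(d) for f, d in per_frequency_mean_diff_db.items()}
    if set(diffs) != set(table.frequencies_hz):
        raise ValueError(
            "mean differences must cover exactly the table's frequencies; "
            f"got {sorted(diffs)} vs {sorted(table.frequencies_hz)}"
        )
    new_entries = []
    for entry in table.entries:
        shift = round_to_multiple_of_5(diffs[entry.frequency_hz])
        if shift == 0:
            new_entries.append(entry)
        else:
            new_entries.append(
                replace(entry, ref_amplification_db=entry.ref_amplification_db + shift)
            )
    return replace(table, entries=tuple(new_entries))
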