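"""Readers and writers for audiograms, trial logs, panels and configs.

All text outputs are comma-separated UTF-8 with "." decimals and a header
row; dB values keep full precision (repr round-trip), so write-then-read is
bit-exact. Audiograms also serialize to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .agreement import PairedMeasurements, paired_from_long
from .calibration import CalibrationTable, measurable_range
from .staircase import ThresholdResult, TrackStatus, TrialRecord

__all__ = [
    "SessionMetadata",
    "audiogram_to_dataframe",
    "write_audiogram_csv",
    "write_audiogram_json",
    "read_audiogram_csv",
    "write_trial_log_csv",
    "read_paired_audiograms",
    "load_config",
]


@dataclass(frozen=True)
class SessionMetadata:
    """Provenance of one measurement session; seed recorded for every run."""

    participant_id: str
    ear: str
    device_variant: str
    seed: int
    timestamp: str
    config_digest: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def audiogram_to_dataframe(
    audiogram: Mapping[int, ThresholdResult], ear: str = "unspecified"
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ear": ear,
            "frequency_hz": [r.frequency_hz for r in audiogram.values()],
            "threshold_hl": [r.threshold_hl for r in audiogram.values()],
            "status": [r.status.value for r in audiogram.values()],
            "n_trials": [r.n_trials for r in audiogram.values()],
        }
    )


def write_audiogram_csv(
    audiogram: Mapping[int, ThresholdResult], path: str | Path, ear: str = "unspecified"
) -> None:
    audiogram_to_dataframe(audiogram, ear).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_audiogram_json(
    audiogram: Mapping[int, ThresholdResult], path: str | Path, ear: str = "unspecified"
) -> None:
    payload = {
        "ear": ear,
        "thresholds": [
            {
                "frequency_hz": r.frequency_hz,
                "threshold_hl": r.threshold_hl,
                "status": r.status.value,
                "n_trials": r.n_trials,
            }
            for r in audiogram.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_audiogram_csv(path: str | Path) -> dict[int, ThresholdResult]:
    df = pd.read_csv(path, float_precision="round_trip")
    return {
        int(row.frequency_hz): ThresholdResult(
            frequency_hz=int(row.frequency_hz),
            threshold_hl=None if pd.isna(row.threshold_hl) else float(row.threshold_hl),
            status=TrackStatus(row.status),
            n_trials=int(row.n_trials),
        )
        for row in df.itertuples()
    }


def write_trial_log_csv(
    trials: Sequence[tuple[int, TrialRecord, float]],
    path: str | Path,
    ear: str = "unspecified",
) -> None:
    """Trial log: ear, frequency, index, level, amplification, outcome, timing."""
    df = pd.DataFrame(
        {
            "ear": ear,
            "frequency_hz": [f for f, _, _ in trials],
            "trial_index": [t.trial_index for _, t, _ in trials],
            "level_hl": [t.level_hl for _, t, _ in trials],
            "amplification_db": [a for _, _, a in trials],
            "response": [t.response for _, t, _ in trials],
            "latency_ms": [t.latency_ms for _, t, _ in trials],
            "iti_ms": [t.iti_ms for _, t, _ in trials],
        }
    )
    # %.17g guarantees a bit-exact float round-trip through the text file
    df.to_csv(path, index=False, float_format="%.17g")


def read_paired_audiograms(
    path: str | Path, table: CalibrationTable | None = None
) -> list[PairedMeasurements]:
    """Load and validate a long-format paired audiogram CSV.

    Checks required columns, duplicate (participant, ear, device, frequency)
    rows, and — when a calibration table is given — that every threshold lies
    within its frequency's measurable range. Row order is irrelevant.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    required = {"participant", "ear", "device", "frequency_hz", "threshold_hl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    keys = ["participant", "ear", "device", "frequency_hz"]
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (participant, ear, device, frequency) rows at "
            f"index {df.index[dup].tolist()}"
        )
    if table is not None:
        bad_rows = []
        for idx, row in df.iterrows():
            if pd.isna(row.threshold_hl):
                continue
            rng = measurable_range(table, row.frequency_hz)
            if not rng.contains(float(row.threshold_hl)):
                bad_rows.append(
                    f"row {idx}: {row.threshold_hl} dB HL at {row.frequency_hz} Hz "
                    f"outside [{rng.min_hl}, {rng.max_hl}]"
                )
        if bad_rows:
            raise ValueError(f"{path}: out-of-range thresholds:\n" + "\n".join(bad_rows))
    return paired_from_long(df)


def load_config(path: str | Path) -> dict:
    """Flat key-value config (YAML); returns an empty dict for empty files."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return data
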