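"""Bland-Altman agreement between paired audiograms.

For each frequency, the paired per-ear thresholds from two devices (or a
test-retest pair) are reduced to differences d = A - B. The bias is the mean
difference, its spread the sample (n-1) standard deviation, and the 90%
limits of agreement lie 1.64 standard deviations on either side of the bias —
the interval expected to contain 90% of future paired differences under
normality. ``k`` may instead be the exact z(0.95) = 1.6449 via
``exact_z=True``. Differences at or beyond a 15 dB cutoff are reported as an
outlier rate but never removed, to avoid biasing the bias.

Per-frequency results aggregate across frequencies two ways: the unweighted
mean +/- SD of per-frequency biases and limits, and a pooled analysis of all
differences regardless of frequency (the across-frequency summary alone does
not determine how per-frequency SDs combine; both views are reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "AgreementSummary",
    "bland_altman",
    "summarize_across_frequencies",
    "outlier_rate",
    "paired_from_long",
    "agreement_by_frequency",
    "plot_bland_altman",
]

LOA_K_90 = 1.64  # 90% limits-of-agreement multiplier


class InsufficientDataError(ValueError):
    """Fewer than two pairs: the SD of differences is undefined."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired thresholds at one frequency: (ear_id, value_A, value_B)."""

    frequency_hz: float
    pairs: tuple[tuple[str, float, float], ...]

    @property
    def differences(self) -> np.ndarray:
        return np.array([a - b for _, a, b in self.pairs], dtype=float)


@dataclass(frozen=True)
class AgreementResult:
    """Per-frequency Bland-Altman statistics (differences oriented A - B)."""

    frequency_hz: float
    bias_db: float
    sd_db: float
    loa_low_db: float
    loa_high_db: float
    k: float
    n: int
    orientation: str = "A-B"

    def summary(self) -> str:
        return (
            f"{self.frequency_hz:g} Hz: bias {self.bias_db:+.2f} dB "
            f"(SD {self.sd_db:.2f}), LoA [{self.loa_low_db:.2f}, "
            f"{self.loa_high_db:.2f}] dB, n={self.n}"
        )


def _loa_k(k: float | None, exact_z: bool) -> float:
    if k is not None:
        return float(k)
    return float(norm.ppf(0.95)) if exact_z else LOA_K_90


def bland_altman(
    paired: PairedMeasurements | Sequence[float],
    k: float | None = None,
    exact_z: bool = False,
    frequency_hz: float = float("nan"),
) -> AgreementResult:
    """Bias, SD and limits of agreement of paired differences.

    Accepts either a :class:`PairedMeasurements` or a raw difference sequence.
    ``k`` defaults to 1.64 (90% limits); ``exact_z=True`` uses z(0.95).
    """
    if isinstance(paired, PairedMeasurements):
        diffs = paired.differences
        frequency_hz = paired.frequency_hz
    else:
        diffs = np.asarray(paired, dtype=float)
    if diffs.size < 2:
        raise InsufficientDataError(
            f"need >= 2 pairs for an SD, got {diffs.size}"
        )
    kk = _loa_k(k, exact_z)
    if kk <= 0:
        raise ValueError("k must be positive")
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return AgreementResult(
        frequency_hz=float(frequency_hz),
        bias_db=bias,
        sd_db=sd,
        loa_low_db=bias - kk * sd,
        loa_high_db=bias + kk * sd,
        k=kk,
        n=int(diffs.size),
    )


@dataclass(frozen=True)
class AgreementSummary:
    """Across-frequency aggregation of per-frequency Bland-Altman results.

    ``mean_*``/``sd_*`` are the unweighted mean and (n-1) SD over frequencies;
    ``pooled`` re-runs the analysis on all differences lumped together.
    """

    mean_bias_db: float
    sd_bias_db: float
    mean_loa_low_db: float
    sd_loa_low_db: float
    mean_loa_high_db: float
    sd_loa_high_db: float
    n_frequencies: int
    pooled: AgreementResult

    def summary(self) -> str:
        return (
            f"across {self.n_frequencies} frequencies: "
            f"bias {self.mean_bias_db:+.2f} ± {self.sd_bias_db:.2f} dB, "
            f"LoA low {self.mean_loa_low_db:.2f} ± {self.sd_loa_low_db:.2f}, "
            f"LoA high {self.mean_loa_high_db:.2f} ± {self.sd_loa_high_db:.2f}; "
            f"pooled bias {self.pooled.bias_db:+.2f} "
            f"(SD {self.pooled.sd_db:.2f}, n={self.pooled.n})"
        )


def summarize_across_frequencies(
    results: Sequence[AgreementResult],
    all_differences: Sequence[float] | None = None,
) -> AgreementSummary:
    """Unweighted mean +/- SD of per-frequency biases and limits.

    ``all_differences`` feeds the pooled analysis; if omitted it cannot be
    reconstructed from the per-frequency moments alone, so per-frequency
    means weighted by n are pooled as an approximation of the lumped bias
    with the between+within spread combined via the law of total variance.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 frequencies to summarize")
    biases = np.array([r.bias_db for r in results])
    lows = np.array([r.loa_low_db for r in results])
    highs = np.array([r.loa_high_db for r in results])
    if all_differences is not None:
        pooled = bland_altman(list(all_differences), k=results[0].k)
    else:
        ns = np.array([r.n for r in results], dtype=float)
        sds = np.array([r.sd_db for r in results])
        gmean = float(np.sum(ns * biases) / np.sum(ns))
        # within + between variance, (n-1)-style pooling
        ss = np.sum((ns - 1) * sds**2) + np.sum(ns * (biases - gmean) ** 2)
        sd = float(np.sqrt(ss / (np.sum(ns) - 1)))
        k = results[0].k
        pooled = AgreementResult(
            frequency_hz=float("nan"),
            bias_db=gmean,
            sd_db=sd,
            loa_low_db=gmean - k * sd,
            loa_high_db=gmean + k * sd,
            k=k,
            n=int(np.sum(ns)),
        )
    return AgreementSummary(
        mean_bias_db=float(np.mean(biases)),
        sd_bias_db=float(np.std(biases, ddof=1)),
        mean_loa_low_db=float(np.mean(lows)),
        sd_loa_low_db=float(np.std(lows, ddof=1)),
        mean_loa_high_db=float(np.mean(highs)),
        sd_loa_high_db=float(np.std(highs, ddof=1)),
        n_frequencies=len(results),
        pooled=pooled,
    )


def outlier_rate(all_differences: Sequence[float], cutoff_db: float = 15.0) -> float:
    """Fraction of differences with |d| >= cutoff (reported, never removed)."""
    diffs = np.asarray(all_differences, dtype=float)
    if diffs.size == 0:
        raise ValueError("no differences supplied")
    return float(np.mean(np.abs(diffs) >= cutoff_db))


def paired_from_long(df: pd.DataFrame) -> list[PairedMeasurements]:
    """Group a long-format paired audiogram table by frequency.

    Expects columns participant, ear, device (A/B), frequency_hz,
    threshold_hl; rows with a missing threshold (e.g. aborted tracks) are
    dropped pairwise.
    """
    required = {"participant", "ear", "device", "frequency_hz", "threshold_hl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: list[PairedMeasurements] = []
    for freq, g in df.groupby("frequency_hz", sort=True):
        wide = g.pivot_table(
            index=["participant", "ear"],
            columns="device",
            values="threshold_hl",
            aggfunc="first",
        )
        if not {"A", "B"}.issubset(wide.columns):
            raise ValueError(f"frequency {freq}: need both devices A and B")
        wide = wide.dropna(subset=["A", "B"])
        pairs = tuple(
            (f"{pid}-{ear}", float(row["A"]), float(row["B"]))
            for (pid, ear), row in wide.iterrows()
        )
        out.append(PairedMeasurements(frequency_hz=float(freq), pairs=pairs))
    return out


def agreement_by_frequency(
    df: pd.DataFrame, k: float | None = None, exact_z: bool = False
) -> pd.DataFrame:
    """Per-frequency Bland-Altman table from a long-format paired dataset."""
    results = [
        bland_altman(pm, k=k, exact_z=exact_z) for pm in paired_from_long(df)
    ]
    return pd.DataFrame(
        {
            "frequency_hz": [r.frequency_hz for r in results],
            "n": [r.n for r in results],
            "bias_db": [r.bias_db for r in results],
            "sd_db": [r.sd_db for r in results],
            "loa_low_db": [r.loa_low_db for r in results],
            "loa_high_db": [r.loa_high_db for r in results],
            "k": [r.k for r in results],
        }
    )


def plot_bland_altman(paired: Sequence[PairedMeasurements], path=None):
    """Panel of Bland-Altman plots, one per frequency: points, bias, limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(paired)
    ncols = 5
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 2.5 * nrows), squeeze=False
    )
    for ax, pm in zip(axes.flat, paired):
        res = bland_altman(pm)
        means = [(a + b) / 2 for _, a, b in pm.pairs]
        diffs = pm.differences
        ax.scatter(means, diffs, s=12, alpha=0.7)
        ax.axhline(res.bias_db, color="k", lw=1)
        ax.axhline(res.loa_low_db, color="k", lw=1, ls="--")
        ax.axhline(res.loa_high_db, color="k", lw=1, ls="--")
        ax.set_title(
            f"{pm.frequency_hz / 1000:g} kHz: {res.bias_db:+.1f} ± {res.sd_db:.1f} dB",
            fontsize=9,
        )
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.supxlabel("mean of devices (dB HL)")
    fig.supylabel("difference A - B (dB)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
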