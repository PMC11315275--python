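"""Hughson-Westlake staircase: traces, the closed-form oracle, termination."""

import math

import numpy as np
import pytest

from aupiometry import (
    ProcedureConfig,
    TrackStatus,
    Variant,
    deterministic_listener,
    measurable_range,
    run_session,
    run_track,
)
from aupiometry.staircase import (
    StaircaseState,
    StaircaseStateError,
    TrialRecord,
    next_level,
    update,
)


def track_levels(threshold, freq, variant, table):
    """Run a deterministic-listener track and return its presented levels."""
    trials = []
    listener = deterministic_listener(threshold)
    cfg = ProcedureConfig(variant=variant)
    result = run_track(listener, freq, cfg, table, np.random.default_rng(0),
                       collect_trials=trials)
    return result, [(t.level_hl, t.response) for _, t, _ in trials]


def oracle_threshold(true_t, freq, table):
    """Closed-form expectation for a step-function listener.

    The ascending detection lands on the next 5-dB grid point at or above the
    true threshold; listeners below the floor or above the loudest
    presentable level terminate at the range bounds.
    """
    r = measurable_range(table, freq)
    presentable_max = r.max_hl - table.ceiling_bonus_db
    grid_t = 5 * math.ceil(true_t / 5)
    if grid_t <= r.min_hl:
        return r.min_hl, TrackStatus.FLOOR if true_t <= r.min_hl else TrackStatus.VALIDATED
    if grid_t > presentable_max:
        return r.max_hl, TrackStatus.CEILING
    return grid_t, TrackStatus.VALIDATED


class TestHandTraces:
    def test_descending_start_double_inversion(self, table):
        """T=20: detect 40/30/20, miss 10, miss 15, detect 20 validates."""
        result, levels = track_levels(20, 1000, Variant.AUPIOMETER, table)
        assert levels == [(40, True), (30, True), (20, True),
                         (10, False), (15, False), (20, True)]
        assert result.status is TrackStatus.VALIDATED
        assert result.threshold_hl == 20

    def test_ascending_start_aupiometer_triple_inversion(self, table):
        result, levels = track_levels(50, 1000, Variant.AUPIOMETER, table)
        assert levels == [(40, False), (45, False), (50, True),
                         (40, False), (45, False), (50, True)]
        assert result.threshold_hl == 50

    def test_ascending_start_elios_single_inversion(self, table):
        result, levels = track_levels(50, 1000, Variant.ELIOS, table)
        assert levels == [(40, False), (45, False), (50, True)]
        assert result.threshold_hl == 50

    def test_never_responding_listener_hits_ceiling(self, table, config):
        result, levels = track_levels(10_000, 1000, config.variant, table)
        assert result.status is TrackStatus.CEILING
        assert result.threshold_hl == 90  # presentable max 85 plus the 5 dB bonus
        assert levels[-1] == (85, False)

    def test_floor_below_range(self, table, config):
        result, _ = track_levels(-100, 1000, config.variant, table)
        assert result.status is TrackStatus.FLOOR
        assert result.threshold_hl == -10


class TestOracleEquivalence:
    def test_every_grid_threshold_every_frequency_both_variants(self, table, config):
        """Brute force: the staircase equals the closed-form oracle for every
        on-grid threshold inside the presentable range, at all frequencies."""
        for freq in table.frequencies_hz:
            r = measurable_range(table, freq)
            for t in np.arange(r.min_hl, r.max_hl - table.ceiling_bonus_db + 5, 5):
                expected, _ = oracle_threshold(float(t), freq, table)
                result, _ = track_levels(float(t), freq, config.variant, table)
                assert result.threshold_hl == expected, (freq, t)

    @pytest.mark.parametrize("true_t", [-12.3, -7.5, 3, 17.2, 23, 41.01, 86.2, 99])
    def test_off_grid_thresholds_round_up(self, table, config, true_t):
        expected, status = oracle_threshold(true_t, 1000, table)
        result, _ = track_levels(true_t, 1000, config.variant, table)
        assert result.threshold_hl == expected
        assert result.status is status

    def test_monotone_in_true_threshold(self, table, config):
        measured = [
            track_levels(t, 2000, config.variant, table)[0].threshold_hl
            for t in np.arange(-15, 95, 2.5)
        ]
        assert all(a <= b for a, b in zip(measured, measured[1:]))


class TestVariantDifference:
    def test_variants_identical_when_first_trial_detected(self, table):
        """With a detected first trial both variants need two inversions, so
        the whole trial sequence matches."""
        for t in np.arange(-10, 45, 5):
            _, lv_a = track_levels(float(t), 1000, Variant.AUPIOMETER, table)
            _, lv_e = track_levels(float(t), 1000, Variant.ELIOS, table)
            assert lv_a == lv_e

    def test_variants_differ_only_after_first_miss(self, table):
        diffs = []
        for t in np.arange(45, 90, 5):
            _, lv_a = track_levels(float(t), 1000, Variant.AUPIOMETER, table)
            _, lv_e = track_levels(float(t), 1000, Variant.ELIOS, table)
            assert lv_e == lv_a[: len(lv_e)]  # ELIOS stops at the first detection
            diffs.append(len(lv_a) - len(lv_e))
        assert all(d == 3 for d in diffs)  # one extra down-up-up cycle


class TestStateMachine:
    def test_update_after_terminal_raises(self, table, config):
        state = StaircaseState(level_range=measurable_range(table, 1000))
        state.status = TrackStatus.VALIDATED
        with pytest.raises(StaircaseStateError):
            update(state, TrialRecord(0, 40, True), config)
        with pytest.raises(StaircaseStateError):
            next_level(state, config)

    def test_levels_stay_presentable_and_validated_ends_on_detection(self, table, config):
        rng = np.random.default_rng(7)
        from aupiometry import ListenerModel

        listener = ListenerModel(
            true_threshold_hl={1000: 30.0}, slope_db=8, guess_rate=0.05, lapse_rate=0.05
        )
        r = measurable_range(table, 1000)
        for _ in range(20):
            trials = []
            result = run_track(listener, 1000, config, table, rng,
                               collect_trials=trials)
            levels = [t.level_hl for _, t, _ in trials]
            assert all(r.min_hl <= lv <= r.max_hl - table.ceiling_bonus_db
                       for lv in levels)
            if result.status is TrackStatus.VALIDATED:
                assert trials[-1][1].response

    def test_late_press_scored_as_miss(self, table, config):
        def slow_listener(level, freq, rng):
            return True, 3000.0  # presses, but after the 2000 ms stimulus

        result = run_track(slow_listener, 1000, config, table,
                           np.random.default_rng(0))
        assert result.status is TrackStatus.CEILING

    def test_abort_cap(self, table):
        flip = {"v": False}

        def oscillator(level, freq, rng):
            flip["v"] = not flip["v"]
            return flip["v"], 500.0

        cfg = ProcedureConfig(max_trials=9, inversions_descending_start=99,
                              inversions_ascending_start=99)
        result = run_track(oscillator, 1000, cfg, table, np.random.default_rng(0))
        assert result.status is TrackStatus.ABORTED
        assert result.n_trials == 9
        assert result.threshold_hl is None


class TestSession:
    def test_flat_threshold_covers_all_frequencies(self, table, config):
        audiogram = run_session(deterministic_listener(5), config, table, rng=0)
        assert set(audiogram) == set(config.frequency_order_hz)
        assert all(r.threshold_hl == 5 for r in audiogram.values())

    def test_frequency_order_preserved(self, table, config):
        audiogram = run_session(deterministic_listener(5), config, table, rng=0)
        assert tuple(audiogram) == config.frequency_order_hz
        assert audiogram[1000].frequency_hz == 1000

    def test_same_seed_same_audiogram(self, table, config):
        from aupiometry import ListenerModel

        listener = ListenerModel(true_threshold_hl={f: 10.0 for f in
                                                    config.frequency_order_hz})
        a = run_session(listener, config, table, rng=42)
        b = run_session(listener, config, table, rng=42)
        assert a == b

    def test_iti_within_bounds(self, table, config):
        trials = []
        run_session(deterministic_listener(10), config, table, rng=3,
                    collect_trials=trials)
        itis = [t.iti_ms for _, t, _ in trials]
        assert all(config.iti_min_ms <= iti <= config.iti_max_ms for iti in itis)
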