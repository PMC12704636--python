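"""Label algebra: binarization, arousal overlay, transition correction,
rasterization and standalone smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnoseg import (ArousalEvents, ContinuousHypnogram, ContractError,
                      EpochHypnogram, GridLabels, ProbabilityTrack,
                      ValidationError, build_labels, expand_grid,
                      grid_to_intervals, heuristic_correction,
                      incorporate_arousals, rasterize, smooth_standalone,
                      stages_to_binary)
from somnoseg.hypnogram import SLEEP, WAKE_LIKE


def _sleep_grid(n_seconds, onset=0.0):
    return GridLabels(np.zeros(n_seconds, dtype=np.uint8), 1, onset)


class TestStagesToBinary:
    def test_mapping_rule(self):
        out = stages_to_binary(EpochHypnogram(("W", "N2", "REM", "W")))
        assert np.array_equal(out.labels, [1, 0, 0, 1])
        assert out.resolution_s == 30

    def test_all_sleep_night(self):
        out = stages_to_binary(EpochHypnogram(("N3",) * 16))
        assert not out.labels.any()

    def test_matches_lookup_oracle(self, rng):
        stages = tuple(rng.choice(["W", "N1", "N2", "N3", "REM"], size=200))
        out = stages_to_binary(EpochHypnogram(stages))
        oracle = [1 if s == "W" else 0 for s in stages]
        assert np.array_equal(out.labels, oracle)

    def test_unknown_stage_names_index(self):
        with pytest.raises(ValidationError, match="index 2"):
            stages_to_binary(EpochHypnogram(("W", "N2", "SLEEPY")))


class TestExpandGrid:
    def test_replication(self):
        out = expand_grid(GridLabels([1, 0], 30), 1)
        assert out.labels.size == 60
        assert out.labels[:30].all() and not out.labels[30:].any()

    def test_identity(self):
        g = GridLabels([1, 0, 1], 10)
        assert np.array_equal(expand_grid(g, 10).labels, g.labels)

    def test_non_divisible_rejected(self):
        with pytest.raises(ContractError):
            expand_grid(GridLabels([1], 10), 3)

    def test_round_trip_through_majority_contraction(self, rng):
        g = GridLabels(rng.integers(0, 2, 40).astype(np.uint8), 30)
        fine = expand_grid(g, 1)
        coarse = fine.labels.reshape(-1, 30).mean(axis=1) >= 0.5
        assert np.array_equal(coarse.astype(np.uint8), g.labels)


class TestIncorporateArousals:
    def test_worked_overlay_scenario(self):
        # arousal [68, 87) on a 2-minute sleep hypnogram flips 19 cells
        out = incorporate_arousals(_sleep_grid(120), ArousalEvents(((68, 87),)))
        assert out.labels.sum() == 19
        assert out.labels[68:87].all()
        assert not out.labels[:68].any() and not out.labels[87:].any()

    def test_no_arousals_identity(self, rng):
        g = GridLabels(rng.integers(0, 2, 90).astype(np.uint8), 1)
        assert np.array_equal(incorporate_arousals(g, ArousalEvents(())).labels,
                              g.labels)

    def test_matches_per_second_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(60, 240))
            base = rng.integers(0, 2, n).astype(np.uint8)
            k = int(rng.integers(0, 4))
            onsets = np.sort(rng.uniform(0, n - 5, size=k))
            events, last = [], -np.inf
            for on in onsets:
                if on < last:
                    continue
                off = min(on + float(rng.uniform(0.5, 25)), float(n))
                events.append((on, off))
                last = off
            out = incorporate_arousals(GridLabels(base, 1),
                                       ArousalEvents(tuple(events)))
            oracle = base.copy()
            for t in range(n):  # cell [t, t+1): wake if any event overlaps
                if any(a < t + 1 and b > t for a, b in events):
                    oracle[t] = WAKE_LIKE
            assert np.array_equal(out.labels, oracle)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 1), min_size=30, max_size=120),
           st.integers(0, 100), st.integers(3, 25))
    def test_monotone_and_idempotent(self, base, onset, dur):
        n = len(base)
        g = GridLabels(np.array(base, dtype=np.uint8), 1)
        ev = ArousalEvents(((min(onset, n - 1), min(onset + dur, n),),))
        once = incorporate_arousals(g, ev)
        assert np.all(once.labels >= g.labels)  # never SLEEP-ward
        assert once.labels.sum() >= g.labels.sum()
        twice = incorporate_arousals(once, ev)
        assert np.array_equal(once.labels, twice.labels)

    def test_requires_one_second_grid(self):
        with pytest.raises(ContractError):
            incorporate_arousals(GridLabels([0, 1], 30), ArousalEvents(()))


class TestHeuristicCorrection:
    def _fig2_setup(self):
        epochs = EpochHypnogram(("N2", "N2", "W", "N2"))
        base = expand_grid(stages_to_binary(epochs), 1)
        return epochs, base

    def test_worked_transition_correction(self):
        epochs, base = self._fig2_setup()
        arousals = ArousalEvents(((68, 87),))
        labels = incorporate_arousals(base, arousals)
        out = heuristic_correction(labels, arousals, epochs)
        assert not out.labels[60:68].any()     # pre-arousal wake -> sleep
        assert out.labels[68:87].all()         # arousal span untouched
        assert out.labels[87:90].all()         # rest of the W epoch untouched

    def test_second_half_onset_leaves_epoch_unchanged(self):
        epochs, base = self._fig2_setup()
        arousals = ArousalEvents(((76, 87),))
        labels = incorporate_arousals(base, arousals)
        out = heuristic_correction(labels, arousals, epochs)
        assert np.array_equal(out.labels, labels.labels)

    def test_midpoint_onset_does_not_qualify(self):
        epochs, base = self._fig2_setup()
        arousals = ArousalEvents(((75, 87),))
        out = heuristic_correction(incorporate_arousals(base, arousals),
                                   arousals, epochs)
        assert out.labels[60:90].all()

    def test_wake_predecessor_blocks_correction(self):
        epochs = EpochHypnogram(("N2", "W", "W", "N2"))
        base = expand_grid(stages_to_binary(epochs), 1)
        arousals = ArousalEvents(((68, 73),))
        out = heuristic_correction(incorporate_arousals(base, arousals),
                                   arousals, epochs)
        assert out.labels[30:90].all()

    def test_only_cells_before_onset_in_wake_epochs_change(self, rng):
        for _ in range(30):
            stages = tuple(rng.choice(["W", "N2"], size=6))
            epochs = EpochHypnogram(stages)
            base = expand_grid(stages_to_binary(epochs), 1)
            k = int(rng.integers(1, 4))
            onsets = np.sort(rng.uniform(0, 170, size=k))
            events, last = [], -1.0
            for on in onsets:
                if on <= last:
                    continue
                off = min(on + float(rng.uniform(3, 20)), 180.0)
                events.append((float(on), off))
                last = off
            ar = ArousalEvents(tuple(events))
            labels = incorporate_arousals(base, ar)
            out = heuristic_correction(labels, ar, epochs)
            changed = np.flatnonzero(out.labels != labels.labels)
            for t in changed:
                e = t // 30
                assert stages[e] == "W" and e >= 1 and stages[e - 1] != "W"
                assert any(t < a for a, _b in events)  # strictly before an onset


class TestRasterize:
    def test_majority_with_tie_to_wake(self):
        cont = ContinuousHypnogram(((0, 45, SLEEP), (45, 90, WAKE_LIKE)))
        out = rasterize(cont, 30)
        assert np.array_equal(out.labels, [0, 1, 1])  # [30,60) is a 15/15 tie

    def test_exact_copy_at_integral_boundaries(self):
        cont = ContinuousHypnogram(((0, 3, SLEEP), (3, 7, WAKE_LIKE),
                                    (7, 10, SLEEP)))
        out = rasterize(cont, 1)
        assert np.array_equal(out.labels, [0, 0, 0, 1, 1, 1, 1, 0, 0, 0])

    def test_round_trip_with_intervals(self, rng):
        labels = rng.integers(0, 2, 50).astype(np.uint8)
        g = GridLabels(labels, 1)
        cont = grid_to_intervals(g)
        assert np.array_equal(rasterize(cont, 1).labels, labels)

    def test_duration_conserved_against_overlap_oracle(self, rng):
        bounds = np.sort(rng.uniform(0, 600, size=8))
        bounds = np.concatenate(([0.0], bounds, [600.0]))
        states = [(i % 2) for i in range(len(bounds) - 1)]
        cont = ContinuousHypnogram.from_intervals(
            [(a, b, s) for a, b, s in zip(bounds[:-1], bounds[1:], states)
             if b > a])
        for res in (1, 5, 30):
            out = rasterize(cont, res)
            # per-state duration differs from interval truth by at most one
            # resolution unit per state transition
            wake_cells = out.labels.sum() * res
            wake_true = cont.state_duration(WAKE_LIKE)
            n_trans = len(cont.intervals) - 1
            assert abs(wake_cells - wake_true) <= res * max(n_trans, 1)

    def test_commutes_with_trimming(self):
        cont = ContinuousHypnogram.from_intervals(
            [(0, 40, SLEEP), (40, 70, WAKE_LIKE), (70, 120, SLEEP)])
        full = rasterize(cont, 1)
        # crop the annotation to [30, 90) and rasterize the cropped version
        cropped = ContinuousHypnogram.from_intervals(
            [(max(a, 30.0), min(b, 90.0), s) for a, b, s in cont.intervals
             if b > 30.0 and a < 90.0])
        assert np.array_equal(rasterize(cropped, 1).labels, full.labels[30:90])


class TestGridToIntervals:
    def test_run_length_encoding(self):
        out = grid_to_intervals(GridLabels([0, 0, 1, 1, 0], 1))
        assert out.intervals == ((0.0, 2.0, SLEEP), (2.0, 4.0, WAKE_LIKE),
                                 (4.0, 5.0, SLEEP))

    def test_constant_grid_single_interval(self):
        out = grid_to_intervals(GridLabels(np.ones(40, dtype=np.uint8), 30))
        assert out.intervals == ((0.0, 1200.0, WAKE_LIKE),)


class TestSmoothStandalone:
    def test_low_confidence_standalone_flipped(self):
        labels = GridLabels([0, 0, 1, 0, 0], 1)
        probs = ProbabilityTrack([.1, .2, .6, .3, .1], 1)
        out = smooth_standalone(labels, probs)  # window mean 0.367 < 0.5
        assert np.array_equal(out.labels, [0, 0, 0, 0, 0])

    def test_high_confidence_standalone_expands_window(self):
        labels = GridLabels([0, 0, 1, 0, 0], 1)
        probs = ProbabilityTrack([.1, .45, .9, .5, .1], 1)
        out = smooth_standalone(labels, probs)  # window mean 0.617 >= 0.5
        assert np.array_equal(out.labels, [0, 1, 1, 1, 0])

    def test_no_standalone_identity(self, rng):
        labels = GridLabels([0, 0, 1, 1, 0, 0], 1)
        probs = ProbabilityTrack([.1, .2, .8, .9, .2, .1], 1)
        assert np.array_equal(smooth_standalone(labels, probs).labels,
                              labels.labels)

    def test_edits_confined_to_windows(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            labels = rng.integers(0, 2, n).astype(np.uint8)
            p = np.where(labels == 1, rng.uniform(0.5, 1, n),
                         rng.uniform(0, 0.5, n))
            g = GridLabels(labels, 1)
            out = smooth_standalone(g, ProbabilityTrack(p, 1))
            standalone = [t for t in range(1, n - 1)
                          if labels[t - 1] == labels[t + 1] != labels[t]]
            allowed = set()
            for t in standalone:
                allowed.update((t - 1, t, t + 1))
            changed = set(np.flatnonzero(out.labels != labels))
            assert changed <= allowed


class TestBuildLabels:
    def test_conventional_is_expanded_binarization(self):
        epochs = EpochHypnogram(("W", "N2", "N2"))
        out = build_labels(epochs, ArousalEvents(()), "conventional")
        assert np.array_equal(out.labels,
                              expand_grid(stages_to_binary(epochs), 1).labels)

    def test_modified_reproduces_worked_scenario(self):
        epochs = EpochHypnogram(("N2", "N2", "W", "N2"))
        out = build_labels(epochs, ArousalEvents(((68, 87),)), "modified")
        assert not out.labels[60:68].any()
        assert out.labels[68:87].all()
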