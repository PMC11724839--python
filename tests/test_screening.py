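"""Inclusion/exclusion rules and handrail tallying."""

import numpy as np
import pytest

import stumblekit as sk
from stumblekit.events import PerturbationRecord
from stumblekit.screening import (
    PerturbationScreen,
    ScreeningReport,
    check_marker_completeness,
    check_onset_phase,
    detect_handrail_grabs,
    exclude_warmup,
)


def _pert(ordinal, block=0, fraction=0.05):
    return PerturbationRecord(onset=10.0, limb="left", side="intact",
                              duration=0.8, onset_cycle_fraction=fraction,
                              block_index=block,
                              within_block_side_ordinal=ordinal)


class TestWarmup:
    def test_first_two_per_side_excluded(self):
        perts = [_pert(i) for i in range(1, 13)]
        flags = exclude_warmup(perts)
        assert flags == [True, True] + [False] * 10  # 10 retained of 12

    def test_all_excluded_when_only_two(self):
        assert exclude_warmup([_pert(1), _pert(2)]) == [True, True]

    def test_rule_applies_per_block(self):
        perts = [_pert(i, block=b) for b in (0, 1) for i in range(1, 6)]
        flags = exclude_warmup(perts)
        # 3 retained per block of 5
        assert sum(not f for f in flags) == 6


class TestOnsetPhase:
    @pytest.mark.parametrize("fraction,expected", [
        (0.0, True), (0.20, True), (0.21, False), (float("nan"), False)])
    def test_twenty_percent_boundary_inclusive(self, fraction, expected):
        assert check_onset_phase(_pert(3, fraction=fraction)) is expected


def _finger_trial(slow_start, slow_len, n=600, rate=100.0):
    """Fingers swinging at ~1 m/s except a slow stretch of given length."""
    t = np.arange(n) / rate
    markers = {}
    for name in ("L_FINGER", "R_FINGER"):
        x = 0.2 * np.sin(2 * np.pi * 0.8 * t)
        x[slow_start:slow_start + slow_len] = x[slow_start]
        # freeze: hold position => zero velocity
        x[slow_start + slow_len:] += (x[slow_start] -
                                      0.2 * np.sin(2 * np.pi * 0.8 * t[slow_start + slow_len]))
        markers[name] = np.stack([x, np.zeros(n), np.zeros(n)], axis=1)
    return sk.TrialRecording(
        markers=markers, marker_valid={k: np.ones(n, bool) for k in markers},
        marker_rate=rate, forces={"left": np.zeros((n * 10, 3)),
                                  "right": np.zeros((n * 10, 3))},
        force_rate=1000.0, belt_speed=np.ones(n * 10),
        meta=sk.TrialMeta(70.0, "inactive", 0.8))


class TestHandrailDetector:
    def test_sixty_millisecond_pause_is_a_grab(self):
        trial = _finger_trial(200, 7)  # 7 frames => 60 ms interval
        grabs = detect_handrail_grabs(trial, (1.0, 4.0))
        assert len(grabs) >= 1
        assert any(abs(a - 2.0) < 0.2 for a, _ in grabs)

    def test_forty_millisecond_pause_is_not(self):
        n, rate = 600, 100.0
        t = np.arange(n) / rate
        markers = {}
        for name in ("L_FINGER", "R_FINGER"):
            x = 1.0 * t  # constant 1 m/s
            x[200:204] = x[200]  # 4 frames => 30 ms interval < 50 ms
            markers[name] = np.stack([x, np.zeros(n), np.zeros(n)], axis=1)
        trial = _finger_trial(0, 0)
        trial.markers.update(markers)
        grabs = detect_handrail_grabs(trial, (1.5, 3.5))
        assert grabs == []

    def test_inserted_grabs_recovered_exactly(self, corrupted_batch):
        for cfg, trial, truth, ana in corrupted_batch:
            detected = {s.perturbation_index for s in ana.screening.rows
                        if s.handrail_grab}
            inserted = {g[2] for g in truth.handrail_grabs}
            assert detected == inserted


class TestCompleteness:
    def _trial_missing(self, frac, n=1000):
        trial = _finger_trial(0, 0, n=n)
        valid = np.ones(n, bool)
        valid[:int(round(frac * n))] = False
        trial.markers["C7"] = np.zeros((n, 3))
        trial.marker_valid["C7"] = valid
        return trial

    @pytest.mark.parametrize("frac,expected", [(0.0, True), (0.05, True),
                                               (0.051, False)])
    def test_five_percent_boundary(self, frac, expected):
        trial = self._trial_missing(frac)
        got = check_marker_completeness(trial, (0.0, 10.0), markers=("C7",))
        assert got is expected

    def test_dropout_injection_fails_completeness(self, corrupted_batch):
        for cfg, trial, truth, ana in corrupted_batch:
            dropped = {c[3] for c in truth.corrupted_segments if c[0] == "dropout"}
            for s in ana.screening.rows:
                assert s.kinematic_complete == (s.perturbation_index not in dropped)


class TestBeltSeparation:
    def test_clean_gait_passes_and_midline_fails(self, corrupted_batch):
        for cfg, trial, truth, ana in corrupted_batch:
            crossed = {c[3] for c in truth.corrupted_segments if c[0] == "midline"}
            for s in ana.screening.rows:
                assert s.kinetic_separated == (s.perturbation_index not in crossed)

    def test_exact_fifteen_percent_swing_passes(self):
        # one plate below 20 N for exactly 15 % of each 1 s cycle
        n = 4000
        trial = _finger_trial(0, 0, n=400)
        forces = {"left": np.full((n, 3), 0.0), "right": np.full((n, 3), 0.0)}
        forces["left"][:, 2] = 100.0
        forces["right"][:, 2] = 100.0
        for c in range(4):
            forces["left"][c * 1000:c * 1000 + 150, 2] = 0.0   # 15 % exactly
            forces["right"][c * 1000 + 500:c * 1000 + 900, 2] = 0.0
        trial.forces = forces
        events = sk.GaitEventTable(
            heel_strikes={"left": np.array([0.0, 1.0, 2.0, 3.0]),
                          "right": np.array([0.5, 1.5, 2.5, 3.5])},
            toe_offs={"left": np.array([0.6, 1.6, 2.6]),
                      "right": np.array([0.2, 1.2, 2.2])})
        ok = sk.check_belt_separation(trial, events, (0.0, 3.0), "left")
        assert ok is True
        # shave one percentage point below the bound -> fail
        trial.forces["left"][:140, 2] = 0.0
        trial.forces["left"][140:1000, 2] = 100.0
        assert sk.check_belt_separation(trial, events, (0.0, 3.0), "left") is False


class TestAggregation:
    def test_inclusion_truth_table(self):
        base = dict(perturbation_index=0, side="intact", snp_condition="active",
                    warmup_excluded=False, onset_phase_ok=True,
                    handrail_grab=False, kinematic_complete=True,
                    kinetic_separated=True)
        both = PerturbationScreen(**base)
        assert both.kinematic_included and both.kinetic_included
        grabbed = PerturbationScreen(**{**base, "handrail_grab": True})
        assert not grabbed.kinematic_included and not grabbed.kinetic_included
        kin_fail = PerturbationScreen(**{**base, "kinematic_complete": False})
        assert not kin_fail.kinematic_included and kin_fail.kinetic_included

    def test_handrail_tally_partitioned_by_side_and_condition(self, corrupted_batch):
        for cfg, trial, truth, ana in corrupted_batch:
            table = ana.screening.handrail_counts()
            for side in ("intact", "prosthetic"):
                expected = sum(1 for g in truth.handrail_grabs
                               if truth.perturbations[g[2]].side == side)
                assert table.loc[side, cfg.snp_condition] == expected
                assert table.loc[side, ("active" if cfg.snp_condition == "inactive"
                                        else "inactive")] == 0

    def test_included_set_matches_ground_truth_prediction(self, corrupted_batch):
        for cfg, trial, truth, ana in corrupted_batch:
            grabs = {g[2] for g in truth.handrail_grabs}
            drops = {c[3] for c in truth.corrupted_segments if c[0] == "dropout"}
            cross = {c[3] for c in truth.corrupted_segments if c[0] == "midline"}
            warm = {i for i, p in enumerate(ana.perturbations)
                    if p.within_block_side_ordinal <= 2}
            kin = {s.perturbation_index for s in ana.screening.rows
                   if s.kinematic_included}
            kin_expected = {i for i in range(len(ana.perturbations))
                            if i not in grabs | drops | warm}
            assert kin == kin_expected
            kinetic = {s.perturbation_index for s in ana.screening.rows
                       if s.kinetic_included}
            kinetic_expected = {i for i in range(len(ana.perturbations))
                                if i not in grabs | cross | warm}
            assert kinetic == kinetic_expected

    def test_threshold_relaxation_is_monotone(self, corrupted_batch):
        """Loosening any threshold never excludes a previously included trial."""
        cfg, trial, truth, ana = corrupted_batch[0]
        from stumblekit.pipeline import PipelineConfig, analyze_trial

        static = sk.generate_static_trial(cfg)
        strict = analyze_trial(trial, static, PipelineConfig())
        loose = analyze_trial(trial, static, PipelineConfig(
            max_missing_fraction=0.5, min_swing_fraction=0.01,
            onset_max_fraction=0.9, warmup_per_side=0))
        strict_in = {s.perturbation_index for s in strict.screening.rows
                     if s.kinematic_included}
        loose_in = {s.perturbation_index for s in loose.screening.rows
                    if s.kinematic_included}
        assert strict_in <= loose_in
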