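"""Synthetic-trial generator: closed-form checks and ground-truth oracles."""

import numpy as np
import pytest

import stumblekit as sk
from stumblekit.core import GRAVITY, ConfigError, SchedulingError


class TestStaticTrial:
    def test_mean_total_vertical_force_is_body_weight(self):
        cfg = sk.SimulationConfig(participant_mass=71.7, seed=1)
        static = sk.generate_static_trial(cfg)
        total = static.forces["left"][:, 2] + static.forces["right"][:, 2]
        assert total.mean() == pytest.approx(71.7 * GRAVITY, rel=1e-3)  # ~703.4 N
        # plates share the load evenly
        ratio = static.forces["left"][:, 2].mean() / total.mean()
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_noiseless_static_force_is_exact(self):
        cfg = sk.SimulationConfig(participant_mass=100.0, force_noise_sd=0.0, seed=1)
        static = sk.generate_static_trial(cfg)
        total = np.linalg.norm(static.forces["left"] + static.forces["right"], axis=1)
        assert np.allclose(total, 981.0)

    def test_stationarity_invariant(self):
        cfg = sk.SimulationConfig(seed=2)
        static = sk.generate_static_trial(cfg)
        mag = np.linalg.norm(static.forces["left"] + static.forces["right"], axis=1)
        assert mag.std() / mag.mean() < 0.02

    def test_invalid_mass_and_duration(self):
        with pytest.raises(ConfigError):
            sk.SimulationConfig(participant_mass=0.0)
        cfg = sk.SimulationConfig()
        with pytest.raises(ConfigError):
            sk.generate_static_trial(cfg, duration=0.0)


class TestSteadyGait:
    def test_heel_strike_count_matches_cadence(self):
        cfg = sk.SimulationConfig(cadence=100.0, duration=60.0, seed=3)
        _, truth = sk.generate_steady_gait(cfg)
        n = sum(truth.heel_strikes[s].size for s in ("left", "right"))
        # one strike per step minus edge effects at the trial boundaries
        assert abs(n - 100) <= 3

    def test_swing_grf_is_exactly_zero_without_noise(self, noiseless_cfg):
        trial, truth = sk.generate_steady_gait(noiseless_cfg)
        tf = trial.force_time()
        for side in ("left", "right"):
            vz = trial.forces[side][:, 2]
            hs = truth.heel_strikes[side]
            for to in truth.toe_offs[side]:
                nxt = hs[hs > to]
                if nxt.size == 0:
                    continue
                swing = (tf > to + 1e-3) & (tf < float(nxt[0]) - 1e-3)
                assert np.all(vz[swing] == 0.0)

    def test_heel_ap_maxima_coincide_with_ground_truth_strikes(self, noiseless_cfg):
        trial, truth = sk.generate_steady_gait(noiseless_cfg)
        rel = trial.markers["R_HEEL"][:, 0] - trial.pelvis_origin()[:, 0]
        rate = trial.marker_rate
        for hs in truth.heel_strikes["right"][1:-1]:
            i = int(round(hs * rate))
            w = rel[i - 15:i + 16]
            assert abs(int(np.argmax(w)) - 15) <= 1  # within one frame

    def test_seeded_determinism(self, noiseless_cfg):
        t1, _ = sk.simulate_trial(noiseless_cfg)
        t2, _ = sk.simulate_trial(noiseless_cfg)
        assert np.array_equal(t1.markers["C7"], t2.markers["C7"])
        assert np.array_equal(t1.forces["left"], t2.forces["left"])
        assert np.array_equal(t1.belt_speed, t2.belt_speed)

    def test_finger_markers_swing_fast(self, noiseless_cfg):
        trial, _ = sk.generate_steady_gait(noiseless_cfg)
        v = np.gradient(trial.markers["L_FINGER"], 1 / trial.marker_rate, axis=0)
        speed = np.linalg.norm(v, axis=1)
        assert np.median(speed) > 0.3  # well above the 5 cm/s grab threshold


class TestBeltProfile:
    def test_triangular_profile_closed_form(self):
        v = sk.make_belt_profile(v0=1.0, accel=3.0, duration=0.8, onset=1.0,
                                 rate=1000.0, total_duration=3.0)
        t = np.arange(v.size) / 1000.0
        assert v.max() == pytest.approx(2.2, abs=2 * 3.0 / 1000.0)
        assert t[np.argmax(v)] == pytest.approx(1.4, abs=2e-3)
        assert v[int(1.8 * 1000)] == pytest.approx(1.0, abs=3.0 / 1000.0)
        assert np.all(v[t >= 1.8] == 1.0) and np.all(v[t < 1.0] == 1.0)

    def test_short_duration_peak(self):
        v = sk.make_belt_profile(1.0, 3.0, 0.6, 1.0, 1000.0)
        assert v.max() - 1.0 == pytest.approx(0.9, abs=3.0 / 1000.0)

    def test_vanishing_acceleration_limit(self):
        v = sk.make_belt_profile(1.0, 1e-9, 0.8, 1.0, 1000.0)
        assert np.allclose(v, 1.0, atol=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            sk.make_belt_profile(0.0, 3.0, 0.8, 1.0, 1000.0)
        with pytest.raises(ConfigError):
            sk.make_belt_profile(1.0, -3.0, 0.8, 1.0, 1000.0)


class TestScheduling:
    def test_requested_counts_and_spacing(self):
        cfg = sk.SimulationConfig(n_perturbations_per_side=4, seed=11,
                                  marker_noise_sd=0.0, force_noise_sd=0.0,
                                  metric_noise_sd={})
        trial, truth = sk.simulate_trial(cfg)
        perts = truth.perturbations
        assert len(perts) == 8
        assert sum(p.limb == "left" for p in perts) == 4
        onsets = np.array([p.onset for p in perts])
        assert np.all(np.diff(onsets) >= cfg.min_spacing * cfg.stride_period - 1e-9)

    def test_zero_count_returns_unchanged(self, noiseless_cfg):
        import dataclasses

        trial, truth = sk.generate_steady_gait(noiseless_cfg)
        out, truth2 = sk.schedule_perturbations(
            trial, truth,
            dataclasses.replace(noiseless_cfg, n_perturbations_per_side=0))
        assert np.array_equal(out.belt_speed, trial.belt_speed)
        assert truth2.perturbations == []

    def test_short_trial_raises_scheduling_error(self):
        cfg = sk.SimulationConfig(duration=20.0, n_perturbations_per_side=12, seed=1)
        trial, truth = sk.generate_steady_gait(cfg)
        with pytest.raises(SchedulingError):
            sk.schedule_perturbations(trial, truth, cfg)

    def test_trigger_rule_consistency(self, noiseless_trial):
        trial, truth = noiseless_trial
        for p in truth.perturbations:
            i = int(round(p.onset * trial.force_rate))
            vz = trial.forces[p.limb][:, 2]
            assert vz[i] > 100.0 and vz[i - 1] <= 100.0

    def test_belt_returns_to_baseline_with_expected_peak(self, noiseless_trial,
                                                         noiseless_cfg):
        trial, truth = noiseless_trial
        v0 = noiseless_cfg.preferred_speed
        expected = noiseless_cfg.perturbation_accel * noiseless_cfg.perturbation_duration / 2
        assert trial.belt_speed.max() - v0 == pytest.approx(
            expected, abs=noiseless_cfg.perturbation_accel / trial.force_rate)
        for p in truth.perturbations:
            j = int(round((p.onset + p.duration) * trial.force_rate))
            assert trial.belt_speed[j] == pytest.approx(v0, abs=1e-9)


class TestInjection:
    def test_zero_offsets_give_identical_metrics_across_conditions(self):
        kwargs = dict(marker_noise_sd=0.0, force_noise_sd=0.0, metric_noise_sd={},
                      n_perturbations_per_side=2, seed=21)
        _, truth_a = sk.simulate_trial(sk.SimulationConfig(snp_condition="active", **kwargs))
        _, truth_i = sk.simulate_trial(sk.SimulationConfig(snp_condition="inactive", **kwargs))
        assert truth_a.injected_metrics == truth_i.injected_metrics

    def test_exact_offset_at_zero_noise(self):
        kwargs = dict(marker_noise_sd=0.0, force_noise_sd=0.0, metric_noise_sd={},
                      n_perturbations_per_side=2, seed=22)
        off = {("intact", "rec1"): {"trunk_sway": -1.3}}
        _, truth_a = sk.simulate_trial(sk.SimulationConfig(
            snp_condition="active", effect_profile=off, **kwargs))
        _, truth_i = sk.simulate_trial(sk.SimulationConfig(
            snp_condition="inactive", effect_profile=off, **kwargs))
        for (pi, label), inj in truth_a.injected_metrics.items():
            base = truth_i.injected_metrics[(pi, label)]
            side = truth_a.perturbations[pi].side
            expected = -1.3 if (side, label) == ("intact", "rec1") else 0.0
            assert inj["trunk_sway"] - base["trunk_sway"] == pytest.approx(expected)

    def test_negative_grf_target_rejected(self):
        cfg = sk.SimulationConfig(
            snp_condition="active", n_perturbations_per_side=1, seed=2,
            effect_profile={("intact", "rec1"): {"peak_grf": -500.0}})
        with pytest.raises(ConfigError):
            sk.simulate_trial(cfg)

    def test_injected_mean_matches_offset_under_noise(self):
        """Monte-Carlo: the mean injected active-inactive difference sits
        within 3 standard errors of the programmed offset."""
        off = {("intact", "rec1"): {"trunk_sway": -1.3}}
        vals = {"active": [], "inactive": []}
        for cond in ("active", "inactive"):
            for seed in range(3):
                cfg = sk.SimulationConfig(
                    snp_condition=cond, effect_profile=off, seed=300 + seed,
                    n_perturbations_per_side=6,
                    metric_noise_sd={"trunk_sway": 0.3})
                _, truth = sk.simulate_trial(cfg)
                for (pi, label), inj in truth.injected_metrics.items():
                    if label == "rec1" and truth.perturbations[pi].side == "intact":
                        vals[cond].append(inj["trunk_sway"])
        a, b = np.array(vals["active"]), np.array(vals["inactive"])
        diff = a.mean() - b.mean()
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(diff - (-1.3)) < 3 * max(se, 1e-6)


class TestCorruption:
    def test_zero_probabilities_are_identity(self, noiseless_trial, noiseless_cfg):
        trial, truth = noiseless_trial
        out, truth2 = sk.corrupt_trial(trial, truth, noiseless_cfg)
        for name in trial.markers:
            assert np.array_equal(out.markers[name], trial.markers[name])
        assert np.array_equal(out.forces["right"], trial.forces["right"])
        assert truth2.handrail_grabs == [] and truth2.corrupted_segments == []

    def test_certain_grab_freezes_fingers(self):
        cfg = sk.SimulationConfig(n_perturbations_per_side=2, seed=31,
                                  handrail_grab_probability=1.0,
                                  marker_noise_sd=0.0, force_noise_sd=0.0,
                                  metric_noise_sd={})
        trial, truth = sk.simulate_trial(cfg)
        assert len(truth.handrail_grabs) == len(truth.perturbations)
        tm = trial.marker_time()
        for start, end, _ in truth.handrail_grabs:
            sel = (tm >= start + 0.01) & (tm <= end - 0.01)
            for name in ("L_FINGER", "R_FINGER"):
                v = np.gradient(trial.markers[name], 1 / trial.marker_rate, axis=0)
                assert np.all(np.linalg.norm(v, axis=1)[sel] < 0.05)

    def test_certain_dropout_flags_marker_invalid(self):
        cfg = sk.SimulationConfig(n_perturbations_per_side=2, seed=32,
                                  dropout_probability=1.0)
        trial, truth = sk.simulate_trial(cfg)
        drops = [c for c in truth.corrupted_segments if c[0] == "dropout"]
        assert len(drops) == len(truth.perturbations)
        for _, start, end, _, marker in drops:
            tm = trial.marker_time()
            sel = (tm >= start) & (tm <= end)
            assert not trial.marker_valid[marker][sel].any()
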