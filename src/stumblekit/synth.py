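"""Synthetic split-belt treadmill walking trials with ground-truth annotations.

The generator emulates the statistical and mechanical structure the analysis
pipeline assumes rather than musculoskeletal reality:

* periodic marker kinematics built from low-order harmonics, with the heel
  marker's anterior-posterior position relative to the pelvis peaking exactly
  at each heel strike and the toe marker's minimum at each toe-off;
* stance vertical GRF as two raised-cosine humps (the classic double-hump
  curve) peaking near 100-120 %BW and identically zero in swing;
* belt-speed perturbations as a triangular speed profile (constant
  acceleration then deceleration) triggered at the first force sample of the
  chosen stance whose vertical GRF exceeds the trigger threshold;
* step-wise stumble responses realized as raised-cosine trunk-flexion
  excursions whose amplitude and rise time are solved from the target sway and
  peak flexion velocity, so injected metrics are analytically exact at zero
  noise;
* optional corruption: handrail grabs (finger markers frozen), marker
  dropout, and treadmill mid-line crossings (the unloaded plate held above
  the swing-detection force threshold).

Every feature inserted into a trial is logged in a :class:`GroundTruth`
object that downstream tests use as an oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import METRICS, SimulationConfig
from .core import (
    GRAVITY,
    ConfigError,
    GroundTruth,
    GroundTruthPerturbation,
    SchedulingError,
    SIDES,
    StaticTrial,
    TrialMeta,
    TrialRecording,
    other_side,
)

# independent deterministic sub-streams per generation stage
_STREAM_STEADY, _STREAM_SCHEDULE, _STREAM_INJECT, _STREAM_CORRUPT, _STREAM_STATIC = range(5)

#: clearance between a trunk excursion's support and its step boundaries [s];
#: large enough that the excursion's filter ringing stays inside its own step
_LEAD_MARGIN = 0.14
_TRAIL_MARGIN = 0.16
#: bounds on the excursion's return-to-baseline phase [s]
_FALL_MIN, _FALL_MAX = 0.12, 0.35
#: cosine taper used to silence the steady trunk oscillation around a
#: perturbation-response window [s]; the taper finishes shortly before the
#: window so its filtered transient has decayed by the perturbation step
_OSC_TAPER = 0.40
_OSC_GUARD = 0.15


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _raised_cosine(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-peak raised-cosine hump on ``|phase - center| <= width / 2``."""
    out = np.zeros_like(phase)
    mask = np.abs(phase - center) <= width / 2.0
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (phase[mask] - center) / width))
    return out


def generate_static_trial(config: SimulationConfig, duration: float = 5.0) -> StaticTrial:
    """A stationary T-pose force recording.

    The two plates split the participant's weight roughly 50/50 and the summed
    vertical force has mean ``mass * g`` plus the configured sensor noise.
    """
    if config.participant_mass <= 0:
        raise ConfigError("participant mass must be positive")
    if duration <= 0:
        raise ConfigError("static-trial duration must be positive")
    rng = _rng(config, _STREAM_STATIC)
    n = int(round(duration * config.force_rate))
    total = config.participant_mass * GRAVITY
    forces = {}
    for side, share in (("left", 0.5), ("right", 0.5)):
        f = np.zeros((n, 3))
        f[:, 2] = share * total
        if config.force_noise_sd > 0:
            f += rng.normal(0.0, config.force_noise_sd, size=(n, 3))
        forces[side] = f
    return StaticTrial(forces=forces, rate=config.force_rate)


# ---------------------------------------------------------------------------
# steady gait
# ---------------------------------------------------------------------------

def _gait_timing(config: SimulationConfig):
    """First heel-strike time per side; right leads by construction."""
    t_first = {"right": 0.6, "left": 0.6 + config.step_period}
    return t_first


def _event_times(config: SimulationConfig, t_first: float) -> np.ndarray:
    last = config.duration - 1.0 / config.marker_rate
    n = int(np.floor((last - t_first) / config.stride_period)) + 1
    return t_first + np.arange(max(n, 0)) * config.stride_period


def _stance_vgrf(config: SimulationConfig, t: np.ndarray, t_hs0: float,
                 first_peak_bw: float, second_peak_bw: float) -> np.ndarray:
    """Periodic double-hump vertical GRF [N] for one side over the whole trial."""
    bw = config.participant_mass * GRAVITY
    stride = config.stride_period
    phase = np.mod(t - t_hs0, stride) / config.stance_duration  # stance fraction
    f = first_peak_bw / 100.0 * bw * _raised_cosine(phase, 0.25, 0.5)
    f += second_peak_bw / 100.0 * bw * _raised_cosine(phase, 0.75, 0.5)
    f[phase > 1.0] = 0.0
    return f


def _single_stance_vgrf(config: SimulationConfig, t: np.ndarray, t_hs: float,
                        first_peak_bw: float, second_peak_bw: float) -> np.ndarray:
    """Double-hump vertical GRF for one particular stance only."""
    bw = config.participant_mass * GRAVITY
    phase = (t - t_hs) / config.stance_duration
    f = first_peak_bw / 100.0 * bw * _raised_cosine(phase, 0.25, 0.5)
    f += second_peak_bw / 100.0 * bw * _raised_cosine(phase, 0.75, 0.5)
    f[(phase < 0.0) | (phase > 1.0)] = 0.0
    return f


def _trunk_markers_from_angle(pelvis_origin: np.ndarray, theta_deg: np.ndarray):
    """C7/CLAV positions whose midpoint sits a fixed trunk length from the
    pelvis origin along a unit axis tilted ``theta`` anteriorly from vertical."""
    L = 0.45  # m, pelvis origin to C7/CLAV midpoint
    th = np.deg2rad(theta_deg)
    axis = np.stack([np.sin(th), np.zeros_like(th), np.cos(th)], axis=1)
    mid = pelvis_origin + L * axis
    d = np.array([-0.05, 0.0, 0.02])
    return mid + d, mid - d


def generate_steady_gait(config: SimulationConfig):
    """Simulate unperturbed treadmill walking.

    Returns the trial recording together with ground-truth gait events.
    """
    if config.stance_duration >= config.stride_period:
        raise ConfigError("stance_fraction implies stance longer than the stride")
    rng = _rng(config, _STREAM_STEADY)
    t_first = _gait_timing(config)
    tm = np.arange(int(round(config.duration * config.marker_rate))) / config.marker_rate
    tf = np.arange(int(round(config.duration * config.force_rate))) / config.force_rate
    stride = config.stride_period

    truth = GroundTruth()
    last = config.duration - 1.0 / config.marker_rate
    for side in SIDES:
        hs = _event_times(config, t_first[side])
        truth.heel_strikes[side] = hs
        # toe-off train is the heel-strike train shifted by the stance time;
        # it includes the lift-off of the stance that began before recording
        to = np.concatenate([[t_first[side] - config.stride_period], hs]) \
            + config.stance_duration
        truth.toe_offs[side] = to[(to >= 0.0) & (to <= last)]

    # pelvis origin: gentle bob and lateral weight shift
    pel = np.zeros((tm.size, 3))
    pel[:, 0] = 0.02 * np.sin(2 * np.pi * tm / config.step_period)
    pel[:, 1] = 0.02 * np.sin(2 * np.pi * (tm - t_first["right"]) / stride)
    pel[:, 2] = 1.00 + 0.015 * np.sin(4 * np.pi * (tm - t_first["right"]) / stride)

    markers = {}
    # pelvis cluster chosen so its centroid is exactly the pelvis origin
    markers["SACR"] = pel + np.array([-0.16, 0.0, 0.02])
    markers["LASI"] = pel + np.array([0.08, 0.12, -0.01])
    markers["RASI"] = pel + np.array([0.08, -0.12, -0.01])

    heel_amp = 0.40 * config.preferred_speed * config.step_period + 0.08
    toe_amp = heel_amp * 0.9
    for side, prefix, lat in (("left", "L", 0.10), ("right", "R", -0.10)):
        phi = 2 * np.pi * (tm - t_first[side]) / stride
        # per-cycle maximum exactly at each heel strike
        rel_heel = heel_amp * (np.cos(phi) + 0.15 * np.cos(2 * phi))
        heel = pel + np.stack(
            [rel_heel, np.full_like(tm, lat),
             -0.90 + 0.04 * 0.5 * (1 + np.cos(phi + np.pi))], axis=1)
        psi = 2 * np.pi * (tm - t_first[side] - config.stance_duration) / stride
        # per-cycle minimum exactly at each toe-off
        rel_toe = toe_amp * (-np.cos(psi) - 0.10 * np.cos(2 * psi)) + 0.06
        toe = pel + np.stack(
            [rel_toe, np.full_like(tm, lat * 1.2),
             -0.95 + 0.03 * 0.5 * (1 + np.cos(psi + np.pi))], axis=1)
        markers[f"{prefix}_HEEL"] = heel
        markers[f"{prefix}_TOE"] = toe

    # arm swing: fingers move fast (~1 m/s peak) except during injected grabs
    for side, prefix, lat in (("left", "L", 0.28), ("right", "R", -0.28)):
        phi = 2 * np.pi * (tm - t_first[other_side(side)]) / stride
        fing = pel + np.stack(
            [0.22 * np.sin(phi), np.full_like(tm, lat),
             -0.15 + 0.02 * np.sin(2 * phi + 0.7)], axis=1)
        markers[f"{prefix}_FINGER"] = fing

    theta = config.baseline_trunk_lean + config.trunk_osc_amp * np.sin(
        2 * np.pi * (tm - t_first["right"]) / stride)
    markers["C7"], markers["CLAV"] = _trunk_markers_from_angle(pel, theta)

    if config.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, config.marker_noise_sd, size=markers[name].shape)
    marker_valid = {name: np.ones(tm.size, dtype=bool) for name in markers}

    forces = {}
    for side in SIDES:
        vz = _stance_vgrf(config, tf, t_first[side],
                          config.grf_first_peak, config.grf_second_peak)
        f = np.zeros((tf.size, 3))
        f[:, 2] = vz
        forces[side] = f
    if config.force_noise_sd > 0:
        for side in SIDES:
            forces[side] = forces[side] + rng.normal(
                0.0, config.force_noise_sd, size=forces[side].shape)

    meta = TrialMeta(
        participant_mass=config.participant_mass,
        snp_condition=config.snp_condition,
        perturbation_duration=config.perturbation_duration,
        prosthetic_side=config.prosthetic_side,
        preferred_speed=config.preferred_speed,
    )
    trial = TrialRecording(
        markers=markers, marker_valid=marker_valid, marker_rate=config.marker_rate,
        forces=forces, force_rate=config.force_rate,
        belt_speed=np.full(tf.size, config.preferred_speed), meta=meta,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# belt perturbations
# ---------------------------------------------------------------------------

def make_belt_profile(v0: float, accel: float, duration: float, onset: float,
                      rate: float, total_duration: float | None = None) -> np.ndarray:
    """Belt-speed series with one triangular perturbation.

    The belt accelerates at ``accel`` for the first half of ``duration`` and
    decelerates at the same rate for the second half, peaking at
    ``v0 + accel * duration / 2`` and returning to ``v0``.
    """
    if min(v0, accel, duration, onset, rate) <= 0:
        raise ConfigError("v0, accel, duration, onset, and rate must all be positive")
    if total_duration is None:
        total_duration = onset + duration + 1.0
    t = np.arange(int(round(total_duration * rate))) / rate
    return _apply_profile(np.full(t.size, float(v0)), t, v0, accel, duration, onset)


def _apply_profile(speed: np.ndarray, t: np.ndarray, v0: float, accel: float,
                   duration: float, onset: float) -> np.ndarray:
    half = duration / 2.0
    up = (t >= onset) & (t < onset + half)
    down = (t >= onset + half) & (t < onset + duration)
    speed[up] = v0 + accel * (t[up] - onset)
    speed[down] = v0 + accel * (duration - (t[down] - onset))
    return speed


def schedule_perturbations(trial: TrialRecording, truth: GroundTruth,
                           config: SimulationConfig):
    """Insert belt-speed perturbations triggered by the vertical-GRF rule.

    Sides are drawn as a seeded permutation honoring the per-side counts;
    consecutive onsets are at least ``min_spacing`` strides apart.  Each
    onset is the first force sample of the chosen stance at which that
    side's vertical GRF exceeds the trigger threshold.
    """
    trial = trial.copy()
    truth = truth.copy()
    n_side = config.n_perturbations_per_side
    if n_side == 0:
        return trial, truth
    rng = _rng(config, _STREAM_SCHEDULE)
    sides = ["left"] * n_side + ["right"] * n_side
    rng.shuffle(sides)

    stride = config.stride_period
    warmup = 4.0  # s before the first candidate stance
    tail = 3.0 * stride + 1.0  # room for rec1..rec3 after the last onset
    last_onset = warmup - config.min_spacing * stride
    tf = trial.force_time()
    for k, side in enumerate(sides):
        jitter = rng.integers(0, 3) * config.step_period
        earliest = last_onset + config.min_spacing * stride + jitter
        hs = truth.heel_strikes[side]
        candidates = hs[(hs >= earliest) & (hs <= trial.duration - tail)]
        if candidates.size == 0:
            raise SchedulingError(
                f"trial too short: placed {k} of {len(sides)} perturbations "
                f"({config.min_spacing}-stride spacing)")
        t_hs = float(candidates[0])
        onset_idx = _trigger_index(trial, config, side, t_hs)
        onset = tf[onset_idx]
        nxt = hs[hs > t_hs]
        cycle_fraction = (onset - t_hs) / (float(nxt[0]) - t_hs)
        trial.belt_speed = _apply_profile(
            trial.belt_speed, tf, config.preferred_speed,
            config.perturbation_accel, config.perturbation_duration, onset)
        truth.perturbations.append(GroundTruthPerturbation(
            onset=onset, limb=side, side=trial.meta.label_of(side),
            duration=config.perturbation_duration, cycle_fraction=cycle_fraction))
        last_onset = onset
    return trial, truth


def _trigger_index(trial: TrialRecording, config: SimulationConfig,
                   side: str, t_hs: float) -> int:
    """First force sample of the stance at ``t_hs`` whose vertical GRF exceeds
    the trigger threshold."""
    i0 = int(round(t_hs * config.force_rate))
    i1 = min(i0 + int(config.stance_duration * config.force_rate),
             trial.n_force_samples)
    vz = trial.forces[side][i0:i1, 2]
    above = np.nonzero(vz > config.trigger_force)[0]
    if above.size == 0:
        raise SchedulingError(
            f"vertical GRF never exceeds {config.trigger_force} N in the "
            f"stance at t={t_hs:.3f} s")
    return i0 + int(above[0])


# ---------------------------------------------------------------------------
# stumble-response injection
# ---------------------------------------------------------------------------

def _truth_segments(truth: GroundTruth, pert: GroundTruthPerturbation,
                    stance_duration: float):
    """(label, stance limb, start, end) for pert..rec3 from ground-truth events."""
    limb, contra = pert.limb, other_side(pert.limb)
    hs_p = truth.heel_strikes[limb]
    hs_c = truth.heel_strikes[contra]
    before = hs_p[hs_p <= pert.onset]
    if before.size == 0:
        raise SchedulingError("perturbation onset precedes the first heel strike")
    t0 = float(before[-1])
    bounds = [t0]
    sides = []
    cur = t0
    for label, arr, stance in (("pert", hs_c, limb), ("rec1", hs_p, contra),
                               ("rec2", hs_c, limb), ("rec3", hs_p, contra)):
        nxt = arr[arr > cur]
        if nxt.size == 0:
            raise SchedulingError("trial ends before the third recovery step")
        cur = float(nxt[0])
        bounds.append(cur)
        sides.append(stance)
    return [(label, sides[i], bounds[i], bounds[i + 1])
            for i, label in enumerate(("pert", "rec1", "rec2", "rec3"))]


def _raw_excursion(u: np.ndarray, amplitude: float, t1: float, t2: float):
    """Cosine rise (half-sine velocity, peak ``amplitude * pi / (2 * t1)``)
    followed by a cosine fall back to baseline."""
    out = np.zeros_like(u)
    rise = (u >= 0) & (u < t1)
    out[rise] = amplitude * 0.5 * (1.0 - np.cos(np.pi * u[rise] / t1))
    fall = (u >= t1) & (u < t1 + t2)
    out[fall] = amplitude * 0.5 * (1.0 + np.cos(np.pi * (u[fall] - t1) / t2))
    return out


def _excursion(tm: np.ndarray, rate: float, start: float, amplitude: float,
               peak_rate: float, budget: float, bandlimit: float):
    """Band-limited trunk-flexion excursion with calibrated range and peak
    rise rate.

    The raw cosine shape's amplitude and rise time are adjusted by
    fixed-point iteration so that, after the marker filtering chain the
    analysis applies (zero-phase Butterworth plus 3-sample median), the
    trace's range and peak positive rate equal the targets exactly.
    Returns ``(slice, values)`` to add into the trunk-angle trace.
    """
    from scipy import signal as sps

    from .preprocess import median_filter3

    t1 = np.pi * amplitude / (2.0 * peak_rate)
    if budget - t1 < _FALL_MIN:
        raise ConfigError(
            "trunk excursion does not fit inside the step: decrease the "
            "trunk_sway / peak_flexion_velocity ratio or the cadence")
    t2 = float(min(budget - t1, _FALL_MAX))
    sos = sps.butter(4, bandlimit, btype="low", fs=rate, output="sos")
    n0 = max(int((start - 0.5) * rate), 0)
    n1 = min(int(np.ceil((start + t1 + t2 + 0.5) * rate)) + 1, tm.size)
    u = tm[n0:n1] - start
    a_c, t1_c = amplitude, t1
    shape = None
    for _ in range(4):
        shape = _raw_excursion(u, a_c, t1_c, t2)
        filt = median_filter3(sps.sosfiltfilt(sos, shape))
        r = float(filt.max() - filt.min())
        v = float(np.gradient(filt, 1.0 / rate).max())
        scale_a = amplitude / r
        t1_new = float(np.clip(t1_c * (v / peak_rate) * scale_a,
                               0.5 * t1, budget - t2))
        a_c *= scale_a
        t1_c = t1_new
    return slice(n0, n1), shape


def _draw_targets(rng: np.random.Generator, base: dict, offs: dict,
                  noise_sd: dict) -> dict:
    """Per-step metric targets: baseline + offset + noise.

    The two trunk metrics share a response-intensity factor gamma (drawn from
    the sway noise), with extra independent jitter on the velocity making up
    its configured marginal spread; the GRF target gets independent Gaussian
    noise.  Draws are symmetrically clamped at 2.5 sd so targets stay
    physically realizable without biasing the mean.
    """
    a0 = base["trunk_sway"] + offs["trunk_sway"]
    p0 = base["peak_flexion_velocity"] + offs["peak_flexion_velocity"]
    g0 = base["peak_grf"] + offs["peak_grf"]
    s_a = noise_sd.get("trunk_sway", 0.0)
    s_p = noise_sd.get("peak_flexion_velocity", 0.0)
    s_g = noise_sd.get("peak_grf", 0.0)
    gamma = 1.0
    if s_a > 0 and a0 > 0:
        cv = s_a / a0
        gamma = max(0.3, 1.0 + float(np.clip(rng.normal(0.0, cv), -2.5 * cv, 2.5 * cv)))
    eta = 0.0
    if s_p > 0 and p0 > 0:
        cv_p = s_p / p0
        cv_a = s_a / a0 if a0 > 0 else 0.0
        s_eta = np.sqrt(max(cv_p ** 2 - cv_a ** 2, 0.0))
        if s_eta > 0:
            eta = float(np.clip(rng.normal(0.0, s_eta), -0.2, 0.2))
    g_noise = 0.0
    if s_g > 0:
        g_noise = float(np.clip(rng.normal(0.0, s_g), -3 * s_g, 3 * s_g))
    return {"trunk_sway": a0 * gamma,
            "peak_flexion_velocity": p0 * gamma * (1.0 + eta),
            "peak_grf": g0 + g_noise}


def inject_recovery_response(trial: TrialRecording, truth: GroundTruth,
                             config: SimulationConfig):
    """Reshape trunk kinematics and stance GRFs so every step of every
    perturbation carries known metric values.

    For each step the targets are ``baseline + effect-profile offset +
    Gaussian noise``; the trunk trace within the response window is rebuilt
    as a flat lean plus one excursion per step, and the stance vertical GRF
    is rescaled so its first hump peaks at the target %BW.  Because the
    rescaling moves the 100 N trigger crossing, each perturbation's onset and
    belt profile are recomputed afterwards from the final force series.
    """
    trial = trial.copy()
    truth = truth.copy()
    rng = _rng(config, _STREAM_INJECT)
    tm = trial.marker_time()
    tf = trial.force_time()
    bw = config.participant_mass * GRAVITY
    stride = config.stride_period

    theta_extra = np.zeros(tm.size)
    osc_gate = np.ones(tm.size)

    for pi, pert in enumerate(truth.perturbations):
        segments = _truth_segments(truth, pert, config.stance_duration)
        win0, win3 = segments[0][2], segments[-1][3]
        # silence the steady trunk oscillation across the response window
        osc_gate *= _window_gate(tm, win0 - _OSC_GUARD, win3 + _OSC_GUARD,
                                 _OSC_TAPER)

        for label, stance_limb, s, e in segments:
            offs = config.offsets_for(pert.side, label)
            base = config.baseline_response[label]
            if base["peak_grf"] + offs["peak_grf"] <= 0:
                raise ConfigError(
                    f"effect profile yields non-positive peak GRF for "
                    f"({pert.side}, {label})")
            if (base["trunk_sway"] + offs["trunk_sway"] <= 0
                    or base["peak_flexion_velocity"] + offs["peak_flexion_velocity"] <= 0):
                raise ConfigError(
                    f"effect profile yields non-positive trunk targets for "
                    f"({pert.side}, {label})")
            target = _draw_targets(rng, base, offs, config.metric_noise_sd)
            budget = (e - s) - _LEAD_MARGIN - _TRAIL_MARGIN
            try:
                sl, exc = _excursion(tm, config.marker_rate, s + _LEAD_MARGIN,
                                     target["trunk_sway"],
                                     target["peak_flexion_velocity"], budget,
                                     config.trunk_bandlimit)
            except ConfigError:
                # extreme noise draw: let the fall borrow the trailing margin
                sl, exc = _excursion(tm, config.marker_rate, s + _LEAD_MARGIN,
                                     target["trunk_sway"],
                                     target["peak_flexion_velocity"],
                                     budget + _TRAIL_MARGIN - 0.06,
                                     config.trunk_bandlimit)
            theta_extra[sl] += exc

            # rescale this stance's double hump so the first peak hits target
            i0 = int(round(s * config.force_rate))
            i1 = min(int(round((s + config.stance_duration) * config.force_rate)) + 1,
                     trial.n_force_samples)
            seg_t = tf[i0:i1]
            vz = _single_stance_vgrf(config, seg_t, s, target["peak_grf"],
                                     min(config.grf_second_peak, target["peak_grf"] - 4.0))
            if config.force_noise_sd > 0:
                vz = vz + rng.normal(0.0, config.force_noise_sd, size=vz.shape)
            trial.forces[stance_limb][i0:i1, 2] = vz

            truth.injected_metrics[(pi, label)] = dict(target)

        # the rescaled pert-step hump moves the trigger crossing: recompute
        onset_idx = _trigger_index(trial, config, pert.limb, win0)
        new_onset = tf[onset_idx]
        half_profile_mask = (tf >= pert.onset) & (tf < pert.onset + pert.duration)
        trial.belt_speed[half_profile_mask] = config.preferred_speed
        trial.belt_speed = _apply_profile(
            trial.belt_speed, tf, config.preferred_speed,
            config.perturbation_accel, pert.duration, new_onset)
        hs = truth.heel_strikes[pert.limb]
        nxt = hs[hs > win0]
        truth.perturbations[pi] = GroundTruthPerturbation(
            onset=new_onset, limb=pert.limb, side=pert.side, duration=pert.duration,
            cycle_fraction=(new_onset - win0) / (float(nxt[0]) - win0))

    # rebuild the trunk markers from the composed angle trace
    t_first = _gait_timing(config)
    theta = (config.baseline_trunk_lean
             + config.trunk_osc_amp * osc_gate
             * np.sin(2 * np.pi * (tm - t_first["right"]) / stride)
             + theta_extra)
    pel = trial.pelvis_origin()
    c7, clav = _trunk_markers_from_angle(pel, theta)
    if config.marker_noise_sd > 0:
        c7 = c7 + rng.normal(0.0, config.marker_noise_sd, size=c7.shape)
        clav = clav + rng.normal(0.0, config.marker_noise_sd, size=clav.shape)
    trial.markers["C7"], trial.markers["CLAV"] = c7, clav
    return trial, truth


def _window_gate(t: np.ndarray, start: float, end: float, taper: float) -> np.ndarray:
    """1 outside [start - taper, end + taper], 0 inside [start, end], cosine
    ramps in between."""
    g = np.ones_like(t)
    g[(t >= start) & (t <= end)] = 0.0
    pre = (t >= start - taper) & (t < start)
    g[pre] = 0.5 * (1.0 - np.cos(np.pi * (start - t[pre]) / taper))
    post = (t > end) & (t <= end + taper)
    g[post] = 0.5 * (1.0 - np.cos(np.pi * (t[post] - end) / taper))
    return g


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def corrupt_trial(trial: TrialRecording, truth: GroundTruth,
                  config: SimulationConfig):
    """Insert handrail grabs, marker dropout, and mid-line crossings with the
    configured probabilities; zero probabilities return an identical copy."""
    trial = trial.copy()
    truth = truth.copy()
    rng = _rng(config, _STREAM_CORRUPT)
    tm = trial.marker_time()
    tf = trial.force_time()

    for pi, pert in enumerate(truth.perturbations):
        segments = _truth_segments(truth, pert, config.stance_duration)
        seg = {label: (s, e) for label, _, s, e in segments}
        win0, win3 = seg["pert"][0], seg["rec3"][1]

        if rng.random() < config.handrail_grab_probability:
            g0 = pert.onset + 0.25
            g1 = min(g0 + config.handrail_grab_span, win3 - 0.1)
            _freeze_fingers(trial, tm, g0, g1)
            truth.handrail_grabs.append((g0, g1, pi))

        if rng.random() < config.dropout_probability:
            n_win = int((win3 - win0) * config.marker_rate)
            n_drop = max(int(np.ceil(config.dropout_fraction * n_win)), 1)
            mid = (seg["rec1"][0] + seg["rec2"][1]) / 2.0
            j0 = int(round(mid * config.marker_rate)) - n_drop // 2
            j1 = j0 + n_drop
            m = config.dropout_marker
            trial.marker_valid[m][j0:j1] = False
            trial.markers[m][j0:j1] = np.nan
            truth.corrupted_segments.append(
                ("dropout", tm[j0], tm[min(j1, tm.size) - 1], pi, m))

        if rng.random() < config.midline_cross_probability:
            c0, c1 = seg["rec1"][0], seg["rec1"][0] + config.stride_period
            plate = segments[1][1]  # rec1 stance limb's plate stays loaded
            i0, i1 = int(round(c0 * config.force_rate)), int(round(c1 * config.force_rate))
            vz = trial.forces[plate][i0:i1, 2]
            trial.forces[plate][i0:i1, 2] = np.maximum(vz, 40.0)
            truth.corrupted_segments.append(("midline", c0, c1, pi, plate))
    return trial, truth


def _freeze_fingers(trial: TrialRecording, tm: np.ndarray, g0: float, g1: float,
                    blend: float = 0.15):
    """Hold both finger markers still over [g0, g1], then blend back."""
    for name in ("L_FINGER", "R_FINGER"):
        pos = trial.markers[name]
        hold = (tm >= g0) & (tm <= g1)
        if not hold.any():
            continue
        i_start = int(np.nonzero(hold)[0][0])
        pos[hold] = pos[i_start]
        back = (tm > g1) & (tm <= g1 + blend)
        w = (tm[back] - g1) / blend
        pos[back] = (1 - w[:, None]) * pos[i_start] + w[:, None] * pos[back]


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------

def required_duration(config: SimulationConfig) -> float:
    """Trial length that comfortably fits the configured perturbation count
    at the required spacing (including side-order jitter)."""
    n_total = 2 * config.n_perturbations_per_side
    per = (config.min_spacing + 1.5) * config.stride_period
    return 8.0 + n_total * per + 3.0 * config.stride_period + 2.0


def simulate_trial(config: SimulationConfig):
    """Steady gait -> scheduled perturbations -> injected responses ->
    corruption, extending the trial duration if the configured one cannot
    fit the perturbation schedule."""
    need = required_duration(config)
    if config.n_perturbations_per_side > 0 and config.duration < need:
        config = dataclasses.replace(config, duration=need)
    trial, truth = generate_steady_gait(config)
    trial, truth = schedule_perturbations(trial, truth, config)
    trial, truth = inject_recovery_response(trial, truth, config)
    trial, truth = corrupt_trial(trial, truth, config)
    return trial, truth
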