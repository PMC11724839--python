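"""Outcome measures per recovery step.

Three measures characterize each step of a stumble-recovery sequence:

* **trunk angular sway** [deg] - range (max - min) of the trunk-to-vertical
  angle over the step;
* **peak trunk flexion angular velocity** [deg/s] - maximum rate of the trunk
  angle in the flexion (anterior) direction within the step;
* **peak ||GRF||** [%BW] - value of the first local maximum of the stance
  plate's body-weight-normalized GRF magnitude after loading onset.

The trunk angle is the 3-D angle between the trunk axis (pelvis origin to
the C7/CLAV midpoint) and the global vertical, signed by the sagittal-plane
projection: positive when the axis tilts anteriorly (flexion).  A pure
sagittal-projection variant is available via ``mode="sagittal"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, TRUNK_MARKERS, TrialRecording
from .events import StepSegment


@dataclass
class StepMetricsRecord:
    perturbation_index: int
    label: str
    stance_side: str                 # "intact" | "prosthetic"
    trunk_sway: float                # deg
    peak_flexion_velocity: float     # deg/s
    peak_grf: float                  # %BW
    kinematic_valid: bool = True
    kinetic_valid: bool = True
    flexion_peak_flagged: bool = False   # no positive-velocity sample in step
    grf_peak_flagged: bool = False       # no interior local maximum


class MissingStanceError(RuntimeError):
    """The stance plate is never loaded within the step window."""


# ---------------------------------------------------------------------------
# trunk kinematics
# ---------------------------------------------------------------------------

def trunk_angle_series(markers: dict, pelvis_origin: np.ndarray,
                       mode: str = "3d") -> np.ndarray:
    """Trunk-to-vertical angle in degrees, positive in flexion.

    ``mode="3d"`` measures the full 3-D angle to +Z with the sign of the
    sagittal (X-Z) tilt; ``mode="sagittal"`` measures the angle of the
    sagittal projection only.
    """
    mid = 0.5 * (markers[TRUNK_MARKERS[0]] + markers[TRUNK_MARKERS[1]])
    axis = mid - pelvis_origin
    norm = np.linalg.norm(axis, axis=1)
    if np.any(norm[np.isfinite(norm)] < 1e-9):
        raise ConfigError("degenerate trunk axis (zero length)")
    if mode == "sagittal":
        theta = np.degrees(np.arctan2(axis[:, 0], axis[:, 2]))
    elif mode == "3d":
        cosang = np.clip(axis[:, 2] / norm, -1.0, 1.0)
        theta = np.degrees(np.arccos(cosang))
        theta = np.where(axis[:, 0] >= 0, theta, -theta)
    else:
        raise ConfigError(f"unknown trunk-angle mode {mode!r}")
    return theta


def trunk_angular_velocity_series(angle_series: np.ndarray, rate: float) -> np.ndarray:
    """Time derivative of the trunk angle: central differences in the
    interior, one-sided differences at the endpoints."""
    angle_series = np.asarray(angle_series, dtype=float)
    if angle_series.size < 2:
        raise ConfigError("need at least 2 samples to differentiate")
    return np.gradient(angle_series, 1.0 / rate)


def _window(series: np.ndarray, segment: StepSegment, rate: float) -> np.ndarray:
    i0 = int(np.ceil(segment.start * rate - 1e-9))
    i1 = int(np.ceil(segment.end * rate - 1e-9))
    if i1 <= i0 or i0 < 0 or i0 >= series.shape[0]:
        raise ConfigError(f"empty or out-of-range step window [{segment.start}, {segment.end})")
    return series[i0:min(i1, series.shape[0])]


def step_trunk_sway(angle_series: np.ndarray, segment: StepSegment,
                    rate: float) -> float:
    """Range of the trunk angle over [start, end)."""
    w = _window(angle_series, segment, rate)
    return float(np.nanmax(w) - np.nanmin(w))


def step_peak_flexion_velocity(velocity_series: np.ndarray, segment: StepSegment,
                               rate: float):
    """Maximum trunk angular velocity in the flexion (positive) direction.

    Returns ``(value, flagged)``; if the velocity never becomes positive the
    window maximum (least negative value) is returned flagged.
    """
    w = _window(velocity_series, segment, rate)
    peak = float(np.nanmax(w))
    return peak, peak <= 0.0


# ---------------------------------------------------------------------------
# ground reaction forces
# ---------------------------------------------------------------------------

def grf_magnitude_series(forces: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the 3-D force series."""
    f = np.asarray(forces, dtype=float)
    return np.sqrt(f[:, 0] ** 2 + f[:, 1] ** 2 + f[:, 2] ** 2)


def step_peak_grf(grf_pct_bw: np.ndarray, segment: StepSegment, rate: float,
                  bw_newtons: float, loading_threshold_n: float = 20.0,
                  prominence_pct_bw: float = 2.0):
    """Value of the first ||GRF|| peak of the step's stance.

    Loading onset is the first sample where the normalized magnitude rises
    through the 20 N equivalent; the peak is the first subsequent local
    maximum with at least the given prominence.  With no interior maximum
    the window maximum is returned flagged.  Returns ``(value, flagged)``.
    """
    from scipy.signal import find_peaks

    w = _window(grf_pct_bw, segment, rate)
    gate = 100.0 * loading_threshold_n / bw_newtons
    loaded = np.flatnonzero(np.nan_to_num(w) > gate)
    if loaded.size == 0:
        raise MissingStanceError(
            f"stance plate never loaded above {loading_threshold_n} N in step "
            f"{segment.label}")
    x = np.nan_to_num(w[loaded[0]:])
    peaks, _ = find_peaks(x, prominence=prominence_pct_bw)
    if peaks.size:
        return float(x[peaks[0]]), False
    return float(np.max(x)), True


# ---------------------------------------------------------------------------
# per-perturbation assembly
# ---------------------------------------------------------------------------

def compute_step_metrics(trial: TrialRecording, segments: list,
                         perturbation_index: int, bw_value: float,
                         trunk_mode: str = "3d") -> list:
    """All three measures for each of the four steps of one perturbation.

    ``kinematic_valid`` is cleared when the trunk trace contains NaN inside a
    step (unfilled marker gaps); ``kinetic_valid`` when the stance plate is
    never loaded.
    """
    pelvis = trial.pelvis_origin()
    theta = trunk_angle_series(trial.markers, pelvis, mode=trunk_mode)
    omega = trunk_angular_velocity_series(theta, trial.marker_rate)
    grf_pct = {side: 100.0 * grf_magnitude_series(trial.forces[side]) / bw_value
               for side in trial.forces}
    records = []
    for seg in segments:
        theta_w = _window(theta, seg, trial.marker_rate)
        kin_ok = bool(np.isfinite(theta_w).all())
        sway = step_trunk_sway(theta, seg, trial.marker_rate)
        pfv, pfv_flag = step_peak_flexion_velocity(omega, seg, trial.marker_rate)
        try:
            grf, grf_flag = step_peak_grf(grf_pct[seg.stance_limb], seg,
                                          trial.force_rate, bw_value)
            kinetic_ok = True
        except MissingStanceError:
            grf, grf_flag, kinetic_ok = float("nan"), True, False
        records.append(StepMetricsRecord(
            perturbation_index=perturbation_index, label=seg.label,
            stance_side=seg.stance_side, trunk_sway=sway,
            peak_flexion_velocity=pfv, peak_grf=grf,
            kinematic_valid=kin_ok, kinetic_valid=kinetic_ok,
            flexion_peak_flagged=pfv_flag, grf_peak_flagged=grf_flag))
    return records
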