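"""Shared containers and errors for treadmill perturbation trials.

A trial bundle holds three synchronized streams sharing one time origin
(t = 0 at the first sample of every stream):

* marker trajectories (metres) sampled at the marker rate, with a per-sample
  validity mask per marker;
* per-belt 3-D force-plate series (newtons) sampled at the force rate;
* the belt-speed command series (m/s) on the force-rate clock.

Coordinate frame: right-handed with +X the direction of walking progression,
+Y to the participant's left, +Z vertical up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRAVITY = 9.81  # m/s^2

SIDES = ("left", "right")

#: Markers the pipeline consumes.  Heel/toe drive gait events, fingers drive
#: the handrail-grab detector, SACR/LASI/RASI define the pelvis origin and
#: C7/CLAV the trunk axis.
REQUIRED_MARKERS = (
    "L_HEEL", "R_HEEL", "L_TOE", "R_TOE",
    "L_FINGER", "R_FINGER",
    "SACR", "LASI", "RASI", "C7", "CLAV",
)

PELVIS_MARKERS = ("SACR", "LASI", "RASI")
TRUNK_MARKERS = ("C7", "CLAV")
STEP_LABELS = ("pert", "rec1", "rec2", "rec3")


class ConfigError(ValueError):
    """An invalid simulation or pipeline configuration value."""


class SchedulingError(RuntimeError):
    """The trial cannot fit the requested perturbations at the required spacing."""


class MalformedTrialError(RuntimeError):
    """A trial violates a structural assumption (e.g. non-returning belt speed)."""


class TruncatedRecoveryError(RuntimeError):
    """Too few post-perturbation gait events to build all recovery steps."""

    def __init__(self, missing_labels):
        self.missing_labels = tuple(missing_labels)
        super().__init__(
            "insufficient gait events after perturbation; missing steps: "
            + ", ".join(self.missing_labels)
        )


class InferenceError(RuntimeError):
    """A statistical routine received groups too small or empty to analyse."""


def other_side(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    return "right" if side == "left" else "left"


@dataclass
class TrialMeta:
    """Per-trial metadata."""

    participant_mass: float          # kg
    snp_condition: str               # "active" | "inactive"
    perturbation_duration: float     # s
    prosthetic_side: str = "right"   # "left" | "right"
    preferred_speed: float = 1.1     # m/s

    def limb_of(self, label: str) -> str:
        """Map an {intact, prosthetic} label to a physical side."""
        if label == "prosthetic":
            return self.prosthetic_side
        if label == "intact":
            return other_side(self.prosthetic_side)
        raise ValueError(f"unknown limb label {label!r}")

    def label_of(self, limb: str) -> str:
        """Map a physical side to its {intact, prosthetic} label."""
        return "prosthetic" if limb == self.prosthetic_side else "intact"


@dataclass
class TrialRecording:
    """Synchronized marker, force, and belt-speed series for one walking block."""

    markers: dict                    # name -> (N, 3) float array [m]
    marker_valid: dict               # name -> (N,) bool array
    marker_rate: float               # Hz
    forces: dict                     # "left"/"right" -> (M, 3) float array [N]
    force_rate: float                # Hz
    belt_speed: np.ndarray           # (M,) float array [m/s]
    meta: TrialMeta
    marker_filled: dict = field(default_factory=dict)  # name -> (N,) bool, gap-filled samples

    @property
    def n_marker_samples(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def n_force_samples(self) -> int:
        return next(iter(self.forces.values())).shape[0]

    @property
    def duration(self) -> float:
        return self.n_force_samples / self.force_rate

    def marker_time(self) -> np.ndarray:
        return np.arange(self.n_marker_samples) / self.marker_rate

    def force_time(self) -> np.ndarray:
        return np.arange(self.n_force_samples) / self.force_rate

    def pelvis_origin(self) -> np.ndarray:
        """Centroid of the pelvis markers, (N, 3)."""
        return np.mean([self.markers[m] for m in PELVIS_MARKERS], axis=0)

    def copy(self) -> "TrialRecording":
        return TrialRecording(
            markers={k: v.copy() for k, v in self.markers.items()},
            marker_valid={k: v.copy() for k, v in self.marker_valid.items()},
            marker_rate=self.marker_rate,
            forces={k: v.copy() for k, v in self.forces.items()},
            force_rate=self.force_rate,
            belt_speed=self.belt_speed.copy(),
            meta=self.meta,
            marker_filled={k: v.copy() for k, v in self.marker_filled.items()},
        )


@dataclass
class StaticTrial:
    """A stationary T-pose recording used to measure body weight."""

    forces: dict                     # "left"/"right" -> (M, 3) float array [N]
    rate: float                      # Hz

    @property
    def duration(self) -> float:
        return next(iter(self.forces.values())).shape[0] / self.rate


@dataclass
class GroundTruthPerturbation:
    onset: float                     # s
    limb: str                        # "left" | "right"
    side: str                        # "intact" | "prosthetic"
    duration: float                  # s
    cycle_fraction: float            # onset position within the limb's gait cycle


@dataclass
class GroundTruth:
    """Oracle annotations emitted by the synthetic generator."""

    heel_strikes: dict = field(default_factory=lambda: {s: np.array([]) for s in SIDES})
    toe_offs: dict = field(default_factory=lambda: {s: np.array([]) for s in SIDES})
    perturbations: list = field(default_factory=list)   # GroundTruthPerturbation
    injected_metrics: dict = field(default_factory=dict)
    #: (pert_index, label) -> {"trunk_sway": deg, "peak_flexion_velocity": deg/s,
    #:                          "peak_grf": %BW}
    handrail_grabs: list = field(default_factory=list)  # (start, end, pert_index)
    corrupted_segments: list = field(default_factory=list)
    #: (kind, start, end, pert_index, detail) with kind in {"dropout", "midline"}

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            heel_strikes={k: v.copy() for k, v in self.heel_strikes.items()},
            toe_offs={k: v.copy() for k, v in self.toe_offs.items()},
            perturbations=list(self.perturbations),
            injected_metrics=dict(self.injected_metrics),
            handrail_grabs=list(self.handrail_grabs),
            corrupted_segments=list(self.corrupted_segments),
        )
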