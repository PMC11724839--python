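"""Simulation configuration for the synthetic treadmill-trial generator.

The defaults encode the study conditions the pipeline is designed for: walking
at a self-selected treadmill speed, belt perturbations accelerating at
3 m/s^2 for half the perturbation duration and decelerating for the other
half, triggered in early stance when the perturbed side's vertical GRF
exceeds 100 N, about 12 perturbations per side spaced at least 10 strides
apart, markers at 100 Hz and force plates at 1000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .core import ConfigError, STEP_LABELS

#: Baseline (no stimulation effect) stumble-response magnitudes per step label:
#: trunk angular sway [deg], peak trunk flexion angular velocity [deg/s], and
#: first-peak ||GRF|| [%BW].  The response is largest on the first recovery
#: step and decays back toward steady gait by rec3.
DEFAULT_BASELINE_RESPONSE = {
    "pert": {"trunk_sway": 6.0, "peak_flexion_velocity": 50.0, "peak_grf": 115.0},
    "rec1": {"trunk_sway": 9.0, "peak_flexion_velocity": 70.0, "peak_grf": 120.0},
    "rec2": {"trunk_sway": 7.0, "peak_flexion_velocity": 60.0, "peak_grf": 115.0},
    "rec3": {"trunk_sway": 6.0, "peak_flexion_velocity": 50.0, "peak_grf": 112.0},
}

#: Per-trial Gaussian spread of the injected step metrics, chosen to match
#: the between-perturbation variability implied by reported standard errors
#: at group sizes near 60 (sd ~ SE * sqrt(n)).  The two trunk metrics covary
#: through a common response-intensity factor (bigger stumbles flex faster),
#: which also keeps injected responses realizable at the marker bandwidth.
DEFAULT_METRIC_NOISE_SD = {
    "trunk_sway": 2.0,          # deg
    "peak_flexion_velocity": 10.0,  # deg/s
    "peak_grf": 8.0,            # %BW
}

METRICS = ("trunk_sway", "peak_flexion_velocity", "peak_grf")


@dataclass
class SimulationConfig:
    # gait
    preferred_speed: float = 1.1         # m/s
    cadence: float = 90.0                # steps/min
    duration: float = 60.0               # s, steady-gait trial length
    stance_fraction: float = 0.62        # stance duration / stride duration
    participant_mass: float = 75.0       # kg
    prosthetic_side: str = "right"
    # sampling
    marker_rate: float = 100.0           # Hz
    force_rate: float = 1000.0           # Hz
    # perturbations
    perturbation_accel: float = 3.0      # m/s^2
    perturbation_duration: float = 0.8   # s (0.8 or 0.6 in the emulated protocol)
    n_perturbations_per_side: int = 12
    min_spacing: int = 10                # strides between consecutive onsets
    trigger_force: float = 100.0         # N, vertical GRF crossing that starts a perturbation
    # stumble response
    snp_condition: str = "inactive"      # "active" | "inactive"
    effect_profile: dict = field(default_factory=dict)
    #: (perturbed side label, step label) -> {metric: additive offset}; applied
    #: only when snp_condition == "active".
    baseline_response: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_BASELINE_RESPONSE.items()})
    metric_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_METRIC_NOISE_SD))
    # measurement noise
    marker_noise_sd: float = 0.0015      # m
    force_noise_sd: float = 2.0          # N
    # corruption
    handrail_grab_probability: float = 0.0
    handrail_grab_span: float = 0.35     # s
    dropout_probability: float = 0.0
    dropout_fraction: float = 0.06       # fraction of the response window dropped
    dropout_marker: str = "C7"
    midline_cross_probability: float = 0.0
    # steady-gait shape
    grf_first_peak: float = 110.0        # %BW, steady walking
    grf_second_peak: float = 105.0       # %BW
    baseline_trunk_lean: float = 5.0     # deg, mean forward lean
    trunk_osc_amp: float = 1.0           # deg, steady-gait trunk oscillation
    trunk_bandlimit: float = 6.0         # Hz, band limit of trunk responses
    seed: int = 0

    def __post_init__(self):
        if self.marker_rate <= 0 or self.force_rate <= 0:
            raise ConfigError("sampling rates must be positive")
        if self.participant_mass <= 0:
            raise ConfigError("participant mass must be positive")
        if self.preferred_speed <= 0 or self.cadence <= 0:
            raise ConfigError("preferred_speed and cadence must be positive")
        if self.perturbation_accel <= 0:
            raise ConfigError("perturbation_accel must be positive")
        if self.perturbation_duration <= 0:
            raise ConfigError("perturbation_duration must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ConfigError("stance_fraction must lie in (0, 1)")
        for name in ("handrail_grab_probability", "dropout_probability",
                     "midline_cross_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ConfigError("dropout_fraction must lie in [0, 1]")
        if self.snp_condition not in ("active", "inactive"):
            raise ConfigError("snp_condition must be 'active' or 'inactive'")
        if self.n_perturbations_per_side < 0:
            raise ConfigError("n_perturbations_per_side must be non-negative")
        for label in self.baseline_response:
            if label not in STEP_LABELS:
                raise ConfigError(f"unknown step label {label!r} in baseline_response")

    # -- derived gait timing ------------------------------------------------
    @property
    def step_period(self) -> float:
        """Seconds per step (heel strike to contralateral heel strike)."""
        return 60.0 / self.cadence

    @property
    def stride_period(self) -> float:
        return 2.0 * self.step_period

    @property
    def stance_duration(self) -> float:
        return self.stance_fraction * self.stride_period

    def offsets_for(self, side_label: str, step_label: str) -> dict:
        """Effect-profile offsets for one (perturbed side, step) cell.

        Zero for every metric unless the stimulation condition is active and
        the profile names the cell.
        """
        if self.snp_condition != "active":
            return {m: 0.0 for m in METRICS}
        cell = self.effect_profile.get((side_label, step_label), {})
        return {m: float(cell.get(m, 0.0)) for m in METRICS}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_profile"] = {f"{s}/{l}": v for (s, l), v in self.effect_profile.items()}
        return d
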