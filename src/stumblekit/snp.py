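"""Closed-loop plantar-pressure-to-stimulation mapping.

An instrumented insole with eight force-sensing resistors (FSRs) is grouped
into three plantar regions - heel (2 sensors), midfoot (1), metatarsal (5).
Each region's pressure is the mean of its sensors.  Stimulation intensity is
modulated by pulse width at a fixed per-region amplitude: zero below a
calibrated threshold pressure, linear between threshold and saturation, and
clamped above.  Commands are issued on a fixed 50 ms inter-pulse interval,
latching the most recent insole frame regardless of the insole frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError

N_SENSORS = 8
REGIONS = {"heel": (0, 1), "midfoot": (2,), "metatarsal": (3, 4, 5, 6, 7)}

AMPLITUDE_RANGE = (0.8, 2.0)     # mA
WIDTH_RANGE = (0.0, 255.0)       # us
INTER_PULSE_INTERVAL = 0.050     # s


@dataclass
class InsoleFrame:
    fsr_values: np.ndarray           # 8 pressures
    timestamp: float                 # s

    def __post_init__(self):
        self.fsr_values = np.asarray(self.fsr_values, dtype=float)
        if self.fsr_values.shape != (N_SENSORS,):
            raise ConfigError(f"expected exactly {N_SENSORS} FSR values")


@dataclass
class RegionCalibration:
    threshold_pressure: float
    saturation_pressure: float
    width_at_threshold: float        # us
    width_at_saturation: float       # us
    amplitude: float                 # mA

    def __post_init__(self):
        if not self.threshold_pressure < self.saturation_pressure:
            raise ConfigError("threshold pressure must be below saturation")
        lo, hi = WIDTH_RANGE
        for w in (self.width_at_threshold, self.width_at_saturation):
            if not lo <= w <= hi:
                raise ConfigError(f"pulse width {w} outside [{lo}, {hi}] us")
        if not AMPLITUDE_RANGE[0] <= self.amplitude <= AMPLITUDE_RANGE[1]:
            raise ConfigError(
                f"amplitude {self.amplitude} outside "
                f"[{AMPLITUDE_RANGE[0]}, {AMPLITUDE_RANGE[1]}] mA")


@dataclass
class StimCommand:
    timestamp: float
    pulse_amplitude: dict            # region -> mA (0 when silent)
    pulse_width: dict                # region -> us
    inter_pulse_interval: float = INTER_PULSE_INTERVAL


def region_pressures(frame: InsoleFrame) -> dict:
    """Arithmetic mean of each region's sensors."""
    return {name: float(frame.fsr_values[list(idx)].mean())
            for name, idx in REGIONS.items()}


def pressure_to_stimulation(region_value: float,
                            calibration: RegionCalibration) -> tuple:
    """(amplitude mA, pulse width us) for one region's pressure.

    Width is 0 below the threshold pressure, interpolates linearly up to the
    saturation pressure, and clamps there; amplitude is the calibrated
    per-region constant whenever stimulation is on.
    """
    c = calibration
    if region_value < c.threshold_pressure:
        return 0.0, 0.0
    if region_value >= c.saturation_pressure:
        return c.amplitude, c.width_at_saturation
    frac = ((region_value - c.threshold_pressure)
            / (c.saturation_pressure - c.threshold_pressure))
    width = c.width_at_threshold + frac * (c.width_at_saturation - c.width_at_threshold)
    return c.amplitude, float(width)


def frame_to_command(frame: InsoleFrame, calibrations: dict,
                     timestamp: float | None = None) -> StimCommand:
    """Full stimulation command for one insole frame."""
    pressures = region_pressures(frame)
    amps, widths = {}, {}
    for region, p in pressures.items():
        amps[region], widths[region] = pressure_to_stimulation(
            p, calibrations[region])
    return StimCommand(
        timestamp=frame.timestamp if timestamp is None else timestamp,
        pulse_amplitude=amps, pulse_width=widths)


def stream_commands(frames: list, calibrations: dict,
                    end_time: float | None = None) -> list:
    """Emit commands on the fixed 50 ms clock, each latching the most recent
    insole frame at or before the command instant."""
    frames = sorted(frames, key=lambda f: f.timestamp)
    if not frames:
        return []
    if end_time is None:
        end_time = frames[-1].timestamp
    commands = []
    t = frames[0].timestamp
    i = 0
    while t <= end_time + 1e-12:
        while i + 1 < len(frames) and frames[i + 1].timestamp <= t + 1e-12:
            i += 1
        commands.append(frame_to_command(frames[i], calibrations, timestamp=t))
        t += INTER_PULSE_INTERVAL
    return commands
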