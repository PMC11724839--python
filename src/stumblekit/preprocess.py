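"""Filtering and normalization of raw marker and force series.

Markers are low-pass filtered at 6 Hz and forces at 10 Hz with zero-phase
4th-order Butterworth filters, followed by a 3-sample median filter to remove
impulse noise.  Forces are normalized to percent body weight, where body
weight is the time-averaged magnitude of the summed plate forces recorded
while the participant stood still.

All filters are NaN-tolerant: each contiguous finite run is filtered
independently so that unfilled marker gaps stay local instead of propagating
through the filter state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import CubicSpline

from .core import ConfigError, StaticTrial, TrialRecording


@dataclass
class BodyWeight:
    """Body weight in newtons measured from a static trial."""

    value: float             # N
    source_duration: float   # s

    def __post_init__(self):
        if not self.value > 0:
            raise ConfigError("body weight must be positive")


def _finite_runs(x: np.ndarray):
    """Start/stop index pairs of maximal finite runs along a 1-D view."""
    finite = np.isfinite(x)
    if finite.all():
        return [(0, x.size)]
    idx = np.flatnonzero(np.diff(finite.astype(np.int8)))
    edges = np.concatenate([[0], idx + 1, [x.size]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if finite[a]]


def lowpass_butterworth(series: np.ndarray, cutoff: float, rate: float,
                        order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    ``order`` is the design order of the underlying filter; the effective
    attenuation is squared by the bidirectional pass, so the gain at the
    cutoff frequency is 1/2 rather than 1/sqrt(2).
    """
    if not 0 < cutoff < rate / 2:
        raise ConfigError("cutoff must lie in (0, Nyquist)")
    series = np.asarray(series, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    out = series.copy()
    flat = out.reshape(series.shape[0], -1)
    default_padlen = 3 * (2 * sos.shape[0] + 1)
    for col in range(flat.shape[1]):
        x = flat[:, col]
        for a, b in _finite_runs(x):
            seg = x[a:b]
            padlen = min(default_padlen, seg.size - 1)
            if padlen < 1:
                continue
            x[a:b] = signal.sosfiltfilt(sos, seg, padlen=padlen)
    return out.reshape(series.shape)


def median_filter3(series: np.ndarray) -> np.ndarray:
    """3-sample sliding median with edge replication at the boundaries."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ConfigError("median filter needs at least 3 samples")
    out = series.copy()
    flat = out.reshape(series.shape[0], -1)
    for col in range(flat.shape[1]):
        x = flat[:, col]
        for a, b in _finite_runs(x):
            if b - a >= 3:
                x[a:b] = ndimage.median_filter(x[a:b], size=3, mode="nearest")
    return out.reshape(series.shape)


def fill_marker_gaps(trial: TrialRecording, max_gap: int = 10) -> TrialRecording:
    """Cubic-spline interpolation of short marker gaps.

    Invalid runs of length <= ``max_gap`` frames are replaced by a cubic
    spline through the valid samples and flagged in ``marker_filled``; longer
    runs and runs touching a series boundary are left invalid (NaN).  The
    original validity mask is preserved so downstream completeness screening
    sees the pre-interpolation state.
    """
    trial = trial.copy()
    for name, valid in trial.marker_valid.items():
        filled = np.zeros(valid.size, dtype=bool)
        if valid.all():
            trial.marker_filled[name] = filled
            continue
        pos = trial.markers[name]
        pos[~valid] = np.nan
        good = np.flatnonzero(valid)
        if good.size < 4:
            trial.marker_filled[name] = filled
            continue
        spline = CubicSpline(good, pos[good], axis=0)
        for a, b in _invalid_runs(valid):
            if b - a <= max_gap and a > 0 and b < valid.size:
                idx = np.arange(a, b)
                pos[idx] = spline(idx)
                filled[idx] = True
        trial.marker_filled[name] = filled
    return trial


def _invalid_runs(valid: np.ndarray):
    idx = np.flatnonzero(np.diff(valid.astype(np.int8)))
    edges = np.concatenate([[0], idx + 1, [valid.size]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if not valid[a]]


def body_weight_from_static(static: StaticTrial) -> BodyWeight:
    """Time-averaged magnitude of the summed plate force vectors."""
    total = sum(np.asarray(f, dtype=float) for f in static.forces.values())
    if total.shape[0] == 0:
        raise ConfigError("static trial is empty")
    mag = np.linalg.norm(total, axis=1)
    return BodyWeight(value=float(mag.mean()), source_duration=static.duration)


def normalize_to_bw(force_series: np.ndarray, bw: BodyWeight) -> np.ndarray:
    """Express a force-magnitude series in percent body weight."""
    if bw.value <= 0:
        raise ConfigError("body weight must be positive")
    return 100.0 * np.abs(np.asarray(force_series, dtype=float)) / bw.value


def preprocess_trial(trial: TrialRecording, marker_cutoff: float = 6.0,
                     force_cutoff: float = 10.0, order: int = 4,
                     max_gap: int = 10, median_window: bool = True) -> TrialRecording:
    """Gap-fill, Butterworth-filter, and median-filter a full trial.

    Interpolation precedes filtering so short gaps do not split the filter
    segments; the median stage follows the Butterworth stage on both marker
    and force channels.
    """
    trial = fill_marker_gaps(trial, max_gap=max_gap)
    for name in trial.markers:
        x = lowpass_butterworth(trial.markers[name], marker_cutoff,
                                trial.marker_rate, order)
        trial.markers[name] = median_filter3(x) if median_window else x
    for side in trial.forces:
        f = lowpass_butterworth(trial.forces[side], force_cutoff,
                                trial.force_rate, order)
        trial.forces[side] = median_filter3(f) if median_window else f
    return trial
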