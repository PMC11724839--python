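"""Gait events, perturbation detection, and recovery-step segmentation.

Heel strikes and toe-offs are detected with the coordinate-based method: the
anterior-posterior position of each foot's heel marker relative to the pelvis
origin attains a per-cycle maximum at heel strike, and the toe marker's
relative position a per-cycle minimum at toe-off.  Perturbations are read
from the belt-speed channel as excursions above the steady speed, and each
perturbation's recovery sequence is tiled into four contiguous steps:

* ``pert`` - from the perturbed limb's heel strike preceding onset to the
  first contralateral heel strike after onset (the step taken while the belt
  accelerates and decelerates);
* ``rec1`` - to the next perturbed-side heel strike (contralateral stance);
* ``rec2`` and ``rec3`` - continuing alternately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    MalformedTrialError,
    SIDES,
    TrialMeta,
    TrialRecording,
    TruncatedRecoveryError,
    other_side,
)


class UndefinedCycleFraction(ValueError):
    """The queried instant is not bracketed by two heel strikes of the side."""


@dataclass
class GaitEventTable:
    heel_strikes: dict   # side -> ascending times [s]
    toe_offs: dict       # side -> ascending times [s]

    def is_empty(self) -> bool:
        return all(self.heel_strikes[s].size == 0 for s in SIDES)


@dataclass
class PerturbationRecord:
    onset: float                     # s
    limb: str                        # "left" | "right"
    side: str                        # "intact" | "prosthetic"
    duration: float                  # s
    onset_cycle_fraction: float      # NaN when undefined
    block_index: int = 0
    within_block_side_ordinal: int = 1


@dataclass
class StepSegment:
    label: str                       # pert | rec1 | rec2 | rec3
    stance_limb: str                 # "left" | "right"
    stance_side: str                 # "intact" | "prosthetic"
    start: float                     # s
    end: float                       # s


# ---------------------------------------------------------------------------
# gait events
# ---------------------------------------------------------------------------

def _dominant_stride_freq(x: np.ndarray, rate: float):
    """Dominant frequency of a (roughly periodic) series in [0.2, 2] Hz."""
    x = np.nan_to_num(x - np.nanmean(x))
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size)))
    freqs = np.fft.rfftfreq(x.size, 1.0 / rate)
    band = (freqs >= 0.2) & (freqs <= 2.0)
    if not band.any() or spec[band].max() <= 0:
        return None
    # require the band peak to stand out over the broadband level
    if spec[band].max() < 5.0 * np.median(spec[freqs > 0.1] + 1e-12):
        return None
    return float(freqs[band][np.argmax(spec[band])])


def detect_gait_events(markers: dict, pelvis_origin: np.ndarray,
                       rate: float) -> GaitEventTable:
    """Detect heel strikes and toe-offs from heel/toe markers.

    Alternation within a side is enforced by discarding the weaker of two
    same-type events with no opposite event between them.
    """
    heel_strikes, toe_offs = {}, {}
    for side, prefix in (("left", "L"), ("right", "R")):
        rel_heel = markers[f"{prefix}_HEEL"][:, 0] - pelvis_origin[:, 0]
        rel_toe = markers[f"{prefix}_TOE"][:, 0] - pelvis_origin[:, 0]
        freq = _dominant_stride_freq(rel_heel, rate)
        if freq is None or np.nanstd(rel_heel) < 0.01:
            warnings.warn(f"no periodic gait detected on the {side} side")
            heel_strikes[side] = np.array([])
            toe_offs[side] = np.array([])
            continue
        if rel_heel.size < 2 * rate / freq:
            warnings.warn(f"fewer than two gait cycles on the {side} side")
            heel_strikes[side] = np.array([])
            toe_offs[side] = np.array([])
            continue
        distance = max(int(0.7 * rate / freq), 1)
        hs_idx, _ = sps.find_peaks(np.nan_to_num(rel_heel, nan=-1e9), distance=distance)
        to_idx, _ = sps.find_peaks(np.nan_to_num(-rel_toe, nan=-1e9), distance=distance)
        hs_idx, to_idx = _enforce_alternation(hs_idx, to_idx, rel_heel, -rel_toe)
        heel_strikes[side] = hs_idx / rate
        toe_offs[side] = to_idx / rate
    return GaitEventTable(heel_strikes=heel_strikes, toe_offs=toe_offs)


def _enforce_alternation(hs_idx, to_idx, hs_strength, to_strength):
    """Drop the weaker of two same-type events with none of the other type
    between them."""
    events = ([(i, 0, hs_strength[i]) for i in hs_idx]
              + [(i, 1, to_strength[i]) for i in to_idx])
    events.sort()
    kept = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    hs = np.array([i for i, kind, _ in kept if kind == 0], dtype=int)
    to = np.array([i for i, kind, _ in kept if kind == 1], dtype=int)
    return hs, to


def detect_events(trial: TrialRecording) -> GaitEventTable:
    """Convenience wrapper detecting events on a (preprocessed) trial."""
    return detect_gait_events(trial.markers, trial.pelvis_origin(),
                              trial.marker_rate)


# ---------------------------------------------------------------------------
# gait-cycle phase
# ---------------------------------------------------------------------------

def gait_cycle_fraction(t: float, events: GaitEventTable, side: str) -> float:
    """Position of ``t`` within the bracketing gait cycle of ``side``:
    (t - previous heel strike) / cycle duration."""
    hs = events.heel_strikes[side]
    before = hs[hs <= t]
    after = hs[hs > t]
    if before.size == 0 or after.size == 0:
        raise UndefinedCycleFraction(
            f"t={t:.3f}s is not inside a complete {side} gait cycle")
    prev, nxt = float(before[-1]), float(after[0])
    return (t - prev) / (nxt - prev)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def detect_perturbations(belt_speed: np.ndarray, rate: float,
                         events: GaitEventTable, meta: TrialMeta,
                         threshold: float = 0.05, baseline_tol: float = 1e-6,
                         block_index: int = 0) -> list:
    """Report belt-speed excursions above the steady speed as perturbations.

    The steady speed is the trial median; an excursion must depart by more
    than ``threshold`` and return.  The onset is the first sample above the
    baseline tolerance within the departure, the perturbed side is the limb
    in stance at onset (most recent heel strike without a subsequent
    toe-off; ties resolved to the later striker).
    """
    belt = np.asarray(belt_speed, dtype=float)
    steady = float(np.median(belt))
    above = belt > steady + threshold
    if not above.any():
        return []
    idx = np.flatnonzero(np.diff(above.astype(np.int8)))
    edges = np.concatenate([[0], idx + 1, [belt.size]])
    records = []
    counts = {"left": 0, "right": 0}
    for a, b in zip(edges[:-1], edges[1:]):
        if not above[a]:
            continue
        if b >= belt.size and above[-1]:
            raise MalformedTrialError("belt speed does not return to baseline")
        # expand to where the speed actually leaves/rejoins the baseline
        i = a
        while i > 0 and belt[i - 1] > steady + baseline_tol:
            i -= 1
        j = b
        while j < belt.size and belt[j] > steady + baseline_tol:
            j += 1
        if j >= belt.size:
            raise MalformedTrialError("belt speed does not return to baseline")
        onset = i / rate
        duration = (j - i) / rate
        limb = _stance_limb_at(onset, events)
        try:
            frac = gait_cycle_fraction(onset, events, limb)
        except UndefinedCycleFraction:
            frac = float("nan")
        counts[limb] += 1
        records.append(PerturbationRecord(
            onset=onset, limb=limb, side=meta.label_of(limb), duration=duration,
            onset_cycle_fraction=frac, block_index=block_index,
            within_block_side_ordinal=counts[limb]))
    return records


def _stance_limb_at(t: float, events: GaitEventTable) -> str:
    """Limb in stance at time ``t``: most recent heel strike with no
    subsequent toe-off; during double support, the later striker."""
    best, best_hs = None, -np.inf
    for side in SIDES:
        hs = events.heel_strikes[side]
        to = events.toe_offs[side]
        last_hs = hs[hs <= t]
        if last_hs.size == 0:
            continue
        last_hs = float(last_hs[-1])
        in_stance = not ((to > last_hs) & (to <= t)).any()
        if in_stance and last_hs > best_hs:
            best, best_hs = side, last_hs
    if best is None:
        # both feet between events; fall back to the most recent striker
        for side in SIDES:
            hs = events.heel_strikes[side]
            if hs.size and float(hs[hs <= t][-1] if (hs <= t).any() else -np.inf) > best_hs:
                best, best_hs = side, float(hs[hs <= t][-1])
    if best is None:
        raise MalformedTrialError(f"no heel strikes precede t={t:.3f} s")
    return best


# ---------------------------------------------------------------------------
# recovery-step segmentation
# ---------------------------------------------------------------------------

def segment_recovery_steps(pert: PerturbationRecord, events: GaitEventTable,
                           meta: TrialMeta) -> list:
    """The four step segments of one perturbation's recovery sequence.

    Steps tile time contiguously; stance sides alternate, with ``pert`` and
    ``rec2`` on the perturbed limb and ``rec1`` and ``rec3`` contralateral.
    """
    limb, contra = pert.limb, other_side(pert.limb)
    hs_p, hs_c = events.heel_strikes[limb], events.heel_strikes[contra]
    before = hs_p[hs_p <= pert.onset]
    if before.size == 0:
        raise TruncatedRecoveryError(["pert", "rec1", "rec2", "rec3"])
    bounds = [float(before[-1])]
    plan = [("pert", limb, hs_c), ("rec1", contra, hs_p),
            ("rec2", limb, hs_c), ("rec3", contra, hs_p)]
    missing = []
    segments = []
    cur = bounds[0]
    for label, stance_limb, arr in plan:
        nxt = arr[arr > cur]
        if nxt.size == 0:
            missing.append(label)
            continue
        end = float(nxt[0])
        segments.append(StepSegment(
            label=label, stance_limb=stance_limb,
            stance_side=meta.label_of(stance_limb), start=cur, end=end))
        cur = end
    if missing:
        raise TruncatedRecoveryError(missing)
    return segments
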