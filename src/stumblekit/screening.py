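"""Per-perturbation inclusion screening and handrail-grab tallying.

Five rules decide whether a perturbation contributes to the kinematic
(trunk) and kinetic (GRF) analyses:

1. the first two perturbations to each side of every walking block are
   warm-up and always excluded;
2. the perturbation must have been initiated within the first 20 % of the
   gait cycle (inclusive);
3. the participant must not have grabbed a handrail - finger-marker speed
   below 5 cm/s sustained for at least 50 ms anywhere between perturbation
   onset and the end of the third recovery step;
4. kinematic analyses additionally require marker completeness: no required
   marker may be missing for more than 5 % of the window (pre-interpolation
   mask, applied per marker by default);
5. kinetic analyses additionally require belt separation: each plate's
   vertical GRF must stay below 20 N for at least 15 % of every gait cycle
   in the window (a loaded "swing" plate indicates a mid-line crossing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import REQUIRED_MARKERS, SIDES, TrialRecording
from .events import GaitEventTable, PerturbationRecord


@dataclass
class PerturbationScreen:
    perturbation_index: int
    side: str                        # perturbed side label
    snp_condition: str
    warmup_excluded: bool
    onset_phase_ok: bool
    handrail_grab: bool
    kinematic_complete: bool
    kinetic_separated: bool
    reasons: list = field(default_factory=list)

    @property
    def kinematic_included(self) -> bool:
        return (not self.warmup_excluded and self.onset_phase_ok
                and not self.handrail_grab and self.kinematic_complete)

    @property
    def kinetic_included(self) -> bool:
        return (not self.warmup_excluded and self.onset_phase_ok
                and not self.handrail_grab and self.kinetic_separated)


@dataclass
class ScreeningReport:
    rows: list = field(default_factory=list)   # PerturbationScreen

    def handrail_counts(self) -> pd.DataFrame:
        """2x2 grab tally by perturbed side and stimulation condition."""
        table = pd.DataFrame(0, index=["intact", "prosthetic"],
                             columns=["inactive", "active"])
        for r in self.rows:
            if r.handrail_grab:
                table.loc[r.side, r.snp_condition] += 1
        return table

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "perturbation_index": r.perturbation_index, "side": r.side,
                "snp_condition": r.snp_condition,
                "warmup_excluded": r.warmup_excluded,
                "onset_phase_ok": r.onset_phase_ok,
                "handrail_grab": r.handrail_grab,
                "kinematic_complete": r.kinematic_complete,
                "kinetic_separated": r.kinetic_separated,
                "kinematic_included": r.kinematic_included,
                "kinetic_included": r.kinetic_included,
                "reasons": ";".join(r.reasons)})
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------

def exclude_warmup(perts: list, warmup_per_side: int = 2) -> list:
    """True for each perturbation that is one of the first ``warmup_per_side``
    to its side within its block."""
    return [p.within_block_side_ordinal <= warmup_per_side for p in perts]


def check_onset_phase(pert: PerturbationRecord, max_fraction: float = 0.20) -> bool:
    """Pass iff the onset gait-cycle fraction is defined and <= the bound
    (inclusive)."""
    f = pert.onset_cycle_fraction
    return bool(np.isfinite(f)) and f <= max_fraction


def detect_handrail_grabs(trial: TrialRecording, window: tuple,
                          speed_threshold: float = 0.05,
                          min_duration: float = 0.05) -> list:
    """Maximal intervals within ``window`` where either finger marker's speed
    stays below the threshold for at least ``min_duration``; overlapping
    intervals from the two hands are merged."""
    t0, t1 = window
    rate = trial.marker_rate
    tm = trial.marker_time()
    sel = (tm >= t0) & (tm <= t1)
    intervals = []
    for name in ("L_FINGER", "R_FINGER"):
        pos = trial.markers[name]
        vel = np.gradient(pos, 1.0 / rate, axis=0)
        speed = np.linalg.norm(vel, axis=1)
        slow = (speed < speed_threshold) & sel
        idx = np.flatnonzero(np.diff(np.concatenate([[0], slow.astype(np.int8), [0]])))
        for a, b in zip(idx[::2], idx[1::2]):
            if (b - 1 - a) / rate >= min_duration:
                intervals.append((tm[a], tm[b - 1]))
    return _merge_intervals(intervals)


def _merge_intervals(intervals: list) -> list:
    merged = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def check_marker_completeness(trial: TrialRecording, window: tuple,
                              max_missing_fraction: float = 0.05,
                              markers: tuple = REQUIRED_MARKERS,
                              pooled: bool = False) -> bool:
    """Pass iff missing-sample fractions within the window stay at or below
    the bound - per required marker by default, pooled across markers when
    requested.  Uses the pre-interpolation validity mask."""
    t0, t1 = window
    tm = trial.marker_time()
    sel = (tm >= t0) & (tm <= t1)
    n = int(sel.sum())
    if n == 0:
        return False
    fractions = [(~trial.marker_valid[m][sel]).sum() / n for m in markers]
    if pooled:
        return bool(np.mean(fractions) <= max_missing_fraction)
    return bool(max(fractions) <= max_missing_fraction)


def check_belt_separation(trial: TrialRecording, events: GaitEventTable,
                          window: tuple, cycle_side: str,
                          force_threshold: float = 20.0,
                          min_swing_fraction: float = 0.15) -> bool:
    """Pass iff each plate's vertical GRF stays below the threshold for at
    least ``min_swing_fraction`` of every gait cycle in the window.

    Cycles are bounded by consecutive heel strikes of ``cycle_side``; a
    window shorter than one cycle fails.
    """
    t0, t1 = window
    hs = events.heel_strikes[cycle_side]
    starts = hs[(hs >= t0 - 1e-9) & (hs < t1)]
    cycles = []
    for s in starts:
        nxt = hs[hs > s]
        if nxt.size and float(nxt[0]) <= t1 + 1e-9:
            cycles.append((float(s), float(nxt[0])))
    if not cycles:
        return False
    tf = trial.force_time()
    for a, b in cycles:
        sel = (tf >= a) & (tf < b)
        if not sel.any():
            return False
        for side in SIDES:
            vz = trial.forces[side][sel, 2]
            if np.mean(vz < force_threshold) < min_swing_fraction:
                return False
    return True


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def screen_perturbation(pert: PerturbationRecord, trial: TrialRecording,
                        events: GaitEventTable, segments: list,
                        index: int, *, warmup_flag: bool,
                        onset_max_fraction: float = 0.20,
                        grab_speed: float = 0.05, grab_min_duration: float = 0.05,
                        max_missing_fraction: float = 0.05,
                        completeness_pooled: bool = False,
                        swing_force_threshold: float = 20.0,
                        min_swing_fraction: float = 0.15) -> PerturbationScreen:
    """Apply all screening rules to one perturbation."""
    window = (pert.onset, segments[-1].end)
    full_window = (segments[0].start, segments[-1].end)
    reasons = []
    if warmup_flag:
        reasons.append("warmup")
    phase_ok = check_onset_phase(pert, onset_max_fraction)
    if not phase_ok:
        reasons.append("late_onset" if np.isfinite(pert.onset_cycle_fraction)
                       else "undefined_cycle_fraction")
    grabs = detect_handrail_grabs(trial, window, grab_speed, grab_min_duration)
    if grabs:
        reasons.append("handrail_grab")
    complete = check_marker_completeness(trial, full_window, max_missing_fraction,
                                         pooled=completeness_pooled)
    if not complete:
        reasons.append("marker_gap")
    separated = check_belt_separation(trial, events, full_window, pert.limb,
                                      swing_force_threshold, min_swing_fraction)
    if not separated:
        reasons.append("midline_cross")
    return PerturbationScreen(
        perturbation_index=index, side=pert.side,
        snp_condition=trial.meta.snp_condition, warmup_excluded=warmup_flag,
        onset_phase_ok=phase_ok, handrail_grab=bool(grabs),
        kinematic_complete=complete, kinetic_separated=separated,
        reasons=reasons)
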