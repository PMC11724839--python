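"""End-to-end analysis runs: preprocess -> events -> metrics -> screening ->
statistics, with a single config object holding every numeric constant the
pipeline uses.

Intact- and prosthetic-side perturbations are analysed separately; the
analysis unit for the mixed-design ANOVA is one perturbation trial, with the
stimulation condition (taken from each walking block's metadata) as the
between-group factor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ConfigError, GroundTruth, StaticTrial, TrialRecording
from .events import detect_events, detect_perturbations, segment_recovery_steps
from .io import load_bundle
from .metrics import compute_step_metrics
from .preprocess import body_weight_from_static, preprocess_trial
from .screening import ScreeningReport, exclude_warmup, screen_perturbation
from .stats import (
    bonferroni_posthoc,
    mixed_anova,
    welch_asymmetry_test,
    welch_two_group_asymmetry,
)

METRIC_COLUMNS = ("trunk_sway", "peak_flexion_velocity", "peak_grf")
KINEMATIC_METRICS = ("trunk_sway", "peak_flexion_velocity")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the analysis, defaulting to the protocol's
    printed values."""

    # preprocessing
    marker_cutoff: float = 6.0           # Hz
    force_cutoff: float = 10.0           # Hz
    filter_order: int = 4
    median_window: int = 3
    max_gap_frames: int = 10
    # event / perturbation detection
    belt_depart_threshold: float = 0.05  # m/s above steady speed
    trigger_force: float = 100.0         # N (simulator-side trigger rule)
    # screening
    onset_max_fraction: float = 0.20
    warmup_per_side: int = 2
    grab_speed: float = 0.05             # m/s
    grab_min_duration: float = 0.05      # s
    max_missing_fraction: float = 0.05
    completeness_pooled: bool = False
    swing_force_threshold: float = 20.0  # N
    min_swing_fraction: float = 0.15
    # statistics
    alpha: float = 0.05
    posthoc_family: int = 4
    welch_mode: str = "difference_of_differences"   # or "two_group"
    trunk_angle_mode: str = "3d"         # or "sagittal"
    seed: int = 0

    def __post_init__(self):
        if self.median_window != 3:
            raise ConfigError("median filter window is fixed at 3 samples")
        if self.welch_mode not in ("difference_of_differences", "two_group"):
            raise ConfigError(f"unknown welch_mode {self.welch_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class TrialAnalysis:
    trial_name: str
    events: object
    perturbations: list
    segments: dict                       # perturbation index -> [StepSegment]
    metrics: pd.DataFrame
    screening: ScreeningReport
    body_weight: float
    errors: list = field(default_factory=list)


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame
    screening: pd.DataFrame
    handrail_counts: pd.DataFrame
    anova: dict                          # (metric, side) -> AnovaTable
    posthoc: pd.DataFrame
    welch: pd.DataFrame
    manifest: dict
    stats_errors: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-trial analysis
# ---------------------------------------------------------------------------

def analyze_trial(trial: TrialRecording, static: StaticTrial,
                  config: PipelineConfig | None = None,
                  trial_name: str = "trial", block_index: int = 0) -> TrialAnalysis:
    """Run preprocessing, detection, metrics, and screening on one block."""
    config = config or PipelineConfig()
    bw = body_weight_from_static(static)
    prepped = preprocess_trial(trial, config.marker_cutoff, config.force_cutoff,
                               config.filter_order, config.max_gap_frames)
    events = detect_events(prepped)
    perts = detect_perturbations(prepped.belt_speed, prepped.force_rate, events,
                                 prepped.meta, config.belt_depart_threshold,
                                 block_index=block_index)
    warmups = exclude_warmup(perts, config.warmup_per_side)
    rows, screens, segments, errors = [], [], {}, []
    for i, pert in enumerate(perts):
        try:
            segs = segment_recovery_steps(pert, events, prepped.meta)
        except Exception as exc:  # truncated recovery near the trial end
            errors.append((trial_name, i, str(exc)))
            continue
        segments[i] = segs
        screens.append(screen_perturbation(
            pert, prepped, events, segs, i, warmup_flag=warmups[i],
            onset_max_fraction=config.onset_max_fraction,
            grab_speed=config.grab_speed,
            grab_min_duration=config.grab_min_duration,
            max_missing_fraction=config.max_missing_fraction,
            completeness_pooled=config.completeness_pooled,
            swing_force_threshold=config.swing_force_threshold,
            min_swing_fraction=config.min_swing_fraction))
        for rec in compute_step_metrics(prepped, segs, i, bw.value,
                                        trunk_mode=config.trunk_angle_mode):
            rows.append({
                "trial": trial_name, "perturbation_index": i,
                "unit": f"{trial_name}/{i}", "side": pert.side,
                "group": trial.meta.snp_condition, "step": rec.label,
                "stance_side": rec.stance_side, "trunk_sway": rec.trunk_sway,
                "peak_flexion_velocity": rec.peak_flexion_velocity,
                "peak_grf": rec.peak_grf, "kinematic_valid": rec.kinematic_valid,
                "kinetic_valid": rec.kinetic_valid})
    metrics = pd.DataFrame(rows)
    if not metrics.empty:
        flags = {s.perturbation_index: (s.kinematic_included, s.kinetic_included)
                 for s in screens}
        metrics["kinematic_included"] = [
            flags[i][0] and ok for i, ok in
            zip(metrics["perturbation_index"], metrics["kinematic_valid"])]
        metrics["kinetic_included"] = [
            flags[i][1] and ok for i, ok in
            zip(metrics["perturbation_index"], metrics["kinetic_valid"])]
    return TrialAnalysis(trial_name=trial_name, events=events,
                         perturbations=perts, segments=segments, metrics=metrics,
                         screening=ScreeningReport(rows=screens),
                         body_weight=bw.value, errors=errors)


# ---------------------------------------------------------------------------
# statistics over pooled trials
# ---------------------------------------------------------------------------

def run_statistics(metrics: pd.DataFrame, config: PipelineConfig | None = None):
    """Mixed ANOVA, post-hoc, and Welch contrast per (metric, perturbed side).

    Kinematic metrics use kinematically included perturbations; the GRF
    metric uses kinetically included ones.  Returns (anova dict, posthoc
    frame, welch frame, error log).
    """
    config = config or PipelineConfig()
    anova, post_rows, welch_rows, errors = {}, [], [], []
    for metric in METRIC_COLUMNS:
        incl_col = ("kinematic_included" if metric in KINEMATIC_METRICS
                    else "kinetic_included")
        usable = metrics[metrics[incl_col]]
        for side in ("intact", "prosthetic"):
            sub = usable[usable["side"] == side]
            if sub.empty:
                errors.append((metric, side, "no included perturbations"))
                continue
            table = sub.rename(columns={metric: "value"})[
                ["unit", "group", "step", "value"]]
            try:
                aov = mixed_anova(table, alpha_sphericity=config.alpha)
            except Exception as exc:
                errors.append((metric, side, str(exc)))
                continue
            anova[(metric, side)] = aov
            ph = bonferroni_posthoc(table, family_size=config.posthoc_family)
            sig = (aov.effects["interaction"].p < config.alpha
                   or aov.effects["group"].p < config.alpha)
            ph.insert(0, "metric", metric)
            ph.insert(1, "side", side)
            ph["exploratory"] = not sig
            post_rows.append(ph)
        # first-recovery-step asymmetry across sides
        rec1 = usable[usable["step"] == "rec1"].rename(columns={metric: "value"})
        try:
            if config.welch_mode == "difference_of_differences":
                w = welch_asymmetry_test(rec1)
            else:
                w = welch_two_group_asymmetry(rec1)
            welch_rows.append({"metric": metric, "estimate": w.estimate,
                               "se": w.se, "T": w.T, "df": w.df, "p": w.p,
                               "degenerate": w.degenerate})
        except Exception as exc:
            errors.append((metric, "rec1-asymmetry", str(exc)))
    posthoc = (pd.concat(post_rows, ignore_index=True)
               if post_rows else pd.DataFrame())
    welch = pd.DataFrame(welch_rows)
    return anova, posthoc, welch, errors


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_analysis(input_dir, output_dir=None,
                 config: PipelineConfig | None = None) -> AnalysisResult:
    """Analyse every trial bundle under ``input_dir`` and write the result
    tables to ``output_dir`` (if given).

    Re-running with the same config and inputs reproduces byte-identical
    numeric outputs.
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    bundles = sorted(p for p in input_dir.iterdir()
                     if p.is_dir() and (p / "meta.json").exists())
    if not bundles:
        raise ConfigError(f"no trial bundles found under {input_dir}")

    analyses = []
    for block_index, b in enumerate(bundles):
        trial, _, static = load_bundle(b)
        if static is None:
            raise ConfigError(f"bundle {b.name} lacks a static trial")
        analyses.append(analyze_trial(trial, static, config,
                                      trial_name=b.name, block_index=block_index))

    metrics = pd.concat([a.metrics for a in analyses if not a.metrics.empty],
                        ignore_index=True)
    screening = pd.concat(
        [a.screening.to_frame().assign(trial=a.trial_name) for a in analyses],
        ignore_index=True)
    handrail = sum((a.screening.handrail_counts() for a in analyses[1:]),
                   analyses[0].screening.handrail_counts())
    anova, posthoc, welch, errors = run_statistics(metrics, config)
    for a in analyses:
        errors.extend(a.errors)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "n_trials": len(analyses),
        "versions": _versions(),
    }
    result = AnalysisResult(metrics=metrics, screening=screening,
                            handrail_counts=handrail, anova=anova,
                            posthoc=posthoc, welch=welch, manifest=manifest,
                            stats_errors=errors)
    if output_dir is not None:
        _write_outputs(result, Path(output_dir))
    return result


def _versions() -> dict:
    import scipy

    return {"stumblekit": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


def _write_outputs(result: AnalysisResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"
    result.metrics.to_csv(out / "step_metrics.csv", index=False, float_format=ff)
    result.screening.to_csv(out / "screening.csv", index=False)
    result.handrail_counts.to_csv(out / "handrail_counts.csv")
    result.posthoc.to_csv(out / "posthoc.csv", index=False, float_format=ff)
    result.welch.to_csv(out / "welch.csv", index=False, float_format=ff)
    anova_json = {}
    for (metric, side), aov in result.anova.items():
        anova_json[f"{metric}/{side}"] = {
            "effects": {k: dataclasses.asdict(e) for k, e in aov.effects.items()},
            "mauchly_w": aov.mauchly_w, "mauchly_p": aov.mauchly_p,
            "epsilon_gg": aov.epsilon_gg, "corrected": aov.corrected,
            "n_per_group": aov.n_per_group, "dropped_units": aov.dropped_units}
    (out / "anova_results.json").write_text(json.dumps(anova_json, indent=1))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    if result.stats_errors:
        (out / "errors.log").write_text(
            "\n".join(str(e) for e in result.stats_errors))
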