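# Methods

This note documents the models, numerical choices, and limitations behind
`stumblekit`. It covers the synthetic trial generator, each analysis stage,
and the inference layer.

## Protocol constants

All thresholds default to the experimental protocol's values and live in
`PipelineConfig` / `SimulationConfig` (nothing is hard-coded elsewhere; a
pipeline test perturbs them and checks the outputs move):

| constant | value | role |
|---|---|---|
| marker / force low-pass cutoff | 6 / 10 Hz | 4th-order zero-phase Butterworth |
| median filter | 3 samples | impulse-noise removal |
| belt acceleration | 3 m/s² | triangular perturbation profile |
| perturbation duration | 0.8 or 0.6 s | accelerate half, decelerate half |
| trigger force | 100 N | vertical GRF crossing in early stance |
| perturbation spacing | ≥ 10 strides | return to steady state |
| perturbations per side | 12 per block | study condition |
| onset phase bound | ≤ 20 % of gait cycle | inclusion rule (inclusive) |
| warm-up exclusion | first 2 per side per block | learning effect |
| handrail grab | < 5 cm/s for ≥ 50 ms | finger-marker speed |
| marker completeness | > 5 % missing fails | per required marker |
| belt separation | < 20 N for ≥ 15 % of cycle | per plate, per cycle |
| sampling | 100 Hz markers, 1000 Hz forces | common time origin |

Boundary comparators are read literally: ≤ 0.20 passes, ≥ 50 ms is a grab,
≥ 15 % passes, > 5 % fails.

## Synthetic trial generator

The generator reproduces the statistical and geometric structure the
pipeline consumes, not musculoskeletal mechanics.

**Kinematic templates.** Marker trajectories are sums of low-order
harmonics of the stride period. The heel marker's anterior–posterior (AP)
position relative to the pelvis centroid is
`A(cos φ + 0.15 cos 2φ)` with φ = 0 at each heel strike, so its per-cycle
maximum falls exactly on the ground-truth event; the toe marker's relative
AP minimum likewise falls on each toe-off. The frame is right-handed,
+X walking direction, +Z up, positions in metres. The marker set is the
minimal one the pipeline uses: per-side HEEL, TOE, FINGER; SACR/LASI/RASI
(pelvis origin = centroid); C7/CLAV (trunk axis = pelvis origin → C7/CLAV
midpoint, length 0.45 m).

**Stance GRF.** Each stance (62 % of the stride) carries a double-hump
vertical GRF built from two raised-cosine humps peaking at 25 % and 75 % of
stance (defaults 110 and 105 %BW), zero in swing. Horizontal components are
zero, so ‖GRF‖ equals the vertical channel; sensor noise (default 2 N) is
added on all three axes.

**Perturbations.** Sides are drawn as a seeded permutation honouring the
per-side counts; onsets are the first force sample of the chosen stance
whose vertical GRF exceeds 100 N, which lands near 4 % of the gait cycle.
The belt profile is an exact triangle: speed `v0 + a·t` for half the
duration, mirrored down, peak increment `a·T/2`.

**Stumble responses.** Each of the four steps of each perturbation receives
a trunk-flexion excursion (cosine rise, cosine fall, flat otherwise) and a
rescaled stance GRF hump so that the step's sway, peak flexion velocity,
and first-peak ‖GRF‖ equal *baseline + condition offset + noise*. Two
numerical points matter:

1. *Measurement-chain calibration.* A 6 Hz zero-phase filter slightly
   reshapes any transient, so injecting a literal cosine of amplitude A
   would be recovered ≈ 1–2 % off. The generator therefore calibrates each
   excursion by fixed-point iteration against the marker filtering chain
   (Butterworth + median): amplitude and rise time are adjusted until the
   *filtered* trace's range and peak rate equal the targets. Excursions
   keep 0.14 s / 0.16 s clearances from step boundaries so their filter
   ringing stays inside their own step, and the steady trunk oscillation is
   smoothly gated off around each response window. Result: noiseless
   end-to-end recovery is better than 1 % relative for all three metrics
   (typically ≤ 0.8 % for sway, ≤ 0.6 % for velocity, ≤ 0.01 % for GRF).
2. *Correlated kinematic noise.* Sway and peak flexion velocity share a
   per-step response-intensity factor γ (larger stumbles flex faster), with
   independent jitter topping up the velocity's marginal spread; draws are
   clamped at ±2.5 sd (symmetric, so means are unbiased). This mirrors real
   stumbles and keeps every drawn (sway, velocity) pair realizable at the
   6 Hz marker bandwidth — an independent pair like (4°, 80°/s) would demand
   a transient the filter cannot transmit. GRF noise is independent
   Gaussian, clamped at ±3 sd.

Baseline response magnitudes (sway 6/9/7/6°, peak flexion velocity
50/70/60/50°/s, first-peak GRF 115/120/115/112 %BW for pert/rec1/rec2/rec3)
and noise sds (2°, 10°/s, 8 %BW) are fixed once as plausible magnitudes for
treadmill stumble recovery: the largest response on the first recovery
step, decaying by the third, with trial-to-trial spreads consistent with
standard errors near 0.3° at group sizes around 60. Cadence defaults to
90 steps/min at 1.1 m/s.

**Corruption.** With configured probabilities per perturbation: both finger
markers freeze for 0.35 s shortly after onset (handrail grab); a contiguous
6 % of the response window of one trunk marker is invalidated (dropout); or
the first-recovery stance plate is held at ≥ 40 N for one full stride
(mid-line crossing). All insertions are logged in the ground truth.

**Determinism.** One integer seed; each stage (steady gait, scheduling,
injection, corruption, static trial) uses an independent derived stream, so
identical configs give bit-identical recordings.

## Preprocessing

Marker gaps ≤ 10 frames (0.1 s) are filled by a cubic spline through valid
samples and flagged; longer or boundary gaps stay invalid (NaN), and the
pre-interpolation mask is preserved for the completeness rule.
Interpolation precedes filtering so short gaps do not fragment the filter
state; NaN runs that remain are filtered segment-wise so gaps stay local.
Filters are zero-phase (forward–backward `sosfiltfilt`) because phase lag
would shift event timing; "4th order" is the design order, so the
bidirectional gain at the cutoff is 1/2. The 3-sample median runs after the
Butterworth on both marker and force channels. Body weight is the
time-averaged magnitude of the summed plate force vectors of a static
T-pose trial; forces are reported as 100·‖F‖/BW (%BW).

## Events and segmentation

Heel strikes are per-cycle maxima of heel AP position relative to the
pelvis centroid, toe-offs per-cycle minima of the toe marker's, found with
a peak picker whose minimum spacing is 0.7 stride (stride period estimated
from the dominant 0.2–2 Hz spectral peak; a trace without such a peak, or
with under two cycles, yields no events and a warning). Alternation within
a side is enforced by dropping the weaker of two same-type events.
Perturbations are read from the belt-speed channel: excursions > 0.05 m/s
above the steady (median) speed, expanded to the sample where speed leaves
and rejoins baseline; a non-returning excursion is a malformed trial. The
perturbed side is the limb in stance at onset — the most recent heel strike
with no subsequent toe-off, ties (double support) resolved to the later
striker. The perturbation step starts at the perturbed limb's preceding
heel strike; steps are bounded by successive heel strikes of opposite feet,
so the four windows tile time and stance sides alternate
(pert/rec2 perturbed, rec1/rec3 contralateral).

## Metrics

The trunk angle is the 3-D angle between the trunk axis and +Z, signed by
the sagittal tilt (a pure sagittal-projection variant is exposed via
`trunk_angle_mode="sagittal"`; the two agree for in-plane motion). Angular
velocity is the central-difference derivative at the marker rate with no
extra smoothing. Sway is the in-window range; peak flexion velocity the
in-window maximum of the positive direction, flagged if the velocity never
turns positive. First-peak ‖GRF‖ gates on loading onset (magnitude rising
through the 20 N equivalent) and takes the first local maximum with
prominence ≥ 2 %BW — the prominence floor and onset gate make "first peak"
robust to noise ripples; a window with no interior maximum returns its
maximum flagged, and an unloaded stance plate is an error.

## Screening

The five rules combine into two inclusion families, tracked separately
because trunk and GRF analyses lose different trials: kinematic inclusion
requires completeness, kinetic inclusion requires belt separation, and both
require non-warm-up, early onset, and no grab. Completeness is applied per
required marker (stricter than pooling; pooling is available by config).
The grab/analysis window runs from perturbation onset to the end of rec3.
Handrail grabs are tallied by perturbed side × stimulation condition.

## Statistics

The split-plot decomposition uses subject means for the between part
(condition df 1, error df n − 2) and within-subject deviations for the
within part: cell means of deviations, weighted marginal step means, so
SS(step) + SS(step×condition) + SS(error) is an exact orthogonal split with
error df 3(n − 2). It matches `pingouin.mixed_anova` to machine precision
for balanced and unbalanced groups (a test asserts 1e-8 relative on random
tables). Mauchly's W is computed on pooled orthonormal-contrast covariance
with n − G error df; if its p < 0.05 the step and interaction p-values are
recomputed with Greenhouse–Geisser ε-deflated dfs (ε ∈ [1/3, 1]); the
reported df pairs stay structural. Units missing any step value are
dropped and counted. Post-hoc step-wise contrasts are Welch two-sample
tests with p × 4 (one comparison per step label), capped at 1, reported as
active − inactive and marked exploratory when neither the interaction nor
the condition main effect reaches 0.05. The first-recovery-step asymmetry
test is the four-group contrast
(Ī_off − P̄_off) − (Ī_on − P̄_on) with SE from the four group variances and
Welch–Satterthwaite df (a two-group variant is exposed by config, since
the exact construction behind reported dfs near n − 7 cannot be pinned
down). Normality is assessed by exported Q-Q diagnostics only; it never
gates inference. Simulation checks: the corrected interaction test's type-I
error at n = 60/60 sits in 0.05 ± 0.02 over 1000 null replicates, and a
rec1-only offset of 4 within-group sds is detected in ≥ 95 % of replicates.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep sampling error
well below the margins they check: 100 noiseless perturbations (5 blocks of
10 per side) for metric recovery, 200 noisy 20 s trials (~12 000 events)
for event detection, 4 corruption-injected blocks for screening exactness,
1000/200 replicates for null/power calibration, and 20 blocks per condition
(~200 analysis units per group, SE ≈ 0.2°) for recovering an injected
−1.3° rec1 sway effect.

## What passing tests do and do not show

The generator shares the pipeline's structural assumptions: events exactly
at relative-AP extrema, GRFs exactly zero in swing, responses confined to
their steps, stationary cadence. Passing tests therefore validate the
pipeline's logic, numerics, and statistics — not its robustness to
violations real data can show (soft-tissue artefact, cadence drift,
atypical footfall geometry, crosstalk between plates, events during the
perturbed stride itself, marker relabeling errors). The event detector's
accuracy under the generator's Gaussian marker noise (≥ 99 % within 2
frames) should be read as an upper bound on real-data performance.

## Known limitations

* Gap filling is a single-marker cubic spline; no rigid-body or donor-marker
  reconstruction.
* The perturbed-limb kinematic templates do not themselves change during a
  perturbation; only the trunk trace and stance GRFs are reshaped, so event
  detection during perturbed strides is easier than in real recordings.
* The mixed ANOVA treats perturbation trials as independent units (as the
  reported error dfs imply); a participant-level random-effects model is
  out of scope.
* Trial bundles are CSV/JSON only; no C3D interchange.
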