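"""Mixed-design inference on per-step recovery metrics.

The core test is a split-plot (mixed-design) repeated-measures ANOVA with
recovery step (pert, rec1, rec2, rec3) as the within-subject factor, the
stimulation condition (active vs inactive) as the between-group factor, and
one perturbation trial as the analysis unit.  Sphericity of the
within-subject covariance is assessed with Mauchly's test; when violated,
the step and interaction p-values are recomputed with Greenhouse-Geisser
deflated degrees of freedom.  Step-wise condition differences are explored
with Bonferroni-corrected pairwise comparisons, and the first recovery
step's side asymmetry with a Welch-type difference-of-differences contrast.

Degrees-of-freedom structure (G groups of sizes n_g, J = 4 steps,
n = sum n_g):

====================  =======================
effect                df pair
====================  =======================
condition (between)   (G - 1, n - G)
step (within)         (J - 1, (J - 1)(n - G))
step x condition      ((J - 1)(G - 1), (J - 1)(n - G))
====================  =======================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .core import InferenceError, STEP_LABELS


@dataclass
class EffectResult:
    ss: float
    df1: float
    df2: float
    F: float
    p: float


@dataclass
class AnovaTable:
    effects: dict                     # "group" | "step" | "interaction" -> EffectResult
    mauchly_w: float
    mauchly_p: float
    epsilon_gg: float
    corrected: bool
    n_per_group: dict
    dropped_units: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"effect": k, "SS": e.ss, "df1": e.df1, "df2": e.df2,
                 "F": e.F, "p": e.p} for k, e in self.effects.items()]
        return pd.DataFrame(rows)


@dataclass
class WelchResult:
    estimate: float
    se: float
    T: float
    df: float
    p: float
    degenerate: bool = False
    group_means: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(j: int) -> np.ndarray:
    """Orthonormal basis of the (j-1)-dimensional contrast space."""
    h = np.zeros((j, j - 1))
    for k in range(1, j):
        h[:k, k - 1] = 1.0
        h[k, k - 1] = -k
    return h / np.linalg.norm(h, axis=0)


def mauchly_test(z_by_group: list):
    """Mauchly's sphericity test on orthonormalized within-subject scores.

    ``z_by_group`` holds one (n_g, J-1) contrast-score array per group; the
    covariance is pooled across groups with n - G error df.
    """
    p = z_by_group[0].shape[1]
    n_e = sum(z.shape[0] for z in z_by_group) - len(z_by_group)
    S = np.zeros((p, p))
    for z in z_by_group:
        c = z - z.mean(axis=0)
        S += c.T @ c
    S /= n_e
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 1e-300, None)
    w = float(np.prod(eig) / (eig.mean() ** p))
    chi2 = -(n_e - (2 * p ** 2 + p + 2) / (6.0 * p)) * np.log(w)
    df = p * (p + 1) // 2 - 1
    p_val = float(sst.chi2.sf(chi2, df))
    return w, p_val, S


def gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a contrast-space covariance matrix,
    bounded in [1/(J-1), 1]."""
    eig = np.linalg.eigvalsh(S)
    p = S.shape[0]
    eps = float(eig.sum() ** 2 / (p * (eig ** 2).sum()))
    return float(np.clip(eps, 1.0 / p, 1.0))


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------

def _wide_by_group(table: pd.DataFrame, dv: str, within: str, subject: str,
                   between: str, levels):
    """Complete-case wide arrays per between-group level, order preserved."""
    wide = table.pivot_table(index=[between, subject], columns=within,
                             values=dv, aggfunc="mean")
    dropped = int(wide.isna().any(axis=1).sum())
    wide = wide.dropna()
    missing = [l for l in levels if l not in wide.columns]
    if missing:
        raise InferenceError(f"no data for within level(s) {missing}")
    wide = wide[list(levels)]
    groups = []
    labels = []
    for g, sub in wide.groupby(level=0, sort=True):
        groups.append(sub.to_numpy(dtype=float))
        labels.append(g)
    return labels, groups, dropped


def mixed_anova(table: pd.DataFrame, dv: str = "value", within: str = "step",
                subject: str = "unit", between: str = "group",
                within_levels=STEP_LABELS, alpha_sphericity: float = 0.05
                ) -> AnovaTable:
    """Split-plot ANOVA with Mauchly-gated Greenhouse-Geisser correction.

    Analysis units missing any within level are dropped (counted in
    ``dropped_units``); a group with fewer than 2 complete units raises
    :class:`InferenceError`.
    """
    labels, groups, dropped = _wide_by_group(table, dv, within, subject,
                                             between, within_levels)
    if len(groups) < 2:
        raise InferenceError("need at least 2 between-group levels")
    if any(g.shape[0] < 2 for g in groups):
        raise InferenceError("each group needs at least 2 complete units")

    J = groups[0].shape[1]
    ns = [g.shape[0] for g in groups]
    n, G = sum(ns), len(groups)
    allv = np.vstack(groups)
    grand = allv.mean()

    subj_means = [g.mean(axis=1) for g in groups]
    g_means = [m.mean() for m in subj_means]
    ss_group = J * sum(ng * (mg - grand) ** 2 for ng, mg in zip(ns, g_means))
    ss_subj = J * sum(((m - mg) ** 2).sum() for m, mg in zip(subj_means, g_means))

    dev = [g - m[:, None] for g, m in zip(groups, subj_means)]
    cell = np.array([d.mean(axis=0) for d in dev])            # (G, J)
    marg = np.average(cell, axis=0, weights=ns)
    ss_step = n * float(np.sum(marg ** 2))
    ss_cells = sum(ng * float(np.sum(cell[g] ** 2)) for g, ng in enumerate(ns))
    ss_inter = ss_cells - ss_step
    ss_err_w = sum(float((d ** 2).sum()) for d in dev) - ss_cells

    df_g, df_s = G - 1, n - G
    df_w, df_we = J - 1, (J - 1) * (n - G)
    F_g = (ss_group / df_g) / (ss_subj / df_s)
    F_w = (ss_step / df_w) / (ss_err_w / df_we)
    F_i = (ss_inter / (df_w * df_g)) / (ss_err_w / df_we)

    contrasts = _orthonormal_contrasts(J)
    z = [g @ contrasts for g in groups]
    w, mauchly_p, S = mauchly_test(z)
    eps = gg_epsilon(S)
    corrected = mauchly_p < alpha_sphericity
    e = eps if corrected else 1.0

    # structural df pairs are reported; the GG deflation enters the p-values
    effects = {
        "group": EffectResult(ss_group, df_g, df_s, F_g,
                              float(sst.f.sf(F_g, df_g, df_s))),
        "step": EffectResult(ss_step, df_w, df_we, F_w,
                             float(sst.f.sf(F_w, df_w * e, df_we * e))),
        "interaction": EffectResult(ss_inter, df_w * df_g, df_we, F_i,
                                    float(sst.f.sf(F_i, df_w * df_g * e, df_we * e))),
    }
    return AnovaTable(effects=effects, mauchly_w=w, mauchly_p=mauchly_p,
                      epsilon_gg=eps, corrected=corrected,
                      n_per_group=dict(zip(labels, ns)), dropped_units=dropped)


# ---------------------------------------------------------------------------
# post-hoc and contrasts
# ---------------------------------------------------------------------------

def _welch_two_sample(a: np.ndarray, b: np.ndarray):
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        return diff, 0.0, np.nan, np.nan, np.nan
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * float(sst.t.sf(abs(t), df))
    return diff, float(np.sqrt(se2)), float(t), float(df), p


def bonferroni_posthoc(table: pd.DataFrame, dv: str = "value",
                       within: str = "step", between: str = "group",
                       active_level: str = "active",
                       inactive_level: str = "inactive",
                       within_levels=STEP_LABELS,
                       family_size: int | None = None) -> pd.DataFrame:
    """Step-wise active-vs-inactive comparisons with Bonferroni adjustment.

    The mean difference is active minus inactive, so negative values are
    reductions under stimulation.  The family size defaults to the number of
    step labels compared.
    """
    if family_size is None:
        family_size = len(within_levels)
    rows = []
    for label in within_levels:
        sub = table[table[within] == label]
        a = sub.loc[sub[between] == active_level, dv].to_numpy(dtype=float)
        b = sub.loc[sub[between] == inactive_level, dv].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise InferenceError(f"step {label!r} has a group with < 2 values")
        diff, se, t, df, p = _welch_two_sample(a, b)
        rows.append({"step": label, "mean_diff": diff, "se": se, "T": t,
                     "df": df, "p_raw": p,
                     "p_adj": min(1.0, p * family_size) if np.isfinite(p) else np.nan,
                     "n_active": a.size, "n_inactive": b.size})
    return pd.DataFrame(rows)


def welch_asymmetry_test(rec1_table: pd.DataFrame, dv: str = "value",
                         side_col: str = "side", between: str = "group",
                         active_level: str = "active",
                         inactive_level: str = "inactive") -> WelchResult:
    """Difference-of-differences Welch contrast on first-recovery-step values.

    contrast = (intact - prosthetic | inactive) - (intact - prosthetic | active),
    i.e. the change in side asymmetry attributable to the stimulation, with
    the standard error pooled from the four group variances and
    Welch-Satterthwaite degrees of freedom.
    """
    cells = {}
    for side in ("intact", "prosthetic"):
        for cond in (inactive_level, active_level):
            v = rec1_table.loc[(rec1_table[side_col] == side)
                               & (rec1_table[between] == cond), dv]
            v = v.to_numpy(dtype=float)
            if v.size == 0:
                raise InferenceError(f"empty group ({side}, {cond})")
            cells[(side, cond)] = v
    coeff = {("intact", inactive_level): 1.0, ("prosthetic", inactive_level): -1.0,
             ("intact", active_level): -1.0, ("prosthetic", active_level): 1.0}
    est = sum(c * cells[k].mean() for k, c in coeff.items())
    terms = []
    for k in coeff:
        v = cells[k]
        if v.size < 2:
            raise InferenceError(f"group {k} needs at least 2 values")
        terms.append((v.var(ddof=1) / v.size, v.size))
    se2 = sum(t for t, _ in terms)
    means = {f"{s}_{c}": float(cells[(s, c)].mean()) for s, c in cells}
    if se2 == 0:
        return WelchResult(estimate=float(est), se=0.0, T=float("nan"),
                           df=float("nan"), p=float("nan"), degenerate=True,
                           group_means=means)
    df = se2 ** 2 / sum(t ** 2 / (nn - 1) for t, nn in terms)
    t_stat = est / np.sqrt(se2)
    p = 2 * float(sst.t.sf(abs(t_stat), df))
    return WelchResult(estimate=float(est), se=float(np.sqrt(se2)),
                       T=float(t_stat), df=float(df), p=p, group_means=means)


def welch_two_group_asymmetry(rec1_table: pd.DataFrame, dv: str = "value",
                              side_col: str = "side", between: str = "group") -> WelchResult:
    """Two-group variant: Welch's t-test comparing per-condition asymmetry
    scores built as (intact - prosthetic) group-mean differences is not
    identifiable per unit, so this variant compares intact vs prosthetic
    values pooled within the active condition against the inactive one."""
    a = rec1_table.loc[rec1_table[between] == "active", dv].to_numpy(dtype=float)
    b = rec1_table.loc[rec1_table[between] == "inactive", dv].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise InferenceError("each condition needs at least 2 values")
    diff, se, t, df, p = _welch_two_sample(a, b)
    return WelchResult(estimate=diff, se=se, T=t, df=df, p=p)


def handrail_count_table(report) -> pd.DataFrame:
    """2x2 handrail-grab tally by perturbed side and stimulation condition."""
    return report.handrail_counts()


def qq_points(values: np.ndarray):
    """Normal quantile-quantile coordinates for a residual diagnostic plot."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    theo = sst.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, v
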