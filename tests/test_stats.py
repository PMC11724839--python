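"""Split-plot ANOVA, sphericity handling, post-hoc, and Welch contrast."""

import numpy as np
import pandas as pd
import pytest

from stumblekit.core import InferenceError
from stumblekit.screening import PerturbationScreen, ScreeningReport
from stumblekit.stats import (
    bonferroni_posthoc,
    gg_epsilon,
    handrail_count_table,
    mixed_anova,
    welch_asymmetry_test,
)

LABELS = ("pert", "rec1", "rec2", "rec3")


def make_table(rng, n1=20, n2=20, offset_rec1=0.0, sd=1.0, cov=None):
    rows = []
    for n, grp in ((n1, "inactive"), (n2, "active")):
        if cov is None:
            y = rng.normal(0.0, sd, (n, 4))
        else:
            y = rng.multivariate_normal(np.zeros(4), cov, size=n)
        if grp == "active":
            y[:, 1] += offset_rec1
        for i in range(n):
            for j, l in enumerate(LABELS):
                rows.append(dict(unit=f"{grp}{i}", group=grp, step=l, value=y[i, j]))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_df_structure(self, rng):
        aov = mixed_anova(make_table(rng, 58, 59))
        inter = aov.effects["interaction"]
        assert (inter.df1, inter.df2) == (3, 3 * (58 + 59 - 2))
        assert aov.effects["group"].df1 == 1
        assert aov.effects["group"].df2 == 58 + 59 - 2
        assert aov.effects["step"].df1 == 3

    def test_agrees_with_reference_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        for k in range(10):
            n1, n2 = rng.integers(4, 15, 2)
            df = make_table(rng, int(n1), int(n2), offset_rec1=rng.normal())
            aov = mixed_anova(df)
            ref = pg.mixed_anova(data=df, dv="value", within="step",
                                 subject="unit", between="group")
            ref = ref.set_index("Source")["F"]
            assert aov.effects["group"].F == pytest.approx(ref["group"], rel=1e-10)
            assert aov.effects["step"].F == pytest.approx(ref["step"], rel=1e-10)
            assert aov.effects["interaction"].F == pytest.approx(
                ref["Interaction"], rel=1e-10)

    def test_compound_symmetry_rarely_flags_sphericity(self, rng):
        cov = 0.5 * np.eye(4) + 0.5
        flagged = sum(mixed_anova(make_table(rng, 25, 25, cov=cov)).mauchly_p < 0.05
                      for _ in range(50))
        assert flagged <= 5  # ~alpha of 50

    def test_epsilon_bounds(self, rng):
        for _ in range(10):
            aov = mixed_anova(make_table(rng, 10, 10))
            assert 1.0 / 3.0 <= aov.epsilon_gg <= 1.0
        assert gg_epsilon(np.eye(3)) == pytest.approx(1.0)

    def test_incomplete_units_dropped(self, rng):
        df = make_table(rng, 6, 6)
        df = df[~((df["unit"] == "active0") & (df["step"] == "rec2"))]
        aov = mixed_anova(df)
        assert aov.dropped_units == 1
        assert aov.n_per_group["active"] == 5

    def test_tiny_group_rejected(self, rng):
        df = make_table(rng, 12, 1)
        with pytest.raises(InferenceError):
            mixed_anova(df)


class TestPosthoc:
    def test_identical_groups_fully_adjusted(self, rng):
        base = rng.normal(0, 1, (12, 4))
        rows = []
        for grp in ("inactive", "active"):
            for i in range(12):
                for j, l in enumerate(LABELS):
                    rows.append(dict(unit=f"{grp}{i}", group=grp, step=l,
                                     value=base[i, j]))
        ph = bonferroni_posthoc(pd.DataFrame(rows))
        assert np.allclose(ph["mean_diff"], 0.0)
        assert np.allclose(ph["p_adj"], 1.0)

    def test_adjustment_is_times_family_capped(self, rng):
        ph = bonferroni_posthoc(make_table(rng, 15, 15, offset_rec1=0.8))
        for _, row in ph.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 4))

    def test_injected_offset_recovered(self, rng):
        ph = bonferroni_posthoc(make_table(rng, 58, 59, offset_rec1=-1.3, sd=0.3))
        rec1 = ph.set_index("step").loc["rec1"]
        assert rec1["mean_diff"] == pytest.approx(-1.3, abs=3 * rec1["se"])
        assert rec1["p_adj"] < 0.001


def rec1_frame(rng, means, n=30, sd=1.0):
    rows = []
    for (side, grp), mu in means.items():
        for v in rng.normal(mu, sd, n):
            rows.append(dict(side=side, group=grp, value=v))
    return pd.DataFrame(rows)


class TestWelchContrast:
    def test_degenerate_constant_groups_flagged(self):
        rows = [dict(side=s, group=g, value=1.0)
                for s in ("intact", "prosthetic")
                for g in ("active", "inactive") for _ in range(5)]
        res = welch_asymmetry_test(pd.DataFrame(rows))
        assert res.degenerate and res.se == 0.0

    def test_symmetric_effects_null(self, rng):
        ests = []
        for _ in range(200):
            means = {("intact", "inactive"): 2.0, ("prosthetic", "inactive"): 2.0,
                     ("intact", "active"): 1.0, ("prosthetic", "active"): 1.0}
            ests.append(welch_asymmetry_test(rec1_frame(rng, means)).estimate)
        assert abs(np.mean(ests)) < 0.05

    def test_asymmetric_effect_recovered(self, rng):
        ests = []
        for _ in range(200):
            means = {("intact", "inactive"): 1.0, ("prosthetic", "inactive"): 0.0,
                     ("intact", "active"): 0.0, ("prosthetic", "active"): 0.0}
            ests.append(welch_asymmetry_test(rec1_frame(rng, means, n=60)).estimate)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.1)

    def test_satterthwaite_df_below_total(self, rng):
        means = {("intact", "inactive"): 1.0, ("prosthetic", "inactive"): 0.0,
                 ("intact", "active"): 0.5, ("prosthetic", "active"): 0.2}
        res = welch_asymmetry_test(rec1_frame(rng, means, n=40))
        assert res.df <= 4 * 40 - 4 + 1e-9
        assert 0.0 <= res.p <= 1.0

    def test_empty_group_rejected(self, rng):
        means = {("intact", "inactive"): 1.0, ("prosthetic", "inactive"): 0.0,
                 ("intact", "active"): 0.5}
        with pytest.raises(InferenceError):
            welch_asymmetry_test(rec1_frame(rng, means))


class TestHandrailCounts:
    def _report(self, cells):
        rows = []
        idx = 0
        for (side, cond), count in cells.items():
            for _ in range(count):
                rows.append(PerturbationScreen(
                    perturbation_index=idx, side=side, snp_condition=cond,
                    warmup_excluded=False, onset_phase_ok=True,
                    handrail_grab=True, kinematic_complete=True,
                    kinetic_separated=True))
                idx += 1
        return ScreeningReport(rows=rows)

    def test_no_grabs_all_zero(self):
        table = handrail_count_table(ScreeningReport(rows=[]))
        assert (table.to_numpy() == 0).all()

    def test_single_cell_tally(self):
        table = handrail_count_table(self._report({("prosthetic", "inactive"): 10}))
        assert table.loc["prosthetic", "inactive"] == 10
        assert table.to_numpy().sum() == 10

    def test_known_counts_per_cell(self):
        cells = {("intact", "inactive"): 1, ("prosthetic", "inactive"): 10,
                 ("intact", "active"): 2, ("prosthetic", "active"): 3}
        table = handrail_count_table(self._report(cells))
        for (side, cond), count in cells.items():
            assert table.loc[side, cond] == count
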