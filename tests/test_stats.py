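"""RM-ANOVA, contrasts, Bayes factors, within-subject SEM, trend."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oculorate.core import CONDITIONS
from oculorate.stats import (
    analyze_sr_table,
    bf01_ttest,
    fdr_bh,
    foreperiod_trend,
    planned_contrasts,
    rm_anova_oneway,
    rm_anova_twoway,
    within_subject_sem,
)

from _oracles import bf01_g_integral, brute_rm_anova_oneway, brute_rm_anova_twoway


def tidy_table(cube, conditions=CONDITIONS, foreperiods=(1000, 2000)):
    rows = []
    for i in range(cube.shape[0]):
        for a, c in enumerate(conditions):
            for b, fp in enumerate(foreperiods):
                rows.append(
                    {"subject_id": f"S{i:02d}", "condition": c,
                     "foreperiod_ms": fp, "mean_sr": cube[i, a, b]}
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    @pytest.mark.parametrize("seed", range(5))
    def test_oneway_matches_bruteforce_and_pingouin(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 6, 4
        Y = rng.normal(1, 0.5, (n, k)) + rng.normal(0, 0.7, (n, 1))
        res = rm_anova_oneway(Y)
        F, df1, df2, p = brute_rm_anova_oneway(Y)
        assert res.F == pytest.approx(F, abs=1e-8)
        assert (res.df1, res.df2) == (df1, df2)
        assert res.p_uncorrected == pytest.approx(p, abs=1e-8)
        df = pd.DataFrame(
            {"y": Y.ravel(), "s": np.repeat(range(n), k), "l": np.tile(range(k), n)}
        )
        aov = pg.rm_anova(data=df, dv="y", within="l", subject="s").iloc[0]
        assert res.F == pytest.approx(float(aov["F"]), abs=1e-8)
        assert res.epsilon_gg == pytest.approx(float(aov["eps"]), abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_twoway_matches_bruteforce_and_pingouin(self, seed):
        rng = np.random.default_rng(100 + seed)
        cube = rng.normal(1.0, 0.4, (6, 4, 2)) + rng.normal(0, 0.5, (6, 1, 1))
        table = tidy_table(cube)
        mine = {r.effect: r for r in rm_anova_twoway(table)}
        oracle = brute_rm_anova_twoway(cube)
        for eff, (F, df1, df2, p) in oracle.items():
            assert mine[eff].F == pytest.approx(F, abs=1e-8)
            assert (mine[eff].df1, mine[eff].df2) == (df1, df2)
            assert mine[eff].p_uncorrected == pytest.approx(p, abs=1e-8)
        aov = pg.rm_anova(
            data=table, dv="mean_sr", within=["condition", "foreperiod_ms"],
            subject="subject_id",
        )
        pg_f = dict(zip(aov["Source"], aov["F"]))
        assert mine["condition"].F == pytest.approx(pg_f["condition"], abs=1e-8)
        assert mine["foreperiod"].F == pytest.approx(pg_f["foreperiod_ms"], abs=1e-8)
        assert mine["condition:foreperiod"].F == pytest.approx(
            pg_f["condition * foreperiod_ms"], abs=1e-8
        )

    def test_sphericity_stats_match_pingouin(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 1, (8, 5)) * rng.uniform(0.5, 2, 5)
        res = rm_anova_oneway(Y)
        df = pd.DataFrame(
            {"y": Y.ravel(), "s": np.repeat(range(8), 5), "l": np.tile(range(5), 8)}
        )
        sph = pg.sphericity(data=df, dv="y", within="l", subject="s")
        assert res.mauchly_w == pytest.approx(float(sph.W), abs=1e-10)
        assert res.mauchly_p == pytest.approx(float(sph.pval), abs=1e-10)
        hf = pg.epsilon(pd.DataFrame(Y), correction="hf")
        assert res.epsilon_hf == pytest.approx(min(1.0, float(hf)), abs=1e-10)

    def test_equal_cells_give_zero_F(self):
        Y = np.tile(np.arange(6)[:, None], (1, 4)).astype(float)  # subject offsets only
        res = rm_anova_oneway(Y)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_level_factor_has_unit_epsilon_no_correction(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (8, 2))
        res = rm_anova_oneway(Y)
        assert res.epsilon_gg == 1.0
        assert res.correction == "none"

    def test_eta_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, (10, 4)) + np.arange(4) * 0.8
        res = rm_anova_oneway(Y)
        lo, hi = res.eta_ci
        assert 0.0 <= lo <= res.partial_eta_sq <= hi <= 1.0

    def test_missing_cell_named_in_error(self):
        rng = np.random.default_rng(4)
        table = tidy_table(rng.normal(1, 0.3, (5, 4, 2)))
        table = table.drop(table.index[3])
        with pytest.raises(ValueError, match="S00"):
            rm_anova_twoway(table)


class TestFdr:
    def test_bh_stepup_example(self):
        np.testing.assert_allclose(
            fdr_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_bh_properties_and_statsmodels_agreement(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestContrasts:
    def _table(self, rng, shift=0.0):
        cube = rng.normal(1.0, 0.3, (10, 4, 2)) + rng.normal(0, 0.4, (10, 1, 1))
        cube[:, 0, :] -= shift  # full_certainty lowered
        return tidy_table(cube)

    def test_paired_t_matches_scipy(self, rng):
        table = self._table(rng, shift=0.4)
        res = {c.label: c for c in planned_contrasts(table)}
        wide = table.pivot_table(
            index="subject_id", columns=["condition", "foreperiod_ms"],
            values="mean_sr",
        )
        t_ref = sps.ttest_rel(
            wide[("full_certainty", 1000)], wide[("low_certainty", 1000)]
        )
        c = res["full_vs_low@1s"]
        assert c.t == pytest.approx(t_ref.statistic, abs=1e-10)
        assert c.p_raw == pytest.approx(t_ref.pvalue, abs=1e-10)
        assert c.df == 9

    def test_constant_shift_closed_form(self):
        rng = np.random.default_rng(0)
        n, c, s = 12, 0.5, 0.2
        noise = rng.normal(0, s, n)
        noise -= noise.mean()
        noise *= s / noise.std(ddof=1)
        cube = np.ones((n, 4, 2))
        cube[:, 0, :] = 1.0 - c + noise[:, None]  # full lower by c with sd s
        res = {r.label: r for r in planned_contrasts(tidy_table(cube))}
        t = res["full_vs_low@1s"].t
        assert t == pytest.approx(-c * math.sqrt(n) / s, rel=1e-9)

    def test_identical_vectors_zero_t(self, rng):
        cube = np.tile(rng.normal(1, 0.3, (10, 1, 1)), (1, 4, 2))
        res = planned_contrasts(tidy_table(cube))
        for c in res:
            assert c.t == 0.0 and np.isnan(c.dz)

    def test_combined_cell_is_within_subject_average(self, rng):
        table = self._table(rng)
        res = {c.label: c for c in planned_contrasts(table)}
        wide = table.pivot_table(
            index="subject_id", columns=["condition", "foreperiod_ms"],
            values="mean_sr",
        )
        diff = wide[("full_certainty", 2000)] - 0.5 * (
            wide[("high_certainty_frequent", 2000)]
            + wide[("high_certainty_rare", 2000)]
        )
        assert res["full_vs_high_combined@2s"].mean_diff == pytest.approx(
            diff.mean(), abs=1e-12
        )

    def test_dz_and_ci(self, rng):
        table = self._table(rng, shift=0.5)
        c = {r.label: r for r in planned_contrasts(table)}["full_vs_low@1s"]
        assert c.dz == pytest.approx(c.t / math.sqrt(c.n), rel=1e-12)
        lo, hi = c.dz_ci
        assert lo < c.dz < hi
        # defining property of the noncentral-t inversion: at the bounds the
        # observed t sits at the 97.5th / 2.5th percentile
        assert sps.nct.cdf(c.t, c.df, lo * math.sqrt(c.n)) == pytest.approx(
            0.975, abs=1e-6
        )
        assert sps.nct.cdf(c.t, c.df, hi * math.sqrt(c.n)) == pytest.approx(
            0.025, abs=1e-6
        )


class TestBayesFactor:
    @pytest.mark.parametrize("t,n", [(0.0, 20), (0.383, 20), (1.2, 8), (2.5, 30), (10.0, 20)])
    def test_matches_independent_quadrature_and_pingouin(self, t, n):
        bf, err = bf01_ttest(t, n)
        assert bf == pytest.approx(bf01_g_integral(t, n), rel=1e-3)
        assert bf == pytest.approx(
            1.0 / float(pg.bayesfactor_ttest(t, n, paired=True)), rel=2e-3
        )
        assert err < 0.1

    def test_null_favored_at_t_zero(self):
        bf, _ = bf01_ttest(0.0, 20)
        assert bf > 1.0

    def test_large_t_overwhelms_null(self):
        bf, _ = bf01_ttest(10.0, 20)
        assert bf < 0.01

    def test_reciprocal_identity(self):
        bf01, _ = bf01_ttest(1.7, 15)
        assert bf01 * (1.0 / bf01) == pytest.approx(1.0)

    def test_monotone_decreasing_in_abs_t(self):
        ts = np.linspace(0, 6, 25)
        bfs = [bf01_ttest(t, 20)[0] for t in ts]
        assert all(b2 < b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert bf01_ttest(-2.0, 20)[0] == pytest.approx(bf01_ttest(2.0, 20)[0])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bf01_ttest(float("nan"), 20)
        with pytest.raises(ValueError):
            bf01_ttest(1.0, 1)


class TestWithinSubjectSem:
    def test_subject_offsets_do_not_inflate_sem(self, rng):
        cube = rng.normal(1.0, 0.3, (12, 4, 2))
        offsets = rng.normal(0, 5.0, (12, 1, 1))
        sem_clean = within_subject_sem(tidy_table(cube))
        sem_off = within_subject_sem(tidy_table(cube + offsets))
        np.testing.assert_allclose(sem_clean["sem"], sem_off["sem"], atol=1e-10)

    def test_identical_values_zero_sem(self):
        cube = np.ones((6, 4, 2))
        assert (within_subject_sem(tidy_table(cube))["sem"] == 0).all()

    def test_two_cell_bias_correction_factor(self, rng):
        cube = rng.normal(1.0, 0.5, (8, 1, 2))  # M = 2 cells
        table = tidy_table(cube, conditions=("full_certainty",))
        sem = within_subject_sem(table)["sem"].to_numpy()
        wide = cube[:, 0, :]
        centered = wide - wide.mean(axis=1, keepdims=True) + wide.mean()
        manual = centered.std(axis=0, ddof=1) / math.sqrt(8) * math.sqrt(2.0)
        np.testing.assert_allclose(sem, manual, atol=1e-12)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            within_subject_sem(tidy_table(np.ones((1, 4, 2))))


class TestTrend:
    def _low_table(self, Y):
        rows = []
        for i in range(Y.shape[0]):
            for j, fp in enumerate((1000, 1500, 2000, 2500, 3000)):
                rows.append(
                    {"subject_id": i, "condition": "low_certainty",
                     "foreperiod_ms": fp, "mean_sr": Y[i, j]}
                )
        return pd.DataFrame(rows)

    def test_strictly_decreasing_gives_negative_trend(self, rng):
        base = np.linspace(2.0, 0.5, 5)
        Y = base + rng.normal(0, 0.05, (10, 5))
        res = foreperiod_trend(self._low_table(Y))
        assert res.trend_t < 0
        assert res.trend_p < 0.001
        assert res.mean_score < 0

    def test_flat_data_zero_trend(self):
        Y = np.tile(np.arange(6)[:, None].astype(float), (1, 5))
        res = foreperiod_trend(self._low_table(Y))
        assert res.trend_t == 0.0
        assert res.anova.F == pytest.approx(0.0, abs=1e-12)

    def test_missing_foreperiod_rejected(self, rng):
        table = self._low_table(rng.normal(1, 0.1, (6, 5)))
        with pytest.raises(ValueError):
            foreperiod_trend(table[table["foreperiod_ms"] != 2500])


class TestFullBattery:
    def test_analyze_requires_complete_cells(self, rng):
        table = tidy_table(rng.normal(1, 0.3, (6, 4, 2)))
        with pytest.raises(ValueError, match="full_certainty"):
            analyze_sr_table(table.drop(table.index[0]))

    def test_verdicts_present_for_both_hypotheses(self, rng):
        table = tidy_table(rng.normal(1, 0.3, (8, 4, 2)))
        res = analyze_sr_table(table)
        assert set(res.verdicts) == {"certainty", "orienting"}
        assert res.trend is None  # no 5-foreperiod low-certainty cells
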