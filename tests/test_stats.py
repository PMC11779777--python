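"""Mixed-design ANOVA, sphericity, post hocs, t-tests, and Bayes factors."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from graphotrace import stats
from graphotrace.exceptions import DegenerateInputError, MissingCellError


# ---------------------------------------------------------------------------
# brute-force oracle: every SS by direct summation over marginal means
# ---------------------------------------------------------------------------

def oracle_mixed_ss(df):
    """Independent SS computation with plain Python loops."""
    subjects = sorted(df.participant_id.unique())
    times = list(pd.unique(df.time_point))
    values = {(r.participant_id, r.time_point): r.value for r in df.itertuples()}
    group_of = {r.participant_id: r.group for r in df.itertuples()}
    groups = sorted(set(group_of.values()))
    k, n_tot = len(times), len(subjects)

    grand = sum(values.values()) / len(values)
    subj_mean = {s: sum(values[(s, t)] for t in times) / k for s in subjects}
    time_mean = {t: sum(values[(s, t)] for s in subjects) / n_tot for t in times}
    group_subjects = {g: [s for s in subjects if group_of[s] == g] for g in groups}
    group_mean = {g: sum(subj_mean[s] for s in group_subjects[g]) / len(group_subjects[g])
                  for g in groups}
    cell_mean = {(g, t): sum(values[(s, t)] for s in group_subjects[g]) / len(group_subjects[g])
                 for g in groups for t in times}

    ss_total = sum((v - grand) ** 2 for v in values.values())
    ss_group = k * sum(len(group_subjects[g]) * (group_mean[g] - grand) ** 2
                       for g in groups)
    ss_subj = k * sum((subj_mean[s] - group_mean[group_of[s]]) ** 2 for s in subjects)
    ss_time = n_tot * sum((time_mean[t] - grand) ** 2 for t in times)
    ss_inter = sum(len(group_subjects[g])
                   * (cell_mean[(g, t)] - group_mean[g] - time_mean[t] + grand) ** 2
                   for g in groups for t in times)
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_inter
    return dict(total=ss_total, group=ss_group, subj=ss_subj, time=ss_time,
                inter=ss_inter, err=ss_err)


def random_table(rng, n_groups, n_times, n_per_group, group_eff=0.0,
                 time_eff=0.0, noise=1.0):
    times = [f"t{i}" for i in range(n_times)]
    rows = []
    for gi in range(n_groups):
        for s in range(n_per_group):
            pid = f"g{gi}s{s}"
            base = rng.normal(gi * group_eff, 1.0)
            for ti, tp in enumerate(times):
                rows.append((pid, f"g{gi}", tp,
                             base + ti * time_eff + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["participant_id", "group",
                                       "time_point", "value"])


class TestMixedAnova:
    def test_matches_bruteforce_oracle_on_100_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = rng.integers(2, 5)
            k = rng.integers(2, 5)
            n = rng.integers(3, 13)
            df = random_table(rng, g, k, n, group_eff=rng.uniform(0, 1),
                              time_eff=rng.uniform(0, 1))
            res = stats.mixed_anova(df)
            oracle = oracle_mixed_ss(df)
            assert res.terms["Group"].ss == pytest.approx(oracle["group"], rel=1e-10)
            assert res.terms["Time"].ss == pytest.approx(oracle["time"], rel=1e-10)
            assert res.terms["Time x Group"].ss == pytest.approx(oracle["inter"], rel=1e-10)
            assert res.ss_total == pytest.approx(oracle["total"], rel=1e-10)
            # decomposition is additive
            parts = (oracle["group"] + oracle["subj"] + oracle["time"]
                     + oracle["inter"] + oracle["err"])
            assert parts == pytest.approx(oracle["total"], rel=1e-9)

    def test_agrees_with_independent_library_implementation(self):
        rng = np.random.default_rng(7)
        df = random_table(rng, 4, 3, 10, group_eff=0.3, time_eff=0.5)
        res = stats.mixed_anova(df)
        ref = pg.mixed_anova(data=df, dv="value", within="time_point",
                             subject="participant_id", between="group")
        ref = ref.set_index("Source")
        assert res.terms["Group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res.terms["Time"].F == pytest.approx(ref.loc["time_point", "F"], rel=1e-9)
        assert res.terms["Time x Group"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert res.terms["Group"].p == pytest.approx(ref.loc["group", "p_unc"], rel=1e-9)

    def test_degenerate_zero_error_flagged(self):
        rows = []
        for g in ("a", "b"):
            for s in range(3):
                for ti, tp in enumerate(("pre", "post")):
                    rows.append((f"{g}{s}", g, tp, 1.0 if g == "a" else 2.0))
        df = pd.DataFrame(rows, columns=["participant_id", "group",
                                         "time_point", "value"])
        res = stats.mixed_anova(df)
        assert res.degenerate

    def test_pure_time_effect_leaves_group_near_null(self):
        # no group effect: across seeds, the group F should straddle its
        # null-distribution median
        rng = np.random.default_rng(0)
        med = sps.f.median(3, 36)
        above = 0
        n_rep = 60
        for _ in range(n_rep):
            df = random_table(rng, 4, 3, 10, group_eff=0.0, time_eff=0.6)
            if stats.mixed_anova(df).terms["Group"].F > med:
                above += 1
        assert sps.binomtest(above, n_rep, 0.5).pvalue > 0.01

    def test_missing_cell_rejected_with_participant_named(self):
        rng = np.random.default_rng(1)
        df = random_table(rng, 2, 3, 4)
        df = df.drop(df[(df.participant_id == "g0s1")
                        & (df.time_point == "t2")].index)
        with pytest.raises(MissingCellError, match="g0s1"):
            stats.mixed_anova(df)


class TestSphericity:
    @staticmethod
    def _one_group_table(y):
        rows = []
        for s in range(y.shape[0]):
            for t in range(y.shape[1]):
                rows.append((f"s{s}", "g", f"t{t}", y[s, t]))
        return pd.DataFrame(rows, columns=["participant_id", "group",
                                           "time_point", "value"])

    def test_compound_symmetric_covariance_w_near_one(self):
        rng = np.random.default_rng(5)
        n, k = 400, 3
        subj = rng.normal(0, 1, n)[:, None]
        y = subj + rng.normal(0, 1, (n, k))
        res = stats.mauchly_test(self._one_group_table(y))
        assert res.applicable
        assert res.mauchly_w > 0.97
        assert res.gg_epsilon > 0.97

    def test_heterogeneous_contrasts_rejected_and_matches_library(self):
        # strong AR(1)-like covariance violates sphericity
        rng = np.random.default_rng(6)
        n, k = 60, 4
        cov = np.array([[0.97 ** abs(i - j) * (1 + 2 * (i == j) * i)
                         for j in range(k)] for i in range(k)])
        y = rng.multivariate_normal(np.zeros(k), cov, n)
        df = self._one_group_table(y)
        res = stats.mauchly_test(df)
        assert res.mauchly_w < 0.8
        assert res.p < 0.05
        spher = pg.sphericity(df, dv="value", within="time_point",
                              subject="participant_id")
        assert res.mauchly_w == pytest.approx(spher.W, rel=1e-6)
        assert res.p == pytest.approx(spher.pval, rel=1e-3)
        eps = pg.epsilon(df, dv="value", within="time_point",
                         subject="participant_id")
        assert stats.gg_epsilon(df) == pytest.approx(float(eps), rel=1e-6)

    def test_two_levels_not_applicable(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, (10, 2))
        res = stats.mauchly_test(self._one_group_table(y))
        assert not res.applicable

    def test_epsilon_bounds_and_correction_direction(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = rng.integers(3, 6)
            y = rng.normal(0, 1, (12, k)) * rng.uniform(0.2, 3.0, k)
            df = self._one_group_table(y)
            eps = stats.gg_epsilon(df)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12
            res = stats.mixed_anova(df)
            if res.corrected:
                t = res.terms["Time"]
                if t.F >= 2.0:
                    # shrinking both dfs is conservative once F is clearly
                    # above 1 (near F = 1 the direction can invert)
                    assert res.corrected["Time"].p >= t.p - 1e-12


class TestPosthoc:
    @staticmethod
    def _paired_table(cols):
        rows = []
        for s in range(len(next(iter(cols.values())))):
            for tp, vals in cols.items():
                rows.append((f"s{s}", "g", tp, vals[s]))
        return pd.DataFrame(rows, columns=["participant_id", "group",
                                           "time_point", "value"])

    def test_identical_columns_give_zero_diff_unit_p(self):
        x = list(np.random.default_rng(0).normal(0, 1, 10))
        res = stats.bonferroni_posthoc(self._paired_table({"a": x, "b": x}))
        assert res[0].mean_diff == 0.0
        assert res[0].p_adjusted == 1.0

    def test_bonferroni_multiplies_by_number_of_pairs(self):
        rng = np.random.default_rng(3)
        tbl = self._paired_table({"a": rng.normal(0, 1, 12),
                                  "b": rng.normal(0.5, 1, 12),
                                  "c": rng.normal(1.0, 1, 12)})
        res = stats.bonferroni_posthoc(tbl)
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_dz_is_mean_diff_over_sd_of_diffs(self):
        # construct paired diffs with mean 2 and SD 1 exactly
        base = np.arange(10, dtype=float)
        d = np.random.default_rng(4).normal(0, 1, 10)
        d = (d - d.mean()) / d.std(ddof=1) + 2.0
        tbl = self._paired_table({"a": base, "b": base + d})
        res = stats.bonferroni_posthoc(tbl, pairs=[("a", "b")])
        assert res[0].cohen_d_z == pytest.approx(2.0)


class TestTwoSampleT:
    def test_equal_groups_give_zero_t_unit_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = stats.welch_or_student_t(x, x.copy())
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_brown_forsythe_detects_variance_heterogeneity(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            a = rng.normal(0, 0.5, 25)
            b = rng.normal(0, 3.0, 25)
            res = stats.welch_or_student_t(a, b)
            hits += res.welch
        assert hits >= 36  # heterogeneity detected almost always

    def test_pooled_t_matches_closed_form_summary_statistics(self):
        # groups constructed to have exactly the published-style summary
        # stats: n = 10 each, means 51.4 / 42.1, SDs 8.9 / 7.8
        def build(mean, sd, n, rng):
            z = rng.normal(0, 1, n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z
        rng = np.random.default_rng(10)
        a = build(51.4, 8.9, 10, rng)
        b = build(42.1, 7.8, 10, rng)
        sp = math.sqrt((9 * 8.9 ** 2 + 9 * 7.8 ** 2) / 18)
        t_oracle = (51.4 - 42.1) / (sp * math.sqrt(2 / 10))
        res = stats.welch_or_student_t(a, b)
        if not res.welch:
            assert res.t == pytest.approx(t_oracle, abs=5e-3)
            assert res.df == 18

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            stats.welch_or_student_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestBayesTTest:
    def test_null_data_favours_null(self):
        x = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, -0.2, 0.2, 0.1])
        assert stats.bayes_factor_ttest(x).bf01 > 1.0

    def test_bf01_decreases_monotonically_in_t(self):
        vals = [stats.jzs_bf01_from_t(t, 20, 19) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(vals) < 0)

    def test_large_t_gives_tiny_bf01(self):
        assert stats.jzs_bf01_from_t(8.0, 20, 19) < 1e-4

    def test_matches_independent_library_implementation(self):
        for t, nx, ny in [(0.5, 12, 15), (2.2, 10, 10), (3.7, 20, 18)]:
            mine = stats.jzs_bf01_from_t(t, nx * ny / (nx + ny), nx + ny - 2)
            ref = float(pg.bayesfactor_ttest(t, nx=nx, ny=ny))
            assert mine == pytest.approx(1.0 / ref, rel=1e-3)


class TestBayesAnova:
    def test_pure_time_effect_selects_time_model(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = random_table(rng, 2, 3, 10, time_eff=0.6, noise=0.7)
            best = stats.bayes_factor_anova(df)[0]
            wins += best.model == "Time"
        assert wins >= 18

    def test_null_data_disfavours_group_model(self):
        count = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            df = random_table(rng, 3, 3, 10)
            res = {b.model: b.bf01 for b in stats.bayes_factor_anova(df)}
            count += res["Group"] > 1.0
        assert count >= 9

    def test_null_model_has_unit_bf01(self):
        rng = np.random.default_rng(1)
        df = random_table(rng, 2, 3, 6)
        res = {b.model: b.bf01 for b in stats.bayes_factor_anova(df)}
        assert res["null"] == 1.0


class TestOneWayAnova:
    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.4, 0.8, 0.1)]
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c", "d"], 10)
        mine = stats.one_way_anova(values, labels)
        ref = sps.f_oneway(*groups)
        assert mine.F == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)
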