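import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microstates.stats import (
    chi_square_2x2,
    gg_epsilon,
    mixed_anova,
    pearson_correlation,
    simple_effects,
    t_from_summary,
    transition_tests,
)

CLASSES = ("A", "B", "C", "D")


def long_table(wide, groups):
    """Tidy parameter table from a subjects-by-classes matrix."""
    rows = []
    for s, (vals, g) in enumerate(zip(wide, groups)):
        for c, v in zip(CLASSES, vals):
            rows.append(
                {
                    "subject_id": f"s{s:03d}",
                    "group": g,
                    "class": c,
                    "duration_ms": float(v),
                }
            )
    return pd.DataFrame(rows)


def anova_oracle(wide, groups):
    """Mixed two-way ANOVA by explicit balanced-design sums of squares."""
    wide = np.asarray(wide, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    g, k = len(levels), wide.shape[1]
    n = wide.shape[0] // g
    grand = wide.mean()
    m_subj = wide.mean(axis=1)
    m_group = np.array([wide[groups == lv].mean() for lv in levels])
    m_class = wide.mean(axis=0)
    m_cell = np.array([wide[groups == lv].mean(axis=0) for lv in levels])

    ss_between_subj = k * np.sum((m_subj - grand) ** 2)
    ss_group = n * k * np.sum((m_group - grand) ** 2)
    ss_subj = ss_between_subj - ss_group
    ss_within = np.sum((wide - m_subj[:, None]) ** 2)
    ss_class = g * n * np.sum((m_class - grand) ** 2)
    ss_inter = n * np.sum(
        (m_cell - m_group[:, None] - m_class[None, :] + grand) ** 2
    )
    ss_error = ss_within - ss_class - ss_inter

    df_group, df_subj = g - 1, g * (n - 1)
    df_class = k - 1
    df_inter = (g - 1) * (k - 1)
    df_error = g * (n - 1) * (k - 1)
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    f_class = (ss_class / df_class) / (ss_error / df_error)
    f_inter = (ss_inter / df_inter) / (ss_error / df_error)
    return {
        "group": (f_group, df_group, df_subj, sps.f.sf(f_group, df_group, df_subj)),
        "class": (f_class, df_class, df_error, sps.f.sf(f_class, df_class, df_error)),
        "interaction": (
            f_inter, df_inter, df_error, sps.f.sf(f_inter, df_inter, df_error),
        ),
    }


class TestMixedAnova:
    def test_study_sized_design_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        wide = rng.standard_normal((127, 4))
        groups = np.array(["mwoa"] * 61 + ["hc"] * 66)
        res = {r.effect: r for r in mixed_anova(long_table(wide, groups), "duration_ms")}
        assert (res["group"].df1, res["group"].df2) == (1, 125)
        assert (res["class"].df1, res["class"].df2) == (3, 375)
        assert (res["interaction"].df1, res["interaction"].df2) == (3, 375)

    def test_matches_explicit_glm_oracle(self):
        rng = np.random.default_rng(1)
        wide = rng.standard_normal((12, 4)) + rng.standard_normal((12, 1))
        groups = np.array(["g1"] * 6 + ["g2"] * 6)
        res = {r.effect: r for r in mixed_anova(long_table(wide, groups), "duration_ms")}
        oracle = anova_oracle(wide, groups)
        for effect, (f, df1, df2, p) in oracle.items():
            assert res[effect].F == pytest.approx(f, rel=1e-9)
            assert (res[effect].df1, res[effect].df2) == (df1, df2)
            assert res[effect].p_uncorrected == pytest.approx(p, rel=1e-9)

    def test_compound_symmetry_gives_epsilon_one(self):
        rng = np.random.default_rng(2)
        n = 400
        x = rng.standard_normal((n, 1)) + rng.standard_normal((n, 4))
        eps = gg_epsilon(x)
        assert eps > 0.95

    def test_epsilon_bounds_for_four_levels(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            x = rng.standard_normal((9, 4)) * rng.uniform(0.2, 3.0, size=4)
            eps = gg_epsilon(x)
            assert 1.0 / 3.0 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_affine_invariance_of_f(self):
        rng = np.random.default_rng(4)
        wide = rng.standard_normal((16, 4))
        groups = np.array(["g1"] * 8 + ["g2"] * 8)
        base = mixed_anova(long_table(wide, groups), "duration_ms")
        shifted = mixed_anova(long_table(wide * 3.7 + 11.0, groups), "duration_ms")
        for a, b in zip(base, shifted):
            assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_between_f_equals_squared_t_on_subject_means(self):
        rng = np.random.default_rng(5)
        wide = rng.standard_normal((20, 4))
        groups = np.array(["g1"] * 10 + ["g2"] * 10)
        res = {r.effect: r for r in mixed_anova(long_table(wide, groups), "duration_ms")}
        m = wide.mean(axis=1)
        t = sps.ttest_ind(m[:10], m[10:], equal_var=True).statistic
        assert res["group"].F == pytest.approx(t**2, rel=1e-9)

    def test_missing_cells_rejected(self):
        rng = np.random.default_rng(6)
        tab = long_table(rng.standard_normal((6, 4)), ["g1"] * 3 + ["g2"] * 3)
        with pytest.raises(ValueError):
            mixed_anova(tab.iloc[:-1], "duration_ms")


class TestSimpleEffects:
    def test_study_sized_degrees_of_freedom(self):
        rng = np.random.default_rng(7)
        wide = rng.standard_normal((127, 4))
        groups = np.array(["mwoa"] * 61 + ["hc"] * 66)
        res = simple_effects(long_table(wide, groups), "duration_ms")
        assert len(res) == 4
        assert all(r.df == 125 for r in res)

    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(8)
        half = rng.standard_normal((9, 4))
        wide = np.vstack([half, half])
        groups = np.array(["g1"] * 9 + ["g2"] * 9)
        res = simple_effects(long_table(wide, groups), "duration_ms")
        for r in res:
            assert r.t == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula_on_toy_table(self):
        wide = np.array(
            [[1.0, 2, 3, 4], [2, 3, 4, 5], [3, 4, 5, 6],
             [2, 1, 0, 1], [3, 2, 1, 2], [4, 3, 2, 3]]
        )
        groups = np.array(["g1"] * 3 + ["g2"] * 3)
        res = {r.comparison: r for r in simple_effects(long_table(wide, groups), "duration_ms")}
        x1, x2 = wide[:3, 0], wide[3:, 0]
        sp = np.sqrt(((x1.var(ddof=1) * 2 + x2.var(ddof=1) * 2) / 4) * (1 / 3 + 1 / 3))
        t_hand = (x1.mean() - x2.mean()) / sp
        key = [k for k in res if "[A]" in k][0]
        assert res[key].t == pytest.approx(t_hand, rel=1e-12)


class TestTransitionTests:
    def trans_table(self, mat1, mat2):
        rows = []
        for g, mat in (("g1", mat1), ("g2", mat2)):
            for s, vals in enumerate(mat):
                for j, tr in enumerate(
                    f"{a}->{b}" for a in CLASSES for b in CLASSES if a != b
                ):
                    rows.append(
                        {
                            "subject_id": f"{g}s{s}",
                            "group": g,
                            "transition": tr,
                            "percent": float(vals[j]),
                        }
                    )
        return pd.DataFrame(rows)

    def test_bonferroni_times_twelve_and_cap(self):
        rng = np.random.default_rng(9)
        res = transition_tests(
            self.trans_table(rng.standard_normal((8, 12)) + 8.3,
                             rng.standard_normal((8, 12)) + 8.3)
        )
        assert len(res) == 12
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, 12 * r.p_raw), abs=1e-12)

    def test_study_sized_degrees_of_freedom(self):
        rng = np.random.default_rng(10)
        res = transition_tests(
            self.trans_table(rng.standard_normal((61, 12)) + 8.3,
                             rng.standard_normal((66, 12)) + 8.3)
        )
        assert all(r.df == 125 for r in res)

    def test_constant_transition_reported_missing(self):
        rng = np.random.default_rng(11)
        m1 = rng.standard_normal((5, 12)) + 8.3
        m2 = rng.standard_normal((5, 12)) + 8.3
        m1[:, 0] = m2[:, 0] = 5.0
        res = transition_tests(self.trans_table(m1, m2))
        assert sum(np.isnan(r.t) for r in res) == 1

    def test_familywise_error_controlled_under_null(self, mwoa_spec):
        """Null cohorts (both groups from the planted chain): the Bonferroni
        battery rejects anywhere in at most ~5% of cohorts."""
        rng = np.random.default_rng(12)
        P = mwoa_spec.embedded_transitions
        cum = P.cumsum(axis=1)
        n_subj, n_seg, n_cohorts = 40, 900, 200
        fw_rejections = 0
        for _ in range(n_cohorts):
            states = rng.integers(0, 4, size=n_subj)
            counts = np.zeros((n_subj, 16))
            for _step in range(n_seg):
                nxt = (rng.random(n_subj)[:, None] < cum[states]).argmax(axis=1)
                np.add.at(counts, (np.arange(n_subj), states * 4 + nxt), 1)
                states = nxt
            pct = counts / counts.sum(axis=1, keepdims=True) * 100.0
            off = [i * 4 + j for i in range(4) for j in range(4) if i != j]
            half = n_subj // 2
            res = transition_tests(self.trans_table(pct[:half][:, off], pct[half:][:, off]))
            if any(r.p_bonferroni < 0.05 for r in res if np.isfinite(r.p_bonferroni)):
                fw_rejections += 1
        assert fw_rejections / n_cohorts <= 0.05 + 0.035


class TestSummaryStatistics:
    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,expected",
        [
            (31.44, 4.63, 66, 32.79, 6.83, 61, -1.31),  # age, HC minus MwoA
            (15.87, 3.08, 66, 15.76, 3.16, 61, 0.20),  # education
            (21.81, 2.74, 66, 21.56, 3.02, 61, 0.50),  # BMI
            (28.50, 0.90, 66, 28.18, 1.12, 61, 1.78),  # MoCA
        ],
    )
    def test_reproduces_printed_demographics(self, m1, s1, n1, m2, s2, n2, expected):
        # inputs are printed at 2 dp, so recomputed t can differ from the
        # printed value by ~0.01 (e.g. BMI: 0.489 vs printed 0.50)
        res = t_from_summary(m1, s1, n1, m2, s2, n2)
        assert res.t == pytest.approx(expected, abs=0.015)
        assert res.df == 125

    def test_equal_means_give_zero(self):
        assert t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12).t == pytest.approx(0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            t_from_summary(1.0, 0.0, 5, 2.0, 1.0, 10)


class TestChiSquare:
    def test_reproduces_printed_sex_table(self):
        res = chi_square_2x2(np.array([[50, 11], [50, 16]]), yates=True)
        assert res.chi2 == pytest.approx(0.41, abs=0.005)
        assert res.df == 1

    def test_identical_rows_give_zero(self):
        res = chi_square_2x2(np.array([[30, 10], [30, 10]]), yates=False)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_permutation_oracle(self):
        """Yates-corrected p tracks the label-permutation p within 0.02."""
        table = np.array([[50, 11], [50, 16]])
        res = chi_square_2x2(table, yates=True)
        obs = chi_square_2x2(table, yates=False).chi2
        rng = np.random.default_rng(13)
        n1, nf, n = 61, 100, 127
        f_in_g1 = rng.hypergeometric(nf, n - nf, n1, size=40000)
        # vectorized uncorrected chi-square over the permuted tables
        a = f_in_g1.astype(float)
        b, c, d = n1 - a, nf - a, (n - n1) - (nf - a)
        tot = float(n)
        ea, eb = n1 * nf / tot, n1 * (n - nf) / tot
        ec, ed = (n - n1) * nf / tot, (n - n1) * (n - nf) / tot
        stats = (
            (a - ea) ** 2 / ea + (b - eb) ** 2 / eb
            + (c - ec) ** 2 / ec + (d - ed) ** 2 / ed
        )
        p_perm = np.mean(stats >= obs - 1e-12)
        assert abs(res.p - p_perm) < 0.02

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x).r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -2 * x + 7).r == pytest.approx(-1.0)

    def test_bivariate_recovery_of_planted_rho(self):
        """500 bivariate-normal replicates at n=61: mean r within 0.03."""
        rng = np.random.default_rng(14)
        rho = -0.27
        rs = []
        for _ in range(500):
            x = rng.standard_normal(61)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(61)
            rs.append(pearson_correlation(x, y).r)
        assert abs(np.mean(rs) - rho) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(10), np.arange(10.0))
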