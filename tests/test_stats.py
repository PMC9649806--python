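import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from osteosim.stats import (ValidationError, arm_table, build_report,
                            fit_inclination_lmm, paired_vs_preop, rm_anova,
                            validate_long_table)
from tests.conftest import make_lmm_table


def make_wide(n=12, k=7, effect=None, seed=0, rho=0.0, subject_sd=1.0,
              noise_sd=0.5):
    rng = np.random.default_rng(seed)
    effect = np.zeros(k) if effect is None else np.asarray(effect)
    Y = np.empty((n, k))
    for i in range(n):
        b = rng.normal(0, subject_sd)
        e = 0.0
        for j in range(k):
            e = rho * e + rng.normal(0, noise_sd * np.sqrt(1 - rho ** 2))
            Y[i, j] = b + effect[j] + e
    return Y


def wide_to_long(Y, angles=None):
    n, k = Y.shape
    angles = list(range(0, 5 * k, 5)) if angles is None else angles
    rows = []
    for i in range(n):
        for j, a in enumerate(angles):
            rows.append({"subject_id": f"S{i:02d}", "inclination_deg": a,
                         "pts_deg": Y[i, j], "pts_change_deg": Y[i, j]})
    return pd.DataFrame(rows)


class TestLongTable:
    def test_unbalanced_rejected(self):
        tab = wide_to_long(make_wide(5, 7))
        with pytest.raises(ValidationError):
            validate_long_table(tab.iloc[:-1],
                                tuple(range(0, 35, 5)))

    def test_arm_restriction(self):
        tab = wide_to_long(make_wide(4, 13), angles=list(range(-30, 31, 5)))
        ant = arm_table(tab, "anterior")
        post = arm_table(tab, "posterior")
        assert set(ant["inclination_deg"]) == set(range(0, 31, 5))
        assert set(post["inclination_deg"]) == set(range(-30, 1, 5))
        with pytest.raises(ValidationError):
            arm_table(tab, "sideways")


class TestRmAnova:
    def test_cross_check_against_pingouin(self):
        Y = make_wide(14, 7, effect=np.linspace(0, 2, 7), seed=2, rho=0.4)
        tab = wide_to_long(Y)
        res = rm_anova(tab, "anterior")
        aov = pg.rm_anova(data=tab, dv="pts_deg", within="inclination_deg",
                          subject="subject_id", correction=True)
        assert res.f_stat == pytest.approx(float(aov["F"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(aov["p_unc"][0]), abs=1e-12)
        sph = pg.sphericity(data=tab, dv="pts_deg", within="inclination_deg",
                            subject="subject_id")
        assert res.mauchly_w == pytest.approx(float(sph.W), rel=1e-9)
        assert res.mauchly_p == pytest.approx(float(sph.pval), rel=1e-6)
        gg = pg.epsilon(tab, dv="pts_deg", within="inclination_deg",
                        subject="subject_id", correction="gg")
        hf = pg.epsilon(tab, dv="pts_deg", within="inclination_deg",
                        subject="subject_id", correction="hf")
        assert res.gg_epsilon == pytest.approx(float(gg), rel=1e-9)
        assert res.hf_epsilon == pytest.approx(min(1.0, float(hf)), rel=1e-9)

    def test_null_f_near_one(self):
        fs = []
        for seed in range(40):
            tab = wide_to_long(make_wide(12, 7, seed=seed))
            fs.append(rm_anova(tab, "anterior").f_stat)
        # E[F] = df2/(df2-2) ~ 1.03 under the null
        assert np.mean(fs) == pytest.approx(1.03, abs=0.25)

    def test_null_p_uniform(self):
        ps = [rm_anova(wide_to_long(make_wide(12, 7, seed=s)),
                       "anterior").corrected_p for s in range(60)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_compound_symmetry_epsilon_near_one(self):
        # CS data satisfy sphericity: HF epsilon ~ 1
        Y = make_wide(40, 5, seed=4, rho=0.0, subject_sd=2.0, noise_sd=1.0)
        res = rm_anova(wide_to_long(Y), "anterior")
        assert res.hf_epsilon > 0.9
        assert res.mauchly_p > 0.01

    def test_two_level_reduces_to_paired_t(self):
        Y = make_wide(10, 2, effect=[0.0, 0.8], seed=5)
        tab = wide_to_long(Y, angles=[0, 5])
        res = rm_anova(tab, "anterior")
        t, p = sps.ttest_rel(Y[:, 0], Y[:, 1])
        assert res.f_stat == pytest.approx(t ** 2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_bonferroni_factor(self):
        Y = make_wide(10, 7, effect=np.linspace(0, 1, 7), seed=6)
        tab = wide_to_long(Y)
        res = rm_anova(tab, "anterior")
        t, praw = sps.ttest_rel(Y[:, 0], Y[:, 3])
        lv = res.levels
        assert res.pairwise_p.loc[lv[0], lv[3]] == \
            pytest.approx(min(1.0, praw * 21), rel=1e-9)
        assert np.allclose(res.pairwise_p.values, res.pairwise_p.values.T,
                           equal_nan=True)


class TestPairedVsPreop:
    def test_identical_pre_post(self):
        tab = wide_to_long(make_wide(8, 3), angles=[0, 5, 10])
        pre = tab[tab.inclination_deg == 0].set_index("subject_id")["pts_deg"]
        res = paired_vs_preop(tab, pre)
        at0 = [r for r in res if r.inclination_deg == 0][0]
        assert at0.t_stat == 0.0 and at0.p_value == 1.0

    def test_constant_shift_degenerate(self):
        Y = make_wide(8, 2, seed=7)
        Y[:, 1] = Y[:, 0] + 1.0
        tab = wide_to_long(Y, angles=[0, 5])
        pre = pd.Series(Y[:, 0], index=[f"S{i:02d}" for i in range(8)])
        res = paired_vs_preop(tab, pre)
        at5 = [r for r in res if r.inclination_deg == 5][0]
        assert at5.degenerate
        assert at5.mean_diff == pytest.approx(1.0)

    def test_hand_computed_five_subjects(self):
        # textbook paired t on printed toy numbers
        pre = np.array([8.0, 9.5, 7.2, 10.1, 8.8])
        post = np.array([9.1, 9.9, 8.0, 10.0, 9.5])
        d = post - pre
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_expect = 2 * sps.t.sf(abs(t_expect), 4)
        rows = [{"subject_id": f"S{i}", "inclination_deg": 10,
                 "pts_deg": post[i], "pts_change_deg": d[i]}
                for i in range(5)]
        res = paired_vs_preop(pd.DataFrame(rows),
                              pd.Series(pre, index=[f"S{i}" for i in range(5)]))
        assert res[0].t_stat == pytest.approx(t_expect, rel=1e-12)
        assert res[0].p_value == pytest.approx(p_expect, rel=1e-12)

    def test_missing_pre_raises(self):
        tab = wide_to_long(make_wide(5, 2), angles=[0, 5])
        pre = tab[tab.inclination_deg == 0].set_index("subject_id")["pts_deg"]
        with pytest.raises(ValidationError):
            paired_vs_preop(tab, pre.iloc[:-1])


class TestLmm:
    def test_recovery_of_known_slope(self):
        tab = make_lmm_table(0.08, tau=0.3, sd=0.3, seed=1)
        res = fit_inclination_lmm(tab, "anterior")
        assert abs(res.beta - 0.08) < 2 * res.se
        assert res.p_value < 0.001

    def test_noise_free_exact(self):
        tab = make_lmm_table(0.08, tau=0.2, sd=1e-9, seed=2)
        res = fit_inclination_lmm(tab, "anterior")
        assert res.beta == pytest.approx(0.08, abs=1e-6)
        assert res.se < 1e-4

    def test_ar1_structure_preferred_on_ar1_data(self):
        tab = make_lmm_table(0.05, tau=0.4, sd=0.5, rho=0.7, seed=3, n=40)
        res = fit_inclination_lmm(tab, "anterior")
        assert res.covariance_structure == "random-intercept+AR1"
        assert 0.4 < res.rho < 0.9

    def test_independent_structure_preferred_on_iid_data(self):
        tab = make_lmm_table(0.05, tau=0.4, sd=0.5, rho=0.0, seed=4, n=40)
        res = fit_inclination_lmm(tab, "anterior")
        assert res.covariance_structure == "random-intercept"

    def test_type_one_error_calibration(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            tab = make_lmm_table(0.0, tau=0.3, sd=0.3, n=10, seed=seed)
            res = fit_inclination_lmm(tab, "anterior")
            hits += abs(res.beta) < 2 * res.se
        assert hits / n_rep >= 0.93

    def test_cross_check_against_statsmodels_random_intercept(self):
        import statsmodels.formula.api as smf
        tab = make_lmm_table(0.06, tau=0.5, sd=0.4, seed=6)
        res = fit_inclination_lmm(tab, "anterior")
        md = smf.mixedlm("pts_change_deg ~ inclination_deg", tab,
                         groups=tab["subject_id"]).fit(reml=True)
        # compare the random-intercept candidate (identical model)
        ri = res.candidates["random-intercept"]
        assert md.params["inclination_deg"] == pytest.approx(res.beta, abs=5e-4)
        assert ri["sigma2"] == pytest.approx(float(md.scale), rel=0.05)


class TestBuildReport:
    def test_schema_and_consistency(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(6):
            b = rng.normal(0, 1)
            for a in range(-30, 31, 5):
                rows.append({"subject_id": f"S{i}", "inclination_deg": a,
                             "pts_deg": 9 + b + 0.07 * a + rng.normal(0, 0.3),
                             "pts_change_deg": 0.07 * a + rng.normal(0, 0.3)})
        tab = pd.DataFrame(rows)
        pre = pd.Series(9.0, index=[f"S{i}" for i in range(6)])
        rep = build_report(tab, pre)
        assert len(rep["summary"]) == 13
        assert set(rep["summary"]["inclination_deg"]) == set(range(-30, 31, 5))
        # summary means equal the long-table group means
        for _, row in rep["summary"].iterrows():
            grp = tab[tab.inclination_deg == row["inclination_deg"]]
            assert row["change_mean"] == pytest.approx(
                grp["pts_change_deg"].mean(), rel=1e-12)
        assert set(rep["lmm"]) == {"anterior", "posterior"}

    def test_ci_shrinks_with_n(self):
        def half_width(n, seed):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(n):
                for a in range(-30, 31, 5):
                    rows.append({"subject_id": f"S{i}", "inclination_deg": a,
                                 "pts_deg": 9 + rng.normal(0, 1),
                                 "pts_change_deg": rng.normal(0, 1)})
            tab = pd.DataFrame(rows)
            pre = pd.Series(9.0, index=[f"S{i}" for i in range(n)])
            rep = build_report(tab, pre)
            return rep["scatter"]["ci95_half"].mean()

        h30 = np.mean([half_width(30, s) for s in range(3)])
        h120 = np.mean([half_width(120, s) for s in range(3)])
        assert h120 < 0.65 * h30  # ~ sqrt(4) shrinkage
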