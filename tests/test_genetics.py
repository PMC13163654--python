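"""MR estimators, heterogeneity, MR-PRESSO, LDSC and colocalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbidnet import genetics, synthdata
from comorbidnet.genetics import InstrumentSet
from comorbidnet.synthdata import ColocScenario, LdscScenario, MrScenario


def ivw_oracle(inst):
    """Closed-form inverse-variance-weighted mean of Wald ratios."""
    ratios = inst.by / inst.bx
    w = inst.bx ** 2 / inst.se_by ** 2
    return np.sum(w * ratios) / np.sum(w)


class TestIvw:
    def test_two_instrument_closed_form(self):
        # ratios 0.2 (se 0.1) and 0.4 (se 0.2) -> weighted mean 0.24,
        # se = 1/sqrt(125)
        inst = InstrumentSet(bx=[1.0, 1.0], se_bx=[1e-6, 1e-6],
                             by=[0.2, 0.4], se_by=[0.1, 0.2])
        r = genetics.mr_fit(inst, method="ivw")
        assert r.estimate == pytest.approx(0.24)
        assert r.se == pytest.approx(1 / math.sqrt(125))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_ivw_equals_weighted_mean_of_ratios(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        inst = InstrumentSet(bx=rng.normal(0.2, 0.1, n) + 0.3,
                             se_bx=rng.uniform(0.01, 0.1, n),
                             by=rng.normal(0, 0.2, n),
                             se_by=rng.uniform(0.01, 0.3, n))
        r = genetics.mr_fit(inst, method="ivw")
        assert r.estimate == pytest.approx(ivw_oracle(inst), rel=1e-10)

    def test_ci_brackets_odds_ratio(self):
        ex, oc = synthdata.gen_mr_data(MrScenario(seed=4))
        inst = genetics.instruments_from_summaries(ex, oc)
        r = genetics.mr_fit(inst)
        assert r.ci_low <= r.odds_ratio <= r.ci_high


class TestEggerAndMedian:
    def test_exact_linear_data_recovers_intercept_and_slope(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        c, theta = 0.05, 0.4
        inst = InstrumentSet(bx=bx, se_bx=[1e-6] * 4,
                             by=c + theta * bx, se_by=[0.05] * 4)
        r = genetics.mr_fit(inst, method="egger")
        assert r.intercept == pytest.approx(c, abs=1e-9)
        assert r.estimate == pytest.approx(theta, abs=1e-9)

    def test_egger_intercept_unbiased_for_planted_pleiotropy(self):
        intercepts = []
        for seed in range(40):
            ex, oc = synthdata.gen_mr_data(
                MrScenario(pleiotropy_intercept=0.05, seed=seed))
            inst = genetics.instruments_from_summaries(ex, oc)
            intercepts.append(genetics.mr_fit(inst, "egger").intercept)
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.01)

    def test_weighted_median_resists_minority_outliers(self):
        rng = np.random.default_rng(7)
        n, theta = 60, math.log(1.32)
        bx = rng.uniform(0.1, 0.4, n)
        by = theta * bx + rng.normal(0, 0.02, n)
        by[-10:] += 0.5                     # 1/6 of instruments pleiotropic
        inst = InstrumentSet(bx=bx, se_bx=np.full(n, 1e-4), by=by,
                             se_by=np.full(n, 0.02))
        wm = genetics.mr_fit(inst, "weighted_median", seed=1)
        ivw = genetics.mr_fit(inst, "ivw")
        assert abs(wm.estimate - theta) < 0.05
        assert abs(wm.estimate - theta) < abs(ivw.estimate - theta)

    def test_minimum_instrument_counts_enforced(self):
        inst = InstrumentSet(bx=[0.1, 0.2], se_bx=[0.01, 0.01],
                             by=[0.0, 0.1], se_by=[0.1, 0.1])
        for method in ("egger", "weighted_median"):
            with pytest.raises(ValueError, match="3"):
                genetics.mr_fit(inst, method)


class TestHeterogeneity:
    def test_two_instrument_hand_computation(self):
        inst = InstrumentSet(bx=[1.0, 1.0], se_bx=[1e-6, 1e-6],
                             by=[0.2, 0.4], se_by=[0.1, 0.2])
        q = genetics.heterogeneity_q(inst)
        assert q["Q"] == pytest.approx(0.8)
        assert q["df"] == 1

    def test_identical_ratios_give_zero_q(self):
        inst = InstrumentSet(bx=[0.1, 0.2, 0.4], se_bx=[1e-6] * 3,
                             by=[0.05, 0.10, 0.20], se_by=[0.1, 0.1, 0.1])
        q = genetics.heterogeneity_q(inst)
        assert q["Q"] == pytest.approx(0.0, abs=1e-12)
        assert q["p"] == pytest.approx(1.0)

    def test_chi_square_tail_matches_reported_scale(self):
        # Q = 142.3 on 126 df has upper-tail p ~ 0.15
        from scipy.stats import chi2
        assert chi2.sf(142.3, 126) == pytest.approx(0.146, abs=0.01)


class TestMrPresso:
    def test_noise_free_instruments_give_p_near_one(self):
        bx = np.linspace(0.1, 0.5, 8)
        inst = InstrumentSet(bx=bx, se_bx=[1e-6] * 8, by=0.3 * bx,
                             se_by=[0.05] * 8)
        res = genetics.mr_presso(inst, n_sim=200, seed=0)
        assert res["global_p"] > 0.9

    def test_planted_outlier_is_flagged(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.1, 0.5, 20)
        by = 0.3 * bx + rng.normal(0, 0.05, 20)
        by[7] += 10 * 0.05
        inst = InstrumentSet(bx=bx, se_bx=[1e-6] * 20, by=by,
                             se_by=[0.05] * 20)
        res = genetics.mr_presso(inst, n_sim=500, seed=1)
        assert res["outlier_flags"][7]
        assert res["global_p"] < 0.05

    def test_clean_default_scenario_rarely_rejects(self):
        rejections = 0
        for seed in range(20):
            ex, oc = synthdata.gen_mr_data(MrScenario(seed=seed))
            inst = genetics.instruments_from_summaries(ex, oc)
            res = genetics.mr_presso(inst, n_sim=200, seed=seed)
            rejections += res["global_p"] < 0.05
        assert rejections <= 3


class TestLeaveOneOut:
    def test_n2_rows_equal_remaining_ratio(self):
        inst = InstrumentSet(bx=[1.0, 2.0], se_bx=[1e-6] * 2,
                             by=[0.2, 0.8], se_by=[0.1, 0.1])
        loo = genetics.leave_one_out(inst)
        assert loo["estimate"].iloc[0] == pytest.approx(0.4)   # keeps snp 2
        assert loo["estimate"].iloc[1] == pytest.approx(0.2)   # keeps snp 1

    def test_outlier_exclusion_moves_estimate_most(self):
        ex, oc = synthdata.gen_mr_data(
            MrScenario(n_outliers=1, outlier_offset=1.0, seed=3))
        inst = genetics.instruments_from_summaries(ex, oc)
        loo = genetics.leave_one_out(inst)
        full = genetics.mr_fit(inst).estimate
        moves = (loo["estimate"] - full).abs()
        assert moves.idxmax() == len(inst) - 1

    def test_default_scenario_all_inside_full_ci(self):
        ex, oc = synthdata.gen_mr_data(MrScenario(seed=1))
        inst = genetics.instruments_from_summaries(ex, oc)
        assert genetics.leave_one_out(inst)["inside_full_ci"].all()


class TestLdsc:
    def test_self_correlation_is_one(self):
        s1, _ = synthdata.gen_gwas_pair(LdscScenario(seed=0))
        r = genetics.ldsc_rg(s1, s1)
        assert r.rg == pytest.approx(1.0, abs=0.02)

    def test_independent_traits_give_near_zero_rg(self):
        hits = 0
        for seed in range(20):
            s1, s2 = synthdata.gen_gwas_pair(LdscScenario(rg=0.0, seed=seed))
            r = genetics.ldsc_rg(s1, s2)
            hits += abs(r.rg) < 2 * r.se
        assert hits >= 18

    def test_invariance_to_snp_order(self):
        s1, s2 = synthdata.gen_gwas_pair(LdscScenario(seed=3))
        r1 = genetics.ldsc_rg(s1, s2)
        perm = s1.sample(frac=1.0, random_state=0).reset_index(drop=True)
        r2 = genetics.ldsc_rg(perm, s2)
        assert r1.rg == pytest.approx(r2.rg, abs=1e-9)

    def test_few_snps_reduce_jackknife_blocks(self):
        s1, s2 = synthdata.gen_gwas_pair(LdscScenario(n_snps=50, seed=0))
        r = genetics.ldsc_rg(s1, s2, n_blocks=200)
        assert np.isfinite(r.rg)


class TestColoc:
    def test_log_abf_hand_value(self):
        # z = 5, V = 0.01, W = 0.04: 0.5*(ln 0.2 + 0.8*25) = 9.195
        from comorbidnet.genetics import _log_abf
        labf = _log_abf(np.array([0.5]), np.array([0.1]), 0.04)
        assert labf[0] == pytest.approx(
            0.5 * (math.log(0.2) + 25 * 0.8), rel=1e-9)

    def test_no_association_favors_pp0(self):
        rng = np.random.default_rng(0)
        m = 200
        se = np.full(m, 0.05)
        df = lambda z: pd.DataFrame(
            {"snp": [f"rs{i}" for i in range(m)], "beta": z * se, "se": se})
        res = genetics.coloc_abf(df(rng.normal(0, 0.1, m)),
                                 df(rng.normal(0, 0.1, m)))
        assert res.pp0 > 0.9

    def test_distinct_causal_variants_favor_pp3(self):
        r1, r2 = synthdata.gen_coloc_region(ColocScenario(shared=False, seed=0))
        res = genetics.coloc_abf(r1, r2)
        assert res.pp3 > res.pp4
        assert res.pp3 > 0.5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_posteriors_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 50))
        se = rng.uniform(0.01, 0.5, m)
        mk = lambda z: pd.DataFrame(
            {"snp": [f"rs{i}" for i in range(m)], "beta": z * se, "se": se})
        res = genetics.coloc_abf(mk(rng.normal(0, 3, m)),
                                 mk(rng.normal(0, 3, m)))
        assert abs(res.as_array().sum() - 1.0) < 1e-9

    def test_mismatched_snp_sets_rejected(self):
        a = pd.DataFrame({"snp": ["rs1", "rs2"], "beta": [0.1, 0.2],
                          "se": [0.1, 0.1]})
        b = pd.DataFrame({"snp": ["rs1", "rs3"], "beta": [0.1, 0.2],
                          "se": [0.1, 0.1]})
        with pytest.raises(ValueError, match="rs"):
            genetics.coloc_abf(a, b)
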