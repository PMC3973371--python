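"""Statistics tests: decomposition, mixed-model fits, Friedman, effect
sizes, summary conventions — each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from frictionpad.scalestats import (
    exponent_composition,
    fit_powerlaw_mixed,
    friedman_test,
    mean_t_ci,
    median_mad,
    real_contact_area,
    rm_effect_size,
    summarize_by_load,
)
from frictionpad.synthgen import SynthParams, make_powerlaw_dataset


class TestRealContactArea:
    def test_high_load_group_means_compose_to_6150_um2(self):
        assert real_contact_area(0.101, 0.132, 0.461) == pytest.approx(
            6.15e3, rel=0.001)

    def test_any_zero_factor_gives_zero(self):
        assert real_contact_area(0.0, 0.132, 0.461) == 0.0
        assert real_contact_area(0.101, 0.0, 0.461) == 0.0

    def test_low_to_high_load_ratio_is_an_order_of_magnitude(self):
        ratio = (real_contact_area(0.101, 0.132, 0.461)
                 / real_contact_area(0.034, 0.071, 0.235))
        assert ratio == pytest.approx(10.8, abs=0.05)
        assert ratio >= 10.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            real_contact_area(-0.1, 0.1, 0.1)


class TestMixedPowerLaw:
    def test_noiseless_offsets_recover_slope_exactly(self):
        df, _ = make_powerlaw_dataset(individual_sd=0.12, noise_sd=0.0,
                                      params=SynthParams(seed=1))
        f = fit_powerlaw_mixed(df, "A_A_mm2")
        assert f.slope == pytest.approx(0.362, abs=1e-9)
        assert f.r2_conditional == pytest.approx(1.0)
        assert f.method == "exact"

    def test_matches_independent_mixed_model_implementation(self):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        df, _ = make_powerlaw_dataset(params=SynthParams(seed=5))
        f = fit_powerlaw_mixed(df, "A_A_mm2")
        d = df.assign(x=np.log10(df.load_mN), y=np.log10(df.A_A_mm2))
        m = statsmodels.mixedlm("y ~ x", d, groups=d.individual_id).fit(
            reml=True)
        assert f.slope == pytest.approx(m.params["x"], abs=1e-4)
        assert f.slope_se == pytest.approx(m.bse["x"], rel=1e-3)
        assert f.intercept == pytest.approx(m.params["Intercept"], abs=1e-4)
        assert f.sigma2_between == pytest.approx(
            float(m.cov_re.iloc[0, 0]), rel=1e-3)
        assert f.sigma2_residual == pytest.approx(m.scale, rel=1e-3)

    def test_conditional_r2_never_below_marginal(self):
        for rep in range(10):
            df, _ = make_powerlaw_dataset(
                individual_sd=0.02 * rep, noise_sd=0.04,
                params=SynthParams(seed=300 + rep))
            f = fit_powerlaw_mixed(df, "N_A_per_um2")
            assert f.r2_marginal <= f.r2_conditional <= 1.0 + 1e-9

    def test_between_variance_recovered_over_replicates(self):
        truth_var = 0.12**2
        est = []
        for rep in range(20):
            df, _ = make_powerlaw_dataset(
                individual_sd=0.12, noise_sd=0.03,
                params=SynthParams(n_individuals=10, seed=700 + rep))
            est.append(fit_powerlaw_mixed(df, "A_A_mm2").sigma2_between)
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - truth_var) <= 3 * se

    def test_zero_between_variance_falls_back_to_pooled_ols(self, caplog):
        df, _ = make_powerlaw_dataset(individual_sd=0.0, noise_sd=0.05,
                                      params=SynthParams(seed=9))
        with caplog.at_level("INFO", logger="frictionpad"):
            f = fit_powerlaw_mixed(df, "A_A_mm2")
        assert f.method == "ols"
        assert f.sigma2_between == 0.0
        # pooled OLS oracle
        slope = np.polyfit(np.log10(df.load_mN), np.log10(df.A_A_mm2), 1)[0]
        assert f.slope == pytest.approx(slope, abs=1e-8)

    def test_nonpositive_response_error_names_rows(self):
        df, _ = make_powerlaw_dataset(params=SynthParams(seed=2))
        df.loc[3, "A_A_mm2"] = 0.0
        with pytest.raises(ValueError, match=r"rows \[3\]"):
            fit_powerlaw_mixed(df, "A_A_mm2")


class TestExponentComposition:
    def test_study_exponents_sum_to_0802(self):
        fits = [_fit_stub(k, se) for k, se in
                [(0.362, 0.023), (0.214, 0.009), (0.226, 0.014)]]
        comp = exponent_composition(*fits)
        assert comp.k_sum == pytest.approx(0.802, abs=1e-12)
        assert comp.near_linear

    def test_zero_exponents_sum_to_zero(self):
        comp = exponent_composition(*[_fit_stub(0.0, 0.0)] * 3)
        assert comp.k_sum == 0.0
        assert not comp.near_linear

    def test_composed_slope_matches_direct_fit_within_2se(self):
        df, _ = make_powerlaw_dataset(params=SynthParams(seed=6))
        fits = {c: fit_powerlaw_mixed(df, c)
                for c in ("A_A_mm2", "N_A_per_um2", "A_Ac_um2", "A_R_um2")}
        comp = exponent_composition(fits["A_A_mm2"], fits["N_A_per_um2"],
                                    fits["A_Ac_um2"])
        direct = fits["A_R_um2"]
        tol = 2 * max(comp.k_sum_se, direct.slope_se)
        assert abs(comp.k_sum - direct.slope) <= tol


def _fit_stub(slope, se):
    from frictionpad.scalestats import PowerLawFit

    return PowerLawFit(intercept=0.0, intercept_se=0.0, slope=slope,
                       slope_se=se, r2_conditional=1.0, r2_marginal=1.0,
                       sigma2_between=0.0, sigma2_residual=0.0,
                       n_individuals=10, n_obs=50, method="stub")


class TestFriedman:
    def test_identical_conditions_give_zero_statistic(self):
        m = np.tile([[1.0, 1.0, 1.0]], (5, 1)) * np.arange(1, 6)[:, None]
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_rank_sum_oracle_on_small_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            m = rng.integers(0, 4, (4, 3)).astype(float)  # many ties
            ours = friedman_test(m)
            # independent tie-robust formulation (Conover): rank sums over
            # the total squared rank deviation
            r = np.apply_along_axis(stats.rankdata, 1, m)
            Rj = r.sum(axis=0)
            n, k = m.shape
            A1 = float((r**2).sum())
            C1 = n * k * (k + 1) ** 2 / 4.0
            if A1 == C1:
                assert ours.statistic == 0.0
                continue
            T1 = (k - 1) * float(((Rj - n * (k + 1) / 2) ** 2).sum()) / (A1 - C1)
            assert ours.statistic == pytest.approx(T1, abs=1e-9)
            assert ours.df == 2

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(10, 3))
        ours = friedman_test(m)
        ref = stats.friedmanchisquare(*m.T)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.pvalue == pytest.approx(ref.pvalue)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(5, 4))
        base = friedman_test(m).statistic
        assert friedman_test(np.exp(m)).statistic == pytest.approx(base)
        assert friedman_test(3 * m + 7).statistic == pytest.approx(base)

    def test_missing_cells_rejected(self):
        m = np.ones((3, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_test(m)


class TestEffectSize:
    @staticmethod
    def _dataset(beta, var_between, var_noise, seed):
        rng = np.random.default_rng(seed)
        loads = np.array([0.2, 0.5, 1.0, 2.0, 4.0])
        rows = []
        for i in range(10):
            a_i = rng.normal(0, np.sqrt(var_between))
            for load in loads:
                rows.append({"individual_id": f"i{i}", "load_mN": load,
                             "y": beta * load + a_i
                             + rng.normal(0, np.sqrt(var_noise))})
        return pd.DataFrame(rows)

    def test_load_independent_response_has_near_zero_eta2(self):
        df = self._dataset(0.0, 0.3, 0.2, seed=0)
        res = rm_effect_size(df, "y", n_boot=200)
        assert res.eta_squared < 0.1

    def test_constructed_variance_share_is_recovered(self):
        # closed-form oracle: choose beta so the expected load sum of
        # squares is half the expected total.  With 10 individuals at the
        # 5 study loads, E[SS_load] = b^2 Sxx + v_e,
        # E[SS_total] = b^2 Sxx + 5*9*v_a + 49*v_e.
        loads = np.array([0.2, 0.5, 1.0, 2.0, 4.0])
        sxx = 10 * np.sum((loads - loads.mean()) ** 2)
        v_a, v_e = 0.3, 0.2
        beta = np.sqrt((0.5 * (45 * v_a + 49 * v_e) - v_e) / (0.5 * sxx))
        etas = [rm_effect_size(self._dataset(beta, v_a, v_e, seed=s), "y",
                               n_boot=50).eta_squared for s in range(20)]
        assert np.mean(etas) == pytest.approx(0.5, abs=0.05)

    def test_report_shape_and_dfs_match_the_design(self):
        df = self._dataset(0.5, 0.3, 0.2, seed=3)
        res = rm_effect_size(df, "y", n_boot=200, seed=1)
        assert (res.df1, res.df2) == (1, 39)  # 50 obs - 10 blocks - 1
        assert res.ci_low <= res.eta_squared <= res.ci_high

    def test_unbalanced_design_rejected(self):
        df = self._dataset(0.5, 0.3, 0.2, seed=4).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_effect_size(df, "y")


class TestSummaryConventions:
    def test_constant_sample_has_zero_margin(self):
        mean, margin = mean_t_ci([2.0] * 10)
        assert (mean, margin) == (2.0, 0.0)

    def test_margin_uses_t_multiplier_for_n10(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=10)
        _, margin = mean_t_ci(v)
        # tabulated t multiplier for 9 degrees of freedom
        assert margin / (v.std(ddof=1) / np.sqrt(10)) == pytest.approx(
            2.2621571628, abs=1e-8)
        expected = stats.t.ppf(0.975, 9) * v.std(ddof=1) / np.sqrt(10)
        assert margin == pytest.approx(expected, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mean_t_ci([1.0])

    @pytest.mark.parametrize("values,expected", [
        ([1, 1, 1], (1.0, 0.0)),
        ([1, 2, 3, 4, 100], (3.0, 1.0)),
    ])
    def test_median_mad_hand_computed(self, values, expected):
        assert median_mad(values) == expected

    def test_median_mad_even_n_matches_brute_force(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=8)
        med, mad = median_mad(v)
        sv = np.sort(v)
        med_bf = (sv[3] + sv[4]) / 2
        dev = np.sort(np.abs(v - med_bf))
        assert med == pytest.approx(med_bf)
        assert mad == pytest.approx((dev[3] + dev[4]) / 2)

    def test_summary_table_reports_mean_and_margin_per_load(self):
        df, _ = make_powerlaw_dataset(params=SynthParams(seed=7))
        out = summarize_by_load(df)
        assert list(out.load_mN) == [0.2, 0.5, 1.0, 2.0, 4.0]
        assert (out.n == 10).all()
        sub = df[df.load_mN == 1.0]["A_A_mm2"]
        assert out.loc[out.load_mN == 1.0, "A_A_mm2_mean"].iloc[0] == \
            pytest.approx(sub.mean())
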