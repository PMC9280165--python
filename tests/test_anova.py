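"""Sums of squares from sufficient statistics and the split-split-plot
ANOVA strata."""

import numpy as np
import pandas as pd
import pytest

from geitools import (error_ss_from_sd, expand, f_test, factorial_ss,
                      split_split_plot_anova)
from geitools.anova import SSP_SOURCES, SplitSplitPlotAnova, ssp_anova_cube
from geitools.simulate import SspSimSpec, simulate_ssp

from conftest import random_summary


class TestFactorialSS:
    def test_constant_table_all_zero(self):
        summary = random_summary(np.random.default_rng(0))
        summary["mean"] = 7.0
        for term in (["condition"], ["tissue"], ["gene"],
                     ["condition", "tissue"], ["condition", "tissue",
                                               "gene"]):
            assert factorial_ss(summary, term) == pytest.approx(0, abs=1e-9)

    def test_two_by_two_hand_case(self):
        # means [[1,2],[3,4]] over rows x columns, singleton third factor:
        # classical balanced SS weights margin deviations by the other
        # factor's size -> rows 4, columns 1, interaction 0
        summary = pd.DataFrame(
            [(c, t, "G", m, 0.0, 1) for (c, t, m) in
             [(1, "a", 1.0), (1, "b", 2.0), (2, "a", 3.0), (2, "b", 4.0)]],
            columns=["condition", "tissue", "gene", "mean", "sd", "n"])
        assert factorial_ss(summary, ["condition"]) == pytest.approx(4.0)
        assert factorial_ss(summary, ["tissue"]) == pytest.approx(1.0)
        assert factorial_ss(summary, ["condition", "tissue"]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_on_expanded_data(self):
        """Independent oracle: OLS sequential ANOVA on pseudo-replicates."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        summary = random_summary(np.random.default_rng(5), conditions=2,
                                 tissues=3, genes=2, n=4)
        table = expand(summary, seed=1).rename(
            columns={"expression": "y"})
        table["condition"] = table["condition"].astype(str)
        fit = smf.ols(
            "y ~ C(condition) * C(tissue) * C(gene)", data=table).fit()
        anova = sm.stats.anova_lm(fit, typ=1)
        got = {
            ("condition",): anova.loc["C(condition)", "sum_sq"],
            ("tissue",): anova.loc["C(tissue)", "sum_sq"],
            ("gene",): anova.loc["C(gene)", "sum_sq"],
            ("condition", "tissue"):
                anova.loc["C(condition):C(tissue)", "sum_sq"],
            ("condition", "tissue", "gene"):
                anova.loc["C(condition):C(tissue):C(gene)", "sum_sq"],
        }
        for term, want in got.items():
            assert factorial_ss(summary, term) == pytest.approx(
                want, rel=1e-8)

    def test_additivity_to_treatment_ss(self):
        """The seven marginal terms partition the between-cell SS."""
        from itertools import chain, combinations
        summary = random_summary(np.random.default_rng(9))
        terms = list(chain.from_iterable(
            combinations(("condition", "tissue", "gene"), k)
            for k in (1, 2, 3)))
        total_terms = sum(factorial_ss(summary, t) for t in terms)
        cell = summary["mean"].to_numpy()
        n = summary["n"].iloc[0]
        treatment = n * ((cell - cell.mean()) ** 2).sum()
        assert total_terms == pytest.approx(treatment, rel=1e-9)

    def test_unbalanced_rejected(self):
        summary = random_summary(np.random.default_rng(1))
        summary.loc[0, "n"] = 5
        with pytest.raises(ValueError, match="unbalanced"):
            factorial_ss(summary, ["gene"])


class TestErrorSS:
    def test_formula(self):
        summary = pd.DataFrame(
            [(1, "a", "G", 0.0, 2.0, 3), (1, "b", "G", 0.0, 1.0, 4)],
            columns=["condition", "tissue", "gene", "mean", "sd", "n"])
        ss, df = error_ss_from_sd(summary)
        assert ss == pytest.approx(2 * 4 + 3 * 1)
        assert df == 5

    def test_zero_sd(self):
        summary = random_summary(np.random.default_rng(2))
        summary["sd"] = 0.0
        ss, df = error_ss_from_sd(summary)
        assert ss == 0
        assert df == len(summary) * 2


class TestFTest:
    def test_unit_ratio(self):
        f, p = f_test(3.5, 4, 3.5, 10)
        assert f == 1.0
        assert 0 < p < 1

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            f_test(1.0, 3, 0.0, 72)

    def test_upper_tail(self):
        from scipy import stats
        f, p = f_test(10.0, 3, 2.0, 20)
        assert p == pytest.approx(stats.f.sf(5.0, 3, 20))


class TestSplitSplitPlot:
    def test_df_column_matches_design(self):
        """b=6, t=4, s=9, g=4 gives the canonical three-strata df layout."""
        spec = SspSimSpec(b=6, t=4, s=9, g=4, seed=0)
        anova = split_split_plot_anova(simulate_ssp(spec))
        assert list(anova["source"]) == SSP_SOURCES
        assert list(anova["df"]) == [5, 3, 15, 8, 24, 160, 3, 9, 24, 72,
                                     540]
        assert anova["df"].sum() == 6 * 4 * 9 * 4 - 1

    def test_zero_noise_recovers_injected_effect(self):
        """Pure temperature signal lands entirely in the Temperature row."""
        eff = np.array([3.0, -1.0, -1.0, -1.0])
        spec = SspSimSpec(b=3, t=4, s=2, g=2, temp_effects=eff,
                          sigma_main=0, sigma_sub=0, sigma=0, seed=0)
        anova = split_split_plot_anova(simulate_ssp(spec)).set_index(
            "source")
        # SS_temp = b*s*g * sum(eff^2)
        assert anova.loc["Temperature", "ss"] == pytest.approx(
            3 * 2 * 2 * (eff ** 2).sum())
        others = anova.drop("Temperature")
        assert np.allclose(others["ss"], 0, atol=1e-18)

    def test_ss_decomposition_and_nonnegativity(self, rng):
        spec = SspSimSpec(b=3, t=3, s=4, g=2, sigma_main=2.0,
                          sigma_sub=1.0, sigma=0.5, seed=42,
                          temp_effects=[1.0, 0.0, -1.0])
        table = simulate_ssp(spec)
        anova = split_split_plot_anova(table)
        y = table["expression"].to_numpy()
        assert anova["ss"].sum() == pytest.approx(
            ((y - y.mean()) ** 2).sum(), rel=1e-9)
        assert (anova["ss"] >= 0).all()

    def test_fixed_terms_use_their_stratum(self):
        spec = SspSimSpec(b=3, t=3, s=3, g=3, seed=7)
        anova = split_split_plot_anova(simulate_ssp(spec)).set_index(
            "source")
        assert anova.loc["Temperature", "f"] == pytest.approx(
            anova.loc["Temperature", "ms"] /
            anova.loc["Main-plot error", "ms"])
        assert anova.loc["Tissue", "f"] == pytest.approx(
            anova.loc["Tissue", "ms"] / anova.loc["Sub-plot error", "ms"])
        assert anova.loc["Gene", "f"] == pytest.approx(
            anova.loc["Gene", "ms"] /
            anova.loc["Sub-sub-plot error", "ms"])
        assert np.isnan(anova.loc["Blocks", "f"])

    def test_missing_cells_listed(self):
        spec = SspSimSpec(b=2, t=2, s=2, g=2, seed=0)
        table = simulate_ssp(spec).iloc[:-3]
        with pytest.raises(ValueError, match="missing cells"):
            split_split_plot_anova(table)

    def test_estimator_params_roundtrip(self):
        est = SplitSplitPlotAnova(value_col="expr")
        assert est.get_params()["value_col"] == "expr"
        est.set_params(value_col="expression")
        assert est.value_col == "expression"

    def test_cube_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            ssp_anova_cube(np.zeros((3, 3, 3)))
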