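import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eelvkit.bias_model import (
    FULL_TERMS,
    bias_frame,
    compare_bias_vs_peep0,
    fit_bias_mixed_model,
    median_split_interaction,
    stepwise_aic,
)
from eelvkit.bias_model import test_bias_zero as bias_zero_pvalue
from eelvkit.errors import DegenerateDataError
from eelvkit.synthetic_cohort import CohortConfig, simulate_cohort


def design_frame(n_animals=14, seed=0):
    config = dataclasses.replace(
        CohortConfig(), n_animals=n_animals, missing_fraction=0.0, seed=seed
    )
    return bias_frame(simulate_cohort(config).table)


class TestMixedModel:
    def test_matches_ols_when_no_between_animal_variance(self):
        # iid noise response: the random-intercept variance collapses to
        # ~0 and the fixed effects coincide with pooled OLS
        frame = design_frame(seed=1)
        rng = np.random.default_rng(1)
        frame["bias"] = rng.normal(0.0, 150.0, len(frame))
        fit = fit_bias_mixed_model(frame, terms=("peep", "vt"))
        assert fit.random_intercept_var < 1.0

        import statsmodels.api as sm

        z = frame.copy()
        for var in ("peep", "vt"):
            z[var] = (z[var] - z[var].mean()) / z[var].std(ddof=0)
        ols = sm.OLS(z["bias"], sm.add_constant(z[["peep", "vt"]])).fit()
        assert fit.params["peep"] == pytest.approx(ols.params["peep"], abs=1e-3)
        assert fit.params["vt"] == pytest.approx(ols.params["vt"], abs=1e-3)

    def test_detects_true_peep_effect(self):
        fit = fit_bias_mixed_model(design_frame(seed=5), terms=("peep",))
        # default generator: bias grows more negative with PEEP
        assert fit.params["peep"] < 0
        assert fit.pvalues["peep"] < 1e-6

    def test_single_animal_rejected(self):
        frame = design_frame(seed=6)
        with pytest.raises(DegenerateDataError):
            fit_bias_mixed_model(frame[frame["animal"] == "pig01"], terms=("peep",))

    def test_aliased_terms_rejected(self):
        frame = design_frame(seed=6)
        frame["vt"] = frame["peep"]  # perfectly collinear
        with pytest.raises(DegenerateDataError, match="aliased|rank"):
            fit_bias_mixed_model(frame, terms=("peep", "vt"))


class TestStepwiseAic:
    def test_path_aics_non_increasing(self):
        path = stepwise_aic(design_frame(seed=7))
        aics = path.aics
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))
        assert path.final.aic <= aics[0]

    def test_marginality_respected_along_path(self):
        path = stepwise_aic(design_frame(seed=8))
        for step in path.steps:
            terms = step["terms"]
            for term in terms:
                factors = term.split(":")
                if len(factors) > 1:
                    # every main effect of a retained interaction is retained
                    for f in factors:
                        assert f in terms

    def test_retains_injected_threeway_signal(self):
        frame = design_frame(n_animals=28, seed=9)
        rng = np.random.default_rng(9)
        z = {
            v: (frame[v] - frame[v].mean()) / frame[v].std(ddof=0)
            for v in ("peep", "vt", "eelv_base")
        }
        frame["bias"] = 60.0 * z["peep"] * z["vt"] * z["eelv_base"] + rng.normal(
            0, 160.0, len(frame)
        )
        path = stepwise_aic(frame)
        assert "peep:vt:eelv_base" in path.final.terms


class TestMedianSplit:
    def test_matches_brute_force_scan_with_printed_cutoffs(self):
        frame = design_frame(seed=10)
        cutoffs = {"vt": 170.0, "peep": 10.0, "eelv_base": 157.0}
        summary = median_split_interaction(frame, cutoffs=cutoffs)
        # brute-force recount of every cell
        for _, row in summary.iterrows():
            values = []
            for _, r in frame.iterrows():
                cls = {
                    v: "high" if r[v] > cutoffs[v] else "low"
                    for v in ("peep", "vt", "eelv_base")
                }
                if (
                    cls["peep"] == row["peep_class"]
                    and cls["vt"] == row["vt_class"]
                    and cls["eelv_base"] == row["eelv_base_class"]
                ):
                    values.append(r["bias"])
            assert row["n"] == len(values)
            assert row["mean_bias_mL"] == pytest.approx(np.mean(values), abs=1e-9)

    def test_identical_rows_fill_single_cell(self):
        frame = pd.DataFrame(
            {
                "animal": ["a"] * 6,
                "peep": 10.0,
                "vt": 170.0,
                "eelv_base": 157.0,
                "bias": np.arange(6.0),
            }
        )
        summary = median_split_interaction(frame)
        assert len(summary) == 1
        assert summary.iloc[0]["n"] == 6

    def test_default_generator_worst_cell_is_high_peep_low_vt_low_base(self):
        summary = median_split_interaction(design_frame(seed=0))
        worst = summary.loc[summary["mean_bias_mL"].idxmin()]
        assert (
            worst["peep_class"],
            worst["vt_class"],
            worst["eelv_base_class"],
        ) == ("high", "low", "low")


class TestDunnettContrasts:
    def test_single_level_reduces_to_two_sample_t(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(
            {
                "animal": ["a"] * 24,
                "vt": 170.0,
                "eelv_base": 200.0,
                "peep": [0.0] * 12 + [10.0] * 12,
                "bias": np.concatenate(
                    [rng.normal(0, 50, 12), rng.normal(-90, 50, 12)]
                ),
            }
        )
        contrast = compare_bias_vs_peep0(frame)[0]
        a = frame.loc[frame["peep"] == 10, "bias"]
        b = frame.loc[frame["peep"] == 0, "bias"]
        t = stats.ttest_ind(a, b)
        ci = t.confidence_interval(0.95)
        assert contrast.estimate == pytest.approx(a.mean() - b.mean(), abs=1e-9)
        assert contrast.ci_low == pytest.approx(ci.low, abs=0.5)
        assert contrast.ci_high == pytest.approx(ci.high, abs=0.5)
        assert contrast.p_adjusted == pytest.approx(t.pvalue, rel=0.15)

    def test_default_generator_significant_only_at_high_peep(self):
        contrasts = compare_bias_vs_peep0(
            simulate_cohort(CohortConfig(seed=1)).table, with_ci=False
        )
        significant = {c.peep for c in contrasts if c.p_adjusted < 0.05}
        assert {12.0, 14.0, 16.0, 18.0, 20.0} <= significant
        assert {2.0, 4.0} & significant == set()

    def test_missing_reference_level_rejected(self):
        frame = design_frame(seed=13)
        with pytest.raises(DegenerateDataError, match="PEEP 0"):
            compare_bias_vs_peep0(frame[frame["peep"] > 0])


class TestBiasZero:
    def test_symmetric_sample_not_significant(self):
        assert bias_zero_pvalue([-30, 30, -20, 20, -10, 10]) > 0.5

    def test_consistently_positive_sample_significant(self):
        assert bias_zero_pvalue(list(range(1, 21))) < 1e-3

    def test_all_zero_convention(self):
        assert bias_zero_pvalue([0.0] * 8) == 1.0

    def test_exact_p_matches_sign_pattern_enumeration(self):
        x = np.array([12.0, -5.0, 8.0, 3.0, -16.0, 7.0])
        p = bias_zero_pvalue(x, method="signed_rank")
        # brute force: the signed-rank null assigns each |x| rank a random
        # sign; enumerate all 2^6 patterns
        ranks = stats.rankdata(np.abs(x))
        w_obs = float(np.sum(ranks[x > 0]))
        total = float(ranks.sum())
        stats_all = []
        for signs in itertools.product([0, 1], repeat=len(x)):
            w = float(np.sum(ranks[np.array(signs, dtype=bool)]))
            stats_all.append(w)
        stats_all = np.array(stats_all)
        # two-sided: fold around the mean of the null distribution
        center = total / 2.0
        p_brute = float(np.mean(np.abs(stats_all - center) >= abs(w_obs - center)))
        assert p == pytest.approx(p_brute, abs=1e-12)

    def test_mann_whitney_variant_runs(self):
        p = bias_zero_pvalue([-200, -150, -120, -90, -60, -30, 10], method="mann_whitney")
        assert 0.0 < p < 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            bias_zero_pvalue([1.0, 2.0])
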