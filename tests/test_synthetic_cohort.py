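import dataclasses

import numpy as np
import pytest

from eelvkit import agreement, trending
from eelvkit.errors import ConfigError, DomainError
from eelvkit.study_data import paired_series
from eelvkit.synthetic_cohort import (
    BiasParams,
    CohortConfig,
    RecruitmentParams,
    apply_bias,
    config_from_dict,
    draw_animal,
    expected_paired_rows,
    recruitment_curve,
    simulate_cohort,
    table_to_csv_bytes,
)


class TestConfig:
    def test_default_config_valid(self):
        CohortConfig().validate()

    def test_invalid_fields_listed(self):
        bad = CohortConfig(n_animals=0, missing_fraction=1.5, noise_sd_ct=-1)
        with pytest.raises(ConfigError) as err:
            bad.validate()
        msg = str(err.value)
        assert "n_animals" in msg and "missing_fraction" in msg and "noise_sd_ct" in msg

    def test_odd_peep_level_rejected(self):
        with pytest.raises(ConfigError, match="peep_schedule"):
            CohortConfig(peep_schedule=(20, 15, 10)).validate()

    def test_config_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ConfigError, match="typo_field"):
            config_from_dict({"typo_field": 3})

    def test_config_round_trip_yaml(self, tmp_path):
        import yaml

        path = tmp_path / "c.yaml"
        path.write_text(
            yaml.safe_dump(
                {"n_animals": 5, "seed": 9, "bias": {"intercept": 10.0, "slope": 0.0}}
            )
        )
        from eelvkit.synthetic_cohort import config_from_yaml

        config = config_from_yaml(path)
        assert config.n_animals == 5 and config.bias.intercept == 10.0


class TestRecruitmentCurve:
    def test_anchored_at_baseline(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            animal = draw_animal(CohortConfig(), rng)
            assert recruitment_curve(0.0, animal) == pytest.approx(
                animal.baseline, abs=1e-9
            )
            assert recruitment_curve(20.0, animal) == pytest.approx(
                animal.peep20, abs=1e-9
            )

    def test_monotone_in_peep(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(0, 20, 41)
        for _ in range(50):
            animal = draw_animal(CohortConfig(), rng)
            values = recruitment_curve(grid, animal)
            assert np.all(np.diff(values) >= -1e-9)

    def test_negative_peep_rejected(self):
        animal = draw_animal(CohortConfig(), np.random.default_rng(2))
        with pytest.raises(DomainError):
            recruitment_curve(-1.0, animal)


class TestApplyBias:
    def test_constant_bias_degenerate_case(self):
        params = BiasParams(intercept=-54.0, slope=0.0, peep_gain=0.0, animal_sd=0.0)
        rng = np.random.default_rng(0)
        out = apply_bias(500.0, 10.0, 168.0, 300.0, params, rng, noise_sd=0.0)
        assert out == pytest.approx(500.0 - 54.0, abs=1e-12)

    def test_bias_more_negative_at_high_peep(self):
        params = BiasParams()
        rng = np.random.default_rng(0)
        at20 = apply_bias(800.0, 20.0, 168.0, 150.0, params, rng, noise_sd=0.0)
        at4 = apply_bias(800.0, 4.0, 168.0, 150.0, params, rng, noise_sd=0.0)
        assert at20 < at4

    def test_result_floored_at_zero(self):
        params = BiasParams(intercept=-500.0, slope=0.0, peep_gain=0.0, animal_sd=0.0)
        rng = np.random.default_rng(0)
        assert apply_bias(100.0, 0.0, 168.0, 300.0, params, rng, noise_sd=0.0) == 0.0


class TestSimulateCohort:
    def test_same_seed_gives_byte_identical_csv(self):
        a = simulate_cohort(CohortConfig(seed=7))
        b = simulate_cohort(CohortConfig(seed=7))
        assert table_to_csv_bytes(a.table) == table_to_csv_bytes(b.table)

    def test_different_seed_differs(self):
        a = simulate_cohort(CohortConfig(seed=7))
        b = simulate_cohort(CohortConfig(seed=8))
        assert table_to_csv_bytes(a.table) != table_to_csv_bytes(b.table)

    def test_complete_design_row_count(self, complete_cohort):
        # 14 animals x (1 onset + 10 PEEP steps + 8 V_T levels)
        assert complete_cohort.table.n_records == 14 * 19 == 266
        assert paired_series(complete_cohort.table).n_pairs == 266

    def test_expected_retained_pairs_matches_design(self):
        # masking exempts the 14 onset rows; of the 252 remaining rows a
        # fraction loses one method, leaving 218 paired rows in expectation
        assert expected_paired_rows(CohortConfig()) == pytest.approx(218.0)

    def test_retained_pairs_concentrate_near_expectation(self):
        counts = [
            paired_series(simulate_cohort(CohortConfig(seed=s)).table).n_pairs
            for s in range(40)
        ]
        # per-cohort SD of the binomial masking is ~6 pairs
        assert abs(np.mean(counts) - 218.0) < 3 * 6.2 / np.sqrt(len(counts))

    def test_truth_sidecar_aligns_with_table(self, default_cohort):
        table = default_cohort.table.frame
        truth = default_cohort.truth
        assert len(truth) == len(table)
        assert (truth["animal_id"].to_numpy() == table["animal_id"].to_numpy()).all()
        # measured CT should scatter around the noise-free truth
        both = table["eelv_ct_mL"].notna()
        resid = table.loc[both, "eelv_ct_mL"] - truth.loc[both.to_numpy(), "true_eelv_ct_mL"]
        assert abs(resid.mean()) < 15.0  # noise_sd_ct / sqrt(n) scale

    def test_optimal_peep_rules_all_run(self):
        for rule in ("random", "best_eelv", "best_compliance_proxy", "peep_fio2_table"):
            config = dataclasses.replace(CohortConfig(seed=3), optimal_peep_rule=rule)
            cohort = simulate_cohort(config)
            ladder = cohort.table.frame.query("stage == 'vt_ladder'")
            assert set(ladder["peep_cmH2O"]).issubset(set(range(0, 21)))


@pytest.fixture(scope="module")
def exact_series():
    config = dataclasses.replace(
        CohortConfig(seed=2),
        bias=BiasParams(intercept=0.0, slope=0.0, peep_gain=0.0, animal_sd=0.0),
        noise_sd_ct=0.0,
        noise_sd_wiwo=0.0,
        missing_fraction=0.0,
    )
    return paired_series(simulate_cohort(config).table)


class TestNoiseFreeDegenerateCohort:
    """With all noise and bias parameters at zero the two methods agree
    exactly, so every downstream agreement statistic must be exact."""

    def test_bias_identically_zero(self, exact_series):
        assert np.abs(exact_series.d).max() == 0.0

    def test_agreement_statistics_exact(self, exact_series):
        result = agreement.nonconstant_bias_loa(exact_series)
        assert result.bias_intercept == pytest.approx(0.0, abs=1e-6)
        assert result.bias_slope == pytest.approx(0.0, abs=1e-9)
        assert result.loa_halfwidth == pytest.approx(0.0, abs=1e-5)
        assert result.percentage_error == pytest.approx(0.0, abs=1e-9)

    def test_concordance_perfect(self, exact_series):
        deltas = trending.consecutive_deltas(exact_series)
        assert trending.concordance_rate(deltas) == 100.0


class TestGeneratorCalibration:
    def test_large_cohort_recovers_printed_calibration_line(self):
        """The default bias parameters are calibrated so that regressing
        the test method on the reference over a large cohort reproduces
        the validation study's calibration line (slope 0.58, intercept
        96 mL) and its overall precision (limits of agreement near
        +/-398 mL)."""
        config = dataclasses.replace(CohortConfig(), n_animals=300, seed=97531)
        series = paired_series(simulate_cohort(config).table)
        slope, intercept, r2, *_ = agreement.linear_calibration(series)
        assert slope == pytest.approx(0.58, abs=0.02)
        assert intercept == pytest.approx(96.0, abs=12.0)
        assert 0.5 < r2 < 0.9
        _, constant_loa = agreement.bland_altman(series)
        assert constant_loa == pytest.approx(398.0, rel=0.10)
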