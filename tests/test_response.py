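"""Effect sizes, rank tests, variance partitioning, and responder calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from omihet.quantify import omi_index
from omihet.response import (
    Classification,
    classify_response,
    cohort_summary,
    correlation_map,
    glass_delta,
    multivariate_regression,
    response_report,
    variance_explained,
    variance_partition,
    wilcoxon_rank_sum,
)
from omihet.simulate import (
    CohortSimSpec,
    MixtureComponent,
    TreatmentSpec,
    generate_cell_table,
)


class TestGlassDelta:
    def test_hand_arithmetic(self):
        assert glass_delta([0, 1, 2], [1, 2, 3]) == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        assert glass_delta([4, 5, 6], [4, 5, 6]) == 0.0

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValueError):
            glass_delta([1, 2], [3, 3, 3])

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(0)
        control = rng.normal(0, 1, 500)
        treated = rng.normal(-0.75, 1, 500)
        assert glass_delta(treated, control) == pytest.approx(0.75, abs=0.15)

    def test_antisymmetric_in_shift_direction(self):
        rng = np.random.default_rng(1)
        control = rng.normal(0, 1, 2000)
        up = rng.normal(0.5, 1, 2000)
        down = rng.normal(-0.5, 1, 2000)
        assert glass_delta(down, control) == pytest.approx(
            -glass_delta(up, control), abs=0.1)


class TestWilcoxonRankSum:
    def test_extreme_small_sample_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum(x, x) == 1.0

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        b = rng.normal(2, 1, 100)
        assert wilcoxon_rank_sum(a, b) < 1e-6

    def test_exact_matches_enumeration_at_n3(self):
        """Full enumeration over all C(6,3) rank assignments."""
        a = [0.1, 2.3, 3.1]
        b = [1.7, 4.2, 5.9]
        pooled = np.sort(np.concatenate([a, b]))
        obs_u = sum(1 for x in a for y in b if x > y)
        us = []
        for combo in itertools.combinations(range(6), 3):
            grp_a = pooled[list(combo)]
            grp_b = np.delete(pooled, list(combo))
            us.append(sum(1 for x in grp_a for y in grp_b if x > y))
        us = np.asarray(us)
        mean_u = us.mean()
        p_exact = np.mean(np.abs(us - mean_u) >= abs(obs_u - mean_u) - 1e-12)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(p_exact, abs=1e-12)

    def test_exact_and_asymptotic_agree_without_ties(self):
        from scipy.stats import mannwhitneyu
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 10)
            b = rng.normal(0.5, 1, 10)
            exact = wilcoxon_rank_sum(a, b)  # n <= 10, no ties -> exact path
            approx = mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=True).pvalue
            assert abs(exact - min(approx, 1.0)) < 0.01


class TestClassifyResponse:
    @pytest.mark.parametrize("delta,dwh,expected", [
        (1.9, -0.1, Classification.RESPONDER),
        (0.3, +0.2, Classification.NON_RESPONDER),
        (0.75, -0.05, Classification.RESPONDER),  # inclusive cutoff
        (0.74, -0.05, Classification.NON_RESPONDER),
        (2.0, +0.3, Classification.NON_RESPONDER),  # expanding heterogeneity
        (1.0, 0.0, Classification.INDETERMINATE),
    ])
    def test_rule_table(self, delta, dwh, expected):
        assert classify_response(delta, 1.0, 1.0 + dwh) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_response(np.nan, 1.0, 0.9)


class TestVarianceExplained:
    def test_null_grouping_near_zero(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, 500)
        groups = np.repeat(np.arange(10), 50)
        assert abs(variance_explained(values, groups)) < 5.0

    def test_saturated_fit_is_100(self):
        values = np.repeat([1.0, 2.0, 5.0], 10)
        groups = np.repeat(["a", "b", "c"], 10)
        assert variance_explained(values, groups) == pytest.approx(100.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.arange(10.0), np.zeros(10))

    def test_planted_fraction_recovered(self):
        # the between-organoid variance estimate dominates the sampling error,
        # with relative SD ~ sqrt(2/(n_organoids - 1)); 100 organoids keep
        # one sigma near 2 percentage points
        spec = CohortSimSpec(n_patients=1, organoids_per_patient=100,
                             cells_per_organoid=30,
                             var_organoid=(0.3,) * 3, var_cell=(0.7,) * 3, seed=5)
        table = generate_cell_table(spec)
        pct = variance_explained(table.redox_ratio_raw, table.organoid_id)
        assert pct == pytest.approx(30.0, abs=6.0)

    def test_partition_table_structure(self):
        spec = CohortSimSpec(n_patients=3, organoids_per_patient=4,
                             cells_per_organoid=20, seed=6)
        table = generate_cell_table(spec)
        by_org = variance_partition(table, ["redox_ratio_raw"], level="organoid")
        assert set(by_org.patient_id) == {"P01", "P02", "P03"}
        by_pat = variance_partition(table, ["redox_ratio_raw", "nadph_tau_m"],
                                    level="patient")
        assert len(by_pat) == 2
        assert (by_pat.pct_explained_floored >= 0).all()


class TestCorrelationMap:
    def test_exact_linear_relation(self):
        x = np.arange(20.0)
        table = pd.DataFrame({"x": x, "y": 2 * x + 1})
        r2, partners = correlation_map(table)
        assert r2.loc["x", "y"] == pytest.approx(1.0)
        assert partners["x"] == 1

    def test_structure_symmetric_unit_diagonal(self, rng):
        table = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        r2, _ = correlation_map(table)
        assert np.allclose(r2, r2.T)
        assert np.allclose(np.diag(r2), 1.0)

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("abc"))
        r2, partners = correlation_map(table)
        off = r2.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(off < 0.05)
        assert (partners == 0).all()

    def test_constant_column_reported_missing(self):
        table = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        r2, _ = correlation_map(table)
        assert np.isnan(r2.loc["a", "b"])


class TestMultivariateRegression:
    def test_exact_linear_dependent(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = 1.0 + 2 * X.a - 3 * X.b + 0.5 * X.c
        assert multivariate_regression(y, X) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 5)))
        y = rng.normal(size=200)
        assert abs(multivariate_regression(y, X)) < 0.1

    def test_collinear_columns_named(self, rng):
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=30)})
        with pytest.raises(ValueError, match="a|b"):
            multivariate_regression(rng.normal(size=30), X)


class TestCohortSummary:
    @pytest.mark.parametrize("attempted,successful,expected", [
        (22, 14, 64),
        (24, 13, 54),
        (10, 10, 100),
    ])
    def test_integer_percent(self, attempted, successful, expected):
        assert cohort_summary(attempted, successful)["success_rate_pct"] == expected

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            cohort_summary(0, 0)
        with pytest.raises(ValueError):
            cohort_summary(5, 7)


def _cohort(shift, mixture=None, seed=0, organoid_sd_multiplier=1.0):
    arm = TreatmentSpec("drug", shift=shift, mixture=mixture,
                        organoid_sd_multiplier=organoid_sd_multiplier)
    spec = CohortSimSpec(n_patients=1, organoids_per_patient=6,
                         cells_per_organoid=40, treatments=[arm], seed=seed)
    table = generate_cell_table(spec)
    return omi_index(table)


class TestResponseReport:
    def test_planted_responder_cohort(self):
        d = 1.5 / np.sqrt(3.0)
        cells = _cohort(shift=0.0, mixture=[MixtureComponent(1.0, (-d, -d, d), 0.6)],
                        seed=11, organoid_sd_multiplier=0.3)
        report = response_report(cells)
        assert len(report) == 1
        row = report.iloc[0]
        assert row.glass_delta > 0.75
        assert row.delta_wh < 0
        assert row.classification == Classification.RESPONDER.value
        assert row.wilcoxon_p < 0.001

    def test_planted_weak_shift_non_responder(self):
        d = 0.1 / np.sqrt(3.0)
        cells = _cohort(shift=(-d, -d, d), seed=12)
        report = response_report(cells)
        assert report.iloc[0].glass_delta < 0.75
        assert report.iloc[0].classification == Classification.NON_RESPONDER.value

    def test_mixture_arm_flags_heterogeneous_response(self):
        d = 2.0
        cells = _cohort(shift=0.0, mixture=[
            MixtureComponent(0.5, (-d, -d, d)), MixtureComponent(0.5, 0.0)],
            seed=13)
        report = response_report(cells)
        assert report.iloc[0].delta_wh > 0
        assert report.iloc[0].classification == Classification.NON_RESPONDER.value

    def test_benjamini_hochberg_option(self):
        cells = _cohort(shift=-0.5, seed=14)
        report = response_report(cells, adjust_p=True)
        assert "wilcoxon_p_adj" in report.columns
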