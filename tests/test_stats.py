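import numpy as np
import pytest
from scipy import stats as sps

from perizone.errors import InsufficientDataError
from perizone.stats import (ancova_gradient, between_group_compare, demographics,
                            holm_adjust, normality_gate, within_group_compare)


class TestNormalityGate:
    def test_size_under_the_null(self):
        rng = np.random.default_rng(1)
        hits = sum(normality_gate(rng.normal(size=30)) == "normal"
                   for _ in range(100))
        assert hits >= 90

    def test_power_against_exponential(self):
        rng = np.random.default_rng(2)
        hits = sum(normality_gate(rng.exponential(size=30)) == "non-normal"
                   for _ in range(100))
        assert hits > 90

    def test_constant_is_non_normal(self):
        assert normality_gate(np.full(10, 3.2)) == "non-normal"

    def test_needs_three_values(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])


class TestWithinGroup:
    def test_identical_zones_give_p_one(self):
        x = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        r = within_group_compare(x, x)
        assert r.p_value == 1.0 and r.test_name == "paired t"

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(3)
        iz = rng.normal(0.18, 0.04, 20)
        oz = iz + rng.normal(0.03, 0.05, 20)
        a = within_group_compare(iz, oz)
        b = within_group_compare(oz, iz)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)

    def test_power_under_calibrated_alternative(self):
        # metastasis FA zone statistics: IZ 0.18 +- 0.04, OZ-IZ 0.03 +- 0.05
        rng = np.random.default_rng(4)
        rejected = 0
        for _ in range(500):
            iz = rng.normal(0.18, 0.04, 28)
            oz = iz + rng.normal(0.03, 0.05, 28)
            if within_group_compare(iz, oz).p_value < 0.05:
                rejected += 1
        assert rejected / 500 > 0.5          # far above the 5% null rate

    def test_gated_pipeline_type_one_error(self):
        # normality-gated paired test keeps its nominal size
        rng = np.random.default_rng(5)
        rejections = sum(
            within_group_compare(rng.normal(size=28),
                                 rng.normal(size=28)).p_value < 0.05
            for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            within_group_compare([1, 2], [2, 3])


class TestBetweenGroup:
    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        sig = sum(between_group_compare(rng.normal(size=30),
                                        rng.normal(size=28)).p_value < 0.05
                  for _ in range(1000))
        assert 0.03 <= sig / 1000 <= 0.07

    def test_separated_groups(self):
        rng = np.random.default_rng(7)
        r = between_group_compare(rng.normal(0, 0.01, 20),
                                  rng.normal(5, 0.01, 20))
        assert r.p_value < 1e-3

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=20), rng.normal(0.4, 1, 22)
        r1 = between_group_compare(a, b)
        r2 = between_group_compare(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_cross_checked_against_independent_library(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=25), rng.normal(0.3, 1.2, 27)
        r = between_group_compare(a, b)
        if r.test_name.endswith("t"):
            expect = float(pingouin.ttest(a, b, correction=True)["p_val"].iloc[0])
        else:
            expect = float(pingouin.mwu(a, b)["p_val"].iloc[0])
        assert r.p_value == pytest.approx(expect, abs=1e-6)


class TestAncova:
    def test_group_effect_recovered_volume_ignored(self):
        rng = np.random.default_rng(10)
        n = 30
        grp = np.array(["gbm"] * n + ["met"] * n)
        vol = rng.uniform(5, 50, 2 * n)
        y = np.where(grp == "met", 0.5, 0.0) + rng.normal(0, 0.1, 2 * n)
        r = ancova_gradient(y, grp, vol)
        assert r.p_value < 1e-6
        assert float(r.estimates["vol_p"]) > 0.05

    def test_volume_driven_gradient_not_attributed_to_group(self):
        rng = np.random.default_rng(11)
        sig = 0
        for _ in range(400):
            n = 25
            grp = np.array(["gbm"] * n + ["met"] * n)
            vol = rng.uniform(5, 50, 2 * n)
            y = 0.01 * vol + rng.normal(0, 0.05, 2 * n)
            if ancova_gradient(y, grp, vol).p_value < 0.05:
                sig += 1
        assert sig / 400 <= 0.075

    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(12)
        grp = ["gbm"] * 10 + ["met"] * 10
        y = np.r_[rng.normal(size=10), rng.normal(1, 1, 10)]
        r = ancova_gradient(y, grp, np.full(20, 25.0))
        assert "dropped" in r.note
        assert 0 <= r.p_value <= 1


class TestDemographics:
    def test_published_sex_table(self):
        # GBM 18 m / 12 f vs metastasis 18 m / 10 f
        rng = np.random.default_rng(13)
        res = demographics(rng.normal(64, 10, 30), rng.normal(64, 10, 28),
                           ((18, 12), (18, 10)),
                           rng.uniform(5, 50, 30), rng.uniform(5, 50, 28))
        sex = [r for r in res if r.metric == "sex"][0]
        assert round(sex.p_value, 2) == 0.74

    def test_identical_ages_give_p_one(self):
        ages = np.array([60.0, 64.0, 68.0, 57.0, 71.0, 62.0])
        res = demographics(ages, ages, ((3, 3), (3, 3)), ages, ages)
        age = [r for r in res if r.metric == "age"][0]
        assert age.p_value == pytest.approx(1.0)

    def test_zero_cell_table_agrees_with_exact_test(self):
        table = ((9, 0), (5, 6))
        rng = np.random.default_rng(14)
        res = demographics(rng.normal(size=9), rng.normal(size=11), table,
                           rng.uniform(1, 5, 9), rng.uniform(1, 5, 11))
        sex = [r for r in res if r.metric == "sex"][0]
        _, p_exact = sps.fisher_exact(table)
        assert 0 <= sex.p_value <= 1
        # same conclusion at the 5% level as the exact oracle
        assert (sex.p_value < 0.05) == (p_exact < 0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            demographics([], [1.0], ((1, 1), (1, 1)), [], [1.0])


def test_holm_adjustment_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    p = np.array([0.001, 0.02, 0.04, 0.3, 0.7])
    expect = multipletests(p, method="holm")[1]
    np.testing.assert_allclose(holm_adjust(p), expect, atol=1e-12)
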