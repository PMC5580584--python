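"""Closed-form statistics against hand computations and independent oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from gmrkit.stats import (
    assign_age_group,
    classify_smoking_status,
    icc,
    one_way_anova,
    paired_t,
    pooled_mean,
    spearman_exact_p,
    spearman_rho,
)


class TestSmokingStatus:
    @pytest.mark.parametrize(
        "lifetime,recent,expected",
        [
            (120, True, "current"),
            (120, False, "former"),
            (50, False, "ineligible"),
            (100, True, "ineligible"),  # strictly greater than 100 required
            (101, True, "current"),
        ],
    )
    def test_definitions(self, lifetime, recent, expected):
        assert classify_smoking_status(lifetime, recent) == expected


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age,label",
        [(19, "19-29"), (29, "19-29"), (30, "30-39"), (59, "50-59"), (60, "60+"), (79, "60+")],
    )
    def test_bins(self, age, label):
        assert assign_age_group(age) == label

    def test_below_study_range_rejected(self):
        with pytest.raises(ValueError, match="below"):
            assign_age_group(18)


class TestPooledMean:
    def test_published_group_cells_pool_to_total(self):
        assert pooled_mean([(26.0, 133), (27.5, 126)]) == pytest.approx(26.7, abs=0.05)
        assert pooled_mean([(4.50, 133), (3.79, 126)]) == pytest.approx(4.15, abs=0.005)

    def test_equal_means_pool_to_same(self):
        assert pooled_mean([(3.3, 7), (3.3, 500)]) == pytest.approx(3.3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_mean([])


class TestAnova:
    def test_hand_computed_example(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.name == "F"
        assert res.value == pytest.approx(3.0)  # SSB = 6, SSW = 6, df (2, 6)
        assert res.df == (2, 6)

    def test_identical_groups_give_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.value == pytest.approx(0.0)

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(0.5, 1, size=9)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.value == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_degenerate_zero_within_variance(self):
        res = one_way_anova([[1, 1], [2, 2]])
        assert np.isinf(res.value)
        assert res.p_value == 0.0
        assert res.degenerate

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 20)) for _ in range(rng.integers(2, 6))]
            res = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert res.value == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.value == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_differences(self):
        res = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.value == pytest.approx(2 * np.sqrt(3), rel=1e-12)  # 3.464
        assert res.df == (2,)

    def test_sign_flip_negates_t(self):
        rng = np.random.default_rng(1)
        b, f = rng.normal(size=10), rng.normal(size=10)
        assert paired_t(b, f).value == pytest.approx(-paired_t(f, b).value)

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_t([1.0, 2.0], [2.0, 3.0])
        assert np.isinf(res.value)
        assert res.degenerate

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(3, 40)
            b, f = rng.normal(size=n), rng.normal(0.2, 1, size=n)
            res = paired_t(b, f)
            ref = sps.ttest_rel(f, b)
            assert res.value == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).value == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [5, 4, 3, 2]).value == pytest.approx(-1.0)

    def test_hand_computed_midrank_example(self):
        res = spearman_rho([1, 2, 2, 4], [10, 20, 30, 40])
        assert res.value == pytest.approx(0.949, abs=5e-4)  # 4.5/sqrt(22.5)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(5, 50)
            x = rng.integers(0, 10, size=n).astype(float)  # ties likely
            y = x + rng.normal(0, 3, size=n)
            res = spearman_rho(x, y)
            ref = sps.spearmanr(x, y)
            assert res.value == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_t_approximation_close_to_exact_permutation_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=7)
        y = x + rng.normal(0, 2, size=7)
        approx = spearman_rho(x, y).p_value
        exact = spearman_exact_p(x, y)
        assert approx == pytest.approx(exact, abs=0.06)


def icc_oracle(m: np.ndarray, model: str) -> float:
    """Mean squares via an explicit two-way ANOVA decomposition (independent path)."""
    n, k = m.shape
    grand = m.mean()
    bms = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    jms = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + grand
    ems = (resid**2).sum() / ((n - 1) * (k - 1))
    within = m - m.mean(axis=1, keepdims=True)
    wms = (within**2).sum() / (n * (k - 1))
    if model == "one_way":
        return (bms - wms) / (bms + (k - 1) * wms)
    return (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)


class TestIcc:
    def test_identical_raters_give_one(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc(m, "one_way").value == pytest.approx(1.0)
        assert icc(m, "two_way").value == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(6, 3))
        perm = m[rng.permutation(6)]
        for model in ("one_way", "two_way"):
            assert icc(m, model).value == pytest.approx(icc(perm, model).value)

    def test_4x2_fixture_matches_mean_squares_oracle(self):
        m = np.array([[9.0, 2.0], [1.0, 1.0], [8.0, 7.0], [2.0, 3.0]])
        for model in ("one_way", "two_way"):
            assert icc(m, model).value == pytest.approx(icc_oracle(m, model), abs=1e-12)

    def test_matches_pingouin_on_random_matrix(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        m = rng.normal(10, 3, size=(8, 3)) + rng.normal(0, 1, size=(8, 1))
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc(m, "one_way").value == pytest.approx(
            ref.loc["ICC(1,1)", "ICC"], abs=1e-10
        )
        # pingouin's ICC(A,1) is the two-way random absolute-agreement form
        assert icc(m, "two_way").value == pytest.approx(
            ref.loc["ICC(A,1)", "ICC"], abs=1e-10
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            icc(np.full((4, 2), 3.0), "one_way")
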