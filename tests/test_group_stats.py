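import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from thermocompare.group_stats import (
    chi_square_independence,
    mean_se,
    pearson_correlation,
    pool_sparse_columns,
    two_sample_t,
)


def chi2_direct(table):
    """Independent oracle: explicit margin sums and direct summation."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    out = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            out += (table[i, j] - e) ** 2 / e
    return out


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.value == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 80*800^2/40^4 = 20
        res = chi_square_independence([[30, 10], [10, 30]])
        assert res.value == pytest.approx(20.0)
        assert res.df == 1

    def test_concentrated_vs_uniform(self):
        table = [[40, 0, 0, 0], [10, 10, 10, 10]]
        res = chi_square_independence(table)
        assert res.value == pytest.approx(chi2_direct(table))
        assert res.df == 3

    def test_matches_scipy_without_pooling(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            table = rng.integers(5, 60, size=(2, rng.integers(2, 8)))
            res = chi_square_independence(table, pool=False)
            ref = sps.chi2_contingency(table, correction=False)
            assert res.value == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_sparse_columns_pooled_into_lower_neighbour(self):
        table = np.array([[50.0, 30.0, 2.0], [50.0, 30.0, 1.0]])
        pooled = pool_sparse_columns(table)
        assert pooled.shape == (2, 2)
        assert pooled[:, 1].tolist() == [32.0, 31.0]

    def test_row_swap_and_column_permutation_invariance(self):
        table = np.array([[12, 30, 8, 20], [25, 9, 14, 31]])
        base = chi_square_independence(table).value
        assert chi_square_independence(table[::-1]).value == pytest.approx(base)
        perm = table[:, [2, 0, 3, 1]]
        assert chi_square_independence(perm, pool=False).value == pytest.approx(
            chi_square_independence(table, pool=False).value
        )

    def test_too_few_columns_after_pooling(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            chi_square_independence([[200, 1], [200, 0]])

    def test_empty_row_errors(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [10, 10]])


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.value == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # mean diff 3, pooled variance 1, SE = sqrt(2/3)
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.value == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4

    def test_degenerate_equal_constants(self):
        res = two_sample_t([0.0, 0.0], [0.0, 0.0])
        assert res.value == 0.0

    def test_degenerate_unequal_constants(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(0, 1, size=rng.integers(3, 30))
            y = rng.normal(0.5, 2, size=rng.integers(3, 30))
            res = two_sample_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert res.value == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(1.0, 6.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.value == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(1.0, 6.0)
        assert pearson_correlation(x, -x).value == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.value == pytest.approx(0.8)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_matches_scipy(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(size=15)
            y = 0.4 * x + rng.normal(size=15)
            res = pearson_correlation(x, y)
            ref = sps.pearsonr(x, y)
            assert res.value == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        x=st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True),
        scale=st.floats(0.1, 10),
        shift=st.floats(-50, 50),
    )
    def test_bounds_symmetry_and_affine_invariance(self, x, scale, shift):
        from hypothesis import assume

        x = np.asarray(x)
        assume(np.std(x, ddof=1) > 1e-3)  # numerically healthy spread
        assume(np.std(x * scale + shift, ddof=1) > 1e-6)
        rng = np.random.default_rng(len(x))
        y = x * 0.3 + rng.normal(size=len(x))
        if np.std(y, ddof=1) == 0:
            return
        r = pearson_correlation(x, y).value
        assert -1.0 <= r <= 1.0
        assert pearson_correlation(y, x).value == pytest.approx(r)
        assert pearson_correlation(np.asarray(x) * scale + shift, y).value == pytest.approx(
            r, abs=1e-8
        )


class TestMeanSE:
    def test_example(self):
        mean, se = mean_se([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert se == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-3)

    def test_constant_vector(self):
        assert mean_se([4.0, 4.0, 4.0]) == (4.0, 0.0)

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            mean_se([1.0])
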