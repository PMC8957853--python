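from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytomap.group_stats import (
    interaction_contrast,
    paired_permutation_contrast,
    paired_t_test,
    permutation_contrast,
)


def enumerate_two_sample(values, n1, c_obs, sidedness):
    """Exhaustive relabeling oracle: exceedance fraction over all C(n, n1)
    assignments of n1 observations to group 1."""
    values = np.asarray(values, float)
    n = len(values)
    cs = []
    for g1 in combinations(range(n), n1):
        g1 = list(g1)
        g2 = [i for i in range(n) if i not in g1]
        cs.append(values[g1].mean() - values[g2].mean())
    cs = np.asarray(cs)
    if sidedness == "two":
        hits = np.abs(cs) >= abs(c_obs) - 1e-12
    elif sidedness == "observed":
        hits = cs <= c_obs + 1e-12 if c_obs < 0 else cs >= c_obs - 1e-12
    elif sidedness == "greater":
        hits = cs >= c_obs - 1e-12
    else:
        raise ValueError(sidedness)
    return hits.mean()


class TestPermutationContrast:
    def test_constant_values_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = permutation_contrast([2.0] * 6, [0, 0, 0, 1, 1, 1],
                                       n_iter=100, seed=1)
        assert res.C_obs == 0.0
        assert res.p_value == 1.0
        assert res.degenerate
        assert not res.significant

    def test_label_swap_symmetry(self):
        vals = [1.0, 2.0, 1.0, 2.0]
        a = permutation_contrast(vals, ["a", "a", "b", "b"], n_iter=2000, seed=3)
        b = permutation_contrast(vals, ["b", "b", "a", "a"], n_iter=2000, seed=3)
        assert a.C_obs == pytest.approx(-b.C_obs)
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_contrast([1.0, 2.0], ["a", "a"], n_iter=10)

    @pytest.mark.parametrize("sidedness,expected", [
        ("observed", 1 / 6),
        ("two", 2 / 6),
    ])
    def test_two_vs_two_matches_enumeration(self, sidedness, expected):
        # values (0,0) vs (1,1): 6 relabelings, C_obs = -1 is matched by a
        # single arrangement in the observed direction
        vals = [0.0, 0.0, 1.0, 1.0]
        labs = [0, 0, 1, 1]
        res = permutation_contrast(vals, labs, n_iter=100_000, seed=5,
                                   sidedness=sidedness)
        assert res.C_obs == pytest.approx(-1.0)
        oracle = enumerate_two_sample(vals, 2, res.C_obs, sidedness)
        assert oracle == pytest.approx(expected)
        se = np.sqrt(expected * (1 - expected) / res.n_iter)
        assert abs(res.p_value - expected) < 3 * se + 2 / (res.n_iter + 1)

    def test_three_vs_three_matches_enumeration(self):
        vals = [0.3, 1.1, 2.9, 3.2, 4.8, 7.5]
        labs = ["x"] * 3 + ["y"] * 3
        res = permutation_contrast(vals, labs, n_iter=100_000, seed=6,
                                   sidedness="two")
        oracle = enumerate_two_sample(vals, 3, res.C_obs, "two")
        se = np.sqrt(oracle * (1 - oracle) / res.n_iter)
        assert abs(res.p_value - oracle) < 3 * se + 2 / (res.n_iter + 1)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_seed_determinism(self, seed):
        vals = np.arange(8.0)
        labs = [0, 1] * 4
        a = permutation_contrast(vals, labs, n_iter=500, seed=seed)
        b = permutation_contrast(vals, labs, n_iter=500, seed=seed)
        assert a == b

    def test_add_one_rule(self):
        res = permutation_contrast(np.arange(10.0), [0, 1] * 5,
                                   n_iter=999, seed=8)
        assert res.p_value == pytest.approx(
            (1 + res.exceedance_rank) / (1 + res.n_iter))
        assert 0 < res.p_value <= 1


class TestInteractionContrast:
    def test_identical_hemisphere_values_give_zero_contrast(self):
        left = np.array([1.0, 2.0, 3.0, 4.0])
        right = left.copy()
        with pytest.warns(UserWarning, match="degenerate"):
            res = interaction_contrast(left, right,
                                       ["male", "male", "female", "female"],
                                       n_iter=100, seed=0)
        assert res.C_obs == 0.0

    def test_sex_swap_antisymmetry(self):
        left = np.array([2.0, 3.0, 1.0, 0.5])
        right = np.array([1.0, 1.5, 2.0, 1.0])
        sex = np.array(["male", "male", "female", "female"])
        swapped = np.where(sex == "male", "female", "male")
        a = interaction_contrast(left, right, sex, n_iter=1000, seed=2)
        b = interaction_contrast(left, right, swapped, n_iter=1000, seed=2)
        assert a.C_obs == pytest.approx(-b.C_obs)

    def test_two_vs_two_enumeration(self):
        # within-subject differences (+1,+1) males vs (-1,-1) females:
        # exhaustive sex relabeling gives one-sided exceedance 1/6
        left = np.array([2.0, 2.0, 0.0, 0.0])
        right = np.array([1.0, 1.0, 1.0, 1.0])
        sex = ["male", "male", "female", "female"]
        res = interaction_contrast(left, right, sex, n_iter=100_000, seed=4,
                                   sidedness="observed")
        assert res.C_obs == pytest.approx(2.0)
        oracle = enumerate_two_sample([1.0, 1.0, -1.0, -1.0], 2, 2.0,
                                      "observed")
        assert oracle == pytest.approx(1 / 6)
        se = np.sqrt(oracle * (1 - oracle) / res.n_iter)
        assert abs(res.p_value - oracle) < 3 * se + 2 / (res.n_iter + 1)

    def test_missing_hemisphere_rejected(self):
        with pytest.raises(ValueError):
            interaction_contrast([1.0, np.nan], [1.0, 2.0],
                                 ["male", "female"], n_iter=10)


class TestPairedPermutation:
    def test_sign_flip_null_on_symmetric_data(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=12)
        b = a + rng.normal(scale=0.5, size=12)
        res = paired_permutation_contrast(a, b, n_iter=20_000, seed=3)
        assert res.C_obs == pytest.approx((a - b).mean())
        assert 0 < res.p_value <= 1


class TestPairedTTest:
    def test_equal_samples_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(a, a)

    def test_constant_shift_rejected(self):
        # d = (1,1,1,1): sd of differences is zero, |t| would be infinite
        a = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(a + 1.0, a)

    def test_hand_computed_statistic(self):
        # d = (-3,-1,-2,-2): mean -2, sample sd sqrt(2/3) = 0.8165,
        # t = -2 / (0.8165/2) = -4.899, df = 3
        a = np.array([0.0, 0.0, 0.0, 0.0])
        b = np.array([3.0, 1.0, 2.0, 2.0])
        res = paired_t_test(a, b)
        assert res.t == pytest.approx(-4.89898, abs=1e-4)
        assert res.df == 3
        assert res.sided == "two"
        # closed-form two-sided p from the t(3) survival function
        from scipy import stats as sps
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(4.89898, df=3), rel=1e-4)
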