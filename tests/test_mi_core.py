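"""Plug-in information estimates against brute-force joint-table oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitn import (
    CategoricalSeries,
    DiscretizationSpec,
    conditional_entropy,
    conditional_mutual_information,
    discretize_equal_frequency,
    entropy,
    interaction_information,
    joint_entropy,
    joint_variable,
    mutual_information,
)
from mitn.mi_core import EmptyColumnError, LengthMismatchError, NonFiniteValueError

from conftest import series
from oracle_utils import (
    bf_conditional_entropy,
    bf_conditional_mutual_information,
    bf_entropy,
    bf_interaction_information,
    bf_mutual_information,
    random_table,
)


class TestDiscretization:
    def test_median_split_of_distinct_ranks(self):
        spec = DiscretizationSpec(n_bins=2, continuity_threshold=2)
        out = discretize_equal_frequency(np.arange(1, 11), spec)
        assert out.codes.tolist() == [0] * 5 + [1] * 5

    def test_constant_column_is_single_category(self):
        out = discretize_equal_frequency([7.0, 7.0, 7.0])
        assert out.codes.tolist() == [0, 0, 0]
        assert out.n_levels == 1

    def test_quantile_bins_are_near_equal_occupancy(self):
        x = np.random.default_rng(5).standard_normal(100)
        out = discretize_equal_frequency(x, DiscretizationSpec(n_bins=5))
        counts = np.bincount(out.codes)
        assert len(counts) == 5
        assert counts.min() >= 18 and counts.max() <= 22

    def test_few_distinct_values_pass_through_as_categorical(self):
        x = [3.0, 1.0, 3.0, 2.0, 1.0] * 10
        out = discretize_equal_frequency(x, DiscretizationSpec(n_bins=2))
        assert out.n_levels == 3  # untouched by binning

    def test_identical_values_share_a_code(self):
        x = np.repeat(np.arange(30.0), 4)
        out = discretize_equal_frequency(x, DiscretizationSpec(n_bins=7))
        for v in np.unique(x):
            assert len(set(out.codes[x == v])) == 1

    @pytest.mark.parametrize("bad", [[1.0, np.nan], [np.inf, 0.0]])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(NonFiniteValueError):
            discretize_equal_frequency(bad)

    def test_empty_rejected(self):
        with pytest.raises(EmptyColumnError):
            discretize_equal_frequency([])


class TestEntropyExamples:
    @pytest.mark.parametrize(
        "codes, expected",
        [([0, 1], 1.0), ([0, 1, 2, 3], 2.0),
         ([0, 0, 0, 1], -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)))],
    )
    def test_entropy_values(self, codes, expected):
        assert entropy(series(codes)) == pytest.approx(expected, abs=1e-12)

    def test_joint_entropy_special_cases(self):
        x = series([0, 0, 1, 1])
        y = series([0, 1, 0, 1])
        assert joint_entropy([x]) == pytest.approx(entropy(x))
        assert joint_entropy([x, x]) == pytest.approx(entropy(x))
        assert joint_entropy([x, y]) == pytest.approx(2.0)

    def test_conditional_entropy_special_cases(self):
        x = series([0, 0, 1, 1])
        assert conditional_entropy(x, x) == pytest.approx(0.0)
        assert conditional_entropy(x, series([0, 0, 0, 0])) == pytest.approx(entropy(x))
        y = series([0, 1, 1, 1])
        assert conditional_entropy(x, y) == pytest.approx(
            bf_conditional_entropy(x.codes, y.codes), abs=1e-12)

    def test_mutual_information_examples(self):
        x = series([0, 0, 1, 1])
        assert mutual_information(x, x) == pytest.approx(entropy(x))
        assert mutual_information(x, series([0, 1, 0, 1])) == pytest.approx(0.0)
        y = series([0, 1, 1, 1])
        expected = 1.0 + entropy(y) - 1.5  # H(X) + H(Y) - H(X,Y)
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(
            bf_mutual_information(x.codes, y.codes), abs=1e-12)

    def test_cmi_special_cases(self, rng):
        x, y, _ = random_table(rng)
        const = np.zeros(len(x), dtype=int)
        assert conditional_mutual_information(
            series(x), series(y), series(const)
        ) == pytest.approx(mutual_information(series(x), series(y)), abs=1e-12)
        assert conditional_mutual_information(
            series(x), series(y), series(y)) == pytest.approx(0.0, abs=1e-12)

    def test_interaction_information_examples(self):
        x = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        y = np.array([0, 1, 0, 1, 0, 0, 1, 1])
        const = np.zeros(8, dtype=int)
        assert interaction_information(series(x), series(y), series(const)) \
            == pytest.approx(0.0, abs=1e-12)
        z = series([0, 1, 0, 1])
        assert interaction_information(z, z, z) == pytest.approx(1.0)

    def test_xor_triple_is_minus_one_bit(self):
        # all 8 combinations equally likely, z = x xor y
        x = np.array([0, 0, 1, 1] * 2)
        y = np.array([0, 1, 0, 1] * 2)
        z = x ^ y
        got = interaction_information(series(x), series(y), series(z))
        assert got == pytest.approx(-1.0, abs=1e-12)
        assert got == pytest.approx(bf_interaction_information(x, y, z), abs=1e-12)

    def test_joint_variable_examples(self):
        a = series([0, 0, 1, 1])
        b = series([0, 1, 0, 1])
        jv = joint_variable(a, b)
        assert jv.n_levels == 4
        assert entropy(jv) == pytest.approx(2.0)
        assert joint_variable(series([0, 1]), series([0, 1])).n_levels == 2
        const = series([0, 0, 0, 0])
        same_partition = joint_variable(a, const)
        assert len(np.unique(same_partition.codes)) == len(np.unique(a.codes))

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            mutual_information(series([0, 1]), series([0, 1, 0]))


class TestInformationIdentities:
    """Exact identities of the plug-in estimates on random tables."""

    def test_identities_on_random_tables(self, rng):
        for _ in range(100):
            levels = rng.integers(2, 5)
            x, y, z = (series(c) for c in random_table(rng, n_levels=levels))
            hx, hy = entropy(x), entropy(y)
            hxy = joint_entropy([x, y])
            i_xy = mutual_information(x, y)
            # symmetry and both chain forms
            assert i_xy == pytest.approx(mutual_information(y, x), abs=1e-12)
            assert hxy == pytest.approx(hy + conditional_entropy(x, y), abs=1e-12)
            assert i_xy == pytest.approx(hx - conditional_entropy(x, y), abs=1e-12)
            assert i_xy == pytest.approx(hy - conditional_entropy(y, x), abs=1e-12)
            # bounds
            assert 0.0 <= i_xy <= min(hx, hy) + 1e-12
            assert 0.0 <= hx <= np.log2(x.n_levels) + 1e-12
            # grouping identity behind the conditional-MI definition
            cmi = conditional_mutual_information(x, y, z)
            assert cmi == pytest.approx(
                mutual_information(x, joint_variable(y, z)) - mutual_information(x, z),
                abs=1e-12)
            assert cmi >= -1e-12

    def test_estimators_match_brute_force(self, rng):
        for _ in range(25):
            x, y, z = random_table(rng, n_rows=40, n_levels=4)
            assert entropy(series(x)) == pytest.approx(bf_entropy(x), abs=1e-12)
            assert mutual_information(series(x), series(y)) == pytest.approx(
                bf_mutual_information(x, y), abs=1e-12)
            assert conditional_mutual_information(
                series(x), series(y), series(z)
            ) == pytest.approx(bf_conditional_mutual_information(x, y, z), abs=1e-10)
            assert interaction_information(
                series(x), series(y), series(z)
            ) == pytest.approx(bf_interaction_information(x, y, z), abs=1e-10)

    def test_interaction_information_is_symmetric(self, rng):
        x, y, z = (series(c) for c in random_table(rng))
        vals = {round(interaction_information(a, b, c), 10)
                for (a, b, c) in [(x, y, z), (y, z, x), (z, x, y), (y, x, z)]}
        assert len(vals) == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=40))
    def test_entropy_bounds_hold_for_any_codes(self, codes):
        s = series(codes)
        h = entropy(s)
        assert -1e-12 <= h <= np.log2(max(s.n_levels, 1)) + 1e-12
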