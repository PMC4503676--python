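"""C-score, the fixed-rows/equiprobable-columns null and the inclusion
filters, checked against brute-force and exhaustive-enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from antgrad import (
    CScoreNullModel,
    OccupancyMatrix,
    apply_inclusion_filters,
    c_score,
    checkerboard_units,
    enumerate_null_distribution,
    null_model_test,
    randomize_fixed_equiprobable,
)


def _mat(values, bait_plot=None):
    values = np.asarray(values)
    return OccupancyMatrix(
        [f"sp{i + 1}" for i in range(values.shape[0])],
        [f"b{j + 1}" for j in range(values.shape[1])],
        values,
        bait_plot,
    )


def _brute_force_checkerboards(row_i, row_j):
    """Direct count of bait pairs {k, l} with species i exclusively at k
    and species j exclusively at l (each unordered pair counted once)."""
    count = 0
    for k, l in itertools.permutations(range(len(row_i)), 2):
        if row_i[k] and not row_j[k] and row_j[l] and not row_i[l]:
            count += 1
    return count


class TestCheckerboardUnits:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([[1, 0, 1], [0, 1, 0]], 2),  # A {1,3}, B {2}: pairs (1,2),(3,2)
            ([[1, 1], [1, 1]], 0),  # full overlap, r_i = S_ij
            ([[1, 0], [0, 1]], 1),  # perfect 2x2 checkerboard
        ],
    )
    def test_formula_on_worked_examples(self, values, expected):
        assert checkerboard_units(_mat(values), "sp1", "sp2") == expected

    def test_unknown_species_raises(self):
        with pytest.raises(KeyError):
            checkerboard_units(_mat([[1, 0], [0, 1]]), "sp1", "ghost")

    @given(
        arrays(np.int8, st.tuples(st.integers(2, 4), st.integers(2, 6)),
               elements=st.integers(0, 1))
    )
    @settings(max_examples=150)
    def test_formula_equals_enumeration(self, values):
        """(r_i − S_ij)(r_j − S_ij) equals brute-force counting of
        checkerboard bait pairs for every matrix up to 4 x 6."""
        mat = _mat(values)
        for i, j in itertools.combinations(range(values.shape[0]), 2):
            assert checkerboard_units(mat, f"sp{i + 1}", f"sp{j + 1}") == \
                _brute_force_checkerboards(values[i], values[j])


class TestCScore:
    def test_single_pair(self, checkerboard_2x3):
        assert c_score(checkerboard_2x3) == 1.0

    def test_three_disjoint_singletons(self):
        assert c_score(_mat(np.eye(3, dtype=int))) == 1.0

    def test_full_rows_contribute_zero(self):
        assert c_score(_mat([[1, 1, 1], [1, 1, 1]])) == 0.0

    def test_needs_two_species(self):
        with pytest.raises(ValueError, match="two species"):
            c_score(_mat([[1, 0, 1]]))


class TestRandomization:
    def test_row_sums_always_preserved(self, rng):
        mat = _mat(rng.integers(0, 2, size=(5, 12)))
        for _ in range(50):
            rand = randomize_fixed_equiprobable(mat, rng)
            assert rand.row_totals().tolist() == mat.row_totals().tolist()
            assert rand.species == mat.species and rand.baits == mat.baits

    def test_full_row_returned_unchanged(self, rng):
        mat = _mat([[1, 1, 1], [1, 0, 0]])
        rand = randomize_fixed_equiprobable(mat, rng)
        assert rand.values[0].tolist() == [1, 1, 1]

    def test_columns_equiprobable(self, rng):
        # 5000 placements of a singleton row over 4 baits: chi-square
        # test of uniformity must not reject wildly
        mat = _mat([[1, 0, 0, 0], [0, 1, 0, 0]])
        counts = np.zeros(4)
        for _ in range(5000):
            counts += randomize_fixed_equiprobable(mat, rng).values[0]
        freq = counts / 5000
        assert np.all(np.abs(freq - 0.25) < 0.02)


class TestNullModelTest:
    def test_worked_example_against_exhaustive_enumeration(self, checkerboard_2x3):
        """Two singleton species on three baits: enumeration of all nine
        placements gives null mean 2/3 and population sd 0.4714; SES of
        the observed C = 1 is +0.707."""
        mean, sd, values, weights = enumerate_null_distribution([1, 1], 3)
        assert mean == pytest.approx(2 / 3)
        assert sd == pytest.approx(np.sqrt(2) / 3)
        res = null_model_test(
            checkerboard_2x3, n_rand=40_000, rng=np.random.default_rng(0)
        )
        assert res.null_mean == pytest.approx(mean, abs=3 * sd / np.sqrt(40_000))
        assert res.ses == pytest.approx((1 - 2 / 3) / sd, abs=0.02)

    @pytest.mark.parametrize("row_sums,n_baits", [((1, 2), 4), ((2, 2, 3), 5)])
    def test_randomized_null_converges_to_enumeration(self, row_sums, n_baits):
        mean, sd, _, _ = enumerate_null_distribution(row_sums, n_baits)
        rng = np.random.default_rng(11)
        obs = np.zeros((len(row_sums), n_baits), dtype=int)
        for i, r in enumerate(row_sums):
            obs[i, :r] = 1
        res = null_model_test(_mat(obs), n_rand=50_000, rng=rng)
        assert res.null_mean == pytest.approx(mean, abs=3 * sd / np.sqrt(50_000))
        assert res.null_sd == pytest.approx(sd, abs=3 * sd / np.sqrt(2 * 50_000))

    def test_degenerate_null_is_flagged(self):
        res = null_model_test(
            _mat([[1, 1, 1], [1, 1, 1]]), n_rand=100, rng=np.random.default_rng(0)
        )
        assert res.degenerate
        assert np.isnan(res.ses)
        assert res.p_upper == 1.0 and res.p_lower == 1.0

    def test_add_one_p_values_bounded_away_from_zero(self, checkerboard_2x3):
        res = null_model_test(
            checkerboard_2x3, n_rand=99, rng=np.random.default_rng(1)
        )
        assert res.p_upper >= 1 / 100 and res.p_lower >= 1 / 100
        assert 0 < res.p_upper <= 1 and 0 < res.p_lower <= 1

    def test_segregated_matrices_score_higher_than_null_ones(self):
        """Power direction: generator segregation < 0 shifts the SES
        distribution upward relative to matched independent matrices."""
        from antgrad import MatrixSpec, simulate_occupancy

        def median_ses(seg, seed0):
            out = []
            for s in range(40):
                mat = simulate_occupancy(
                    MatrixSpec.uniform(3, 60, 0.3, segregation=seg, seed=seed0 + s)
                )
                out.append(
                    null_model_test(
                        mat, n_rand=400, rng=np.random.default_rng(seed0 + s)
                    ).ses
                )
            return np.median(out)

        assert median_ses(-0.45, 100) > median_ses(0.0, 500)

    def test_estimator_follows_sklearn_conventions(self, checkerboard_2x3):
        from sklearn.base import clone

        est = CScoreNullModel(n_rand=200, random_state=3)
        assert clone(est).get_params() == est.get_params()
        fitted = est.fit(checkerboard_2x3)
        assert fitted is est
        assert hasattr(est, "ses_") and est.result_.n_rand == 200
        # plain binary arrays are accepted too
        est2 = CScoreNullModel(n_rand=200, random_state=3).fit(
            checkerboard_2x3.values
        )
        assert est2.c_score_ == est.c_score_


class TestInclusionFilters:
    def test_rare_species_dropped(self):
        values = np.zeros((3, 60), dtype=int)
        values[0, :2] = 1   # 3.3% of baits: dropped
        values[1, :10] = 1
        values[2, 5:20] = 1
        out = apply_inclusion_filters(_mat(values))
        assert out.species == ["sp2", "sp3"]

    def test_exactly_five_percent_retained(self):
        values = np.zeros((2, 60), dtype=int)
        values[0, :3] = 1   # exactly 5%: inclusive threshold keeps it
        values[1, :6] = 1
        out = apply_inclusion_filters(_mat(values))
        assert out.species == ["sp1", "sp2"]

    def test_disjoint_plot_occupancy_skips_analysis(self):
        values = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        bait_plot = {"b1": "p1", "b2": "p1", "b3": "p2", "b4": "p2"}
        with pytest.raises(ValueError, match="same plots"):
            apply_inclusion_filters(_mat(values, bait_plot), min_freq=0.05)

    def test_too_few_survivors_skips_analysis(self):
        values = np.zeros((2, 60), dtype=int)
        values[0, :1] = 1
        values[1, :30] = 1
        with pytest.raises(ValueError, match="fewer than two species"):
            apply_inclusion_filters(_mat(values))
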