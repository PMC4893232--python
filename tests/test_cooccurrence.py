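"""C-score, fixed-equiprobable randomization and the null-model verdict.

The exhaustive-enumeration oracle used here is implemented independently of
the package (plain itertools over per-row column subsets) so the Monte Carlo
engine is checked against a second route.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from bloodmeal import (
    NullModelConfig,
    PresenceAbsenceMatrix,
    build_matrix,
    c_score,
    fixed_equiprobable_randomize,
    run_null_model,
)
from bloodmeal import tables
from bloodmeal.errors import DegenerateMatrixError
from bloodmeal.synth import generate_feeding_scenario


def pam(arr):
    arr = np.asarray(arr, dtype=np.uint8)
    return PresenceAbsenceMatrix(
        arr,
        tuple(f"r{i}" for i in range(arr.shape[0])),
        tuple(f"c{j}" for j in range(arr.shape[1])),
    )


# --- independent oracle -----------------------------------------------------

def oracle_c_score(matrix):
    """Checkerboard-unit mean computed pair by pair, no linear algebra."""
    rows = [list(r) for r in matrix]
    total, n_pairs = 0, 0
    for a, b in itertools.combinations(rows, 2):
        shared = sum(1 for x, y in zip(a, b) if x and y)
        total += (sum(a) - shared) * (sum(b) - shared)
        n_pairs += 1
    return total / n_pairs


def oracle_exact_tails(matrix):
    """Exact fixed-equiprobable tails by brute enumeration of row placements."""
    matrix = np.asarray(matrix)
    n_rows, n_cols = matrix.shape
    observed = oracle_c_score(matrix)
    spaces = [
        list(itertools.combinations(range(n_cols), int(matrix[i].sum())))
        for i in range(n_rows)
    ]
    n_le = n_ge = total = 0
    for placement in itertools.product(*spaces):
        m = np.zeros((n_rows, n_cols), dtype=int)
        for i, cols in enumerate(placement):
            m[i, list(cols)] = 1
        c = oracle_c_score(m)
        total += 1
        n_le += c <= observed + 1e-9
        n_ge += c >= observed - 1e-9
    return n_le / total, n_ge / total


# --- c_score ----------------------------------------------------------------

class TestCScore:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            ([[1, 0], [0, 1]], 1.0),
            ([[1, 1], [1, 1]], 0.0),
            ([[1, 1, 0], [0, 1, 1], [1, 0, 1]], 1.0),
        ],
    )
    def test_hand_enumerated_values(self, matrix, expected):
        assert c_score(pam(matrix)) == expected

    def test_matches_pairwise_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = (rng.random((rng.integers(2, 7), rng.integers(2, 7))) < 0.5).astype(int)
            if m.sum() == 0:
                continue
            assert c_score(m) == pytest.approx(oracle_c_score(m))

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(7)
        m = (rng.random((5, 6)) < 0.4).astype(int)
        base = c_score(m)
        for _ in range(10):
            assert c_score(m[rng.permutation(5)][:, rng.permutation(6)]) == pytest.approx(base)


# --- randomization ----------------------------------------------------------

class TestRandomization:
    def test_row_sums_preserved(self):
        rng = np.random.default_rng(3)
        m = pam((np.random.default_rng(0).random((6, 9)) < 0.4).astype(int))
        for _ in range(20):
            r = fixed_equiprobable_randomize(m, rng)
            assert (r.data.sum(axis=1) == m.data.sum(axis=1)).all()

    def test_all_ones_matrix_is_fixed_point(self):
        m = pam(np.ones((3, 4)))
        r = fixed_equiprobable_randomize(m, np.random.default_rng(0))
        assert (r.data == 1).all()

    def test_single_presence_lands_uniformly(self):
        """One presence in a 5-column row: each column should be hit ~1/5 of
        the time (multinomial goodness-of-fit not rejected at alpha=0.01)."""
        m = pam([[1, 0, 0, 0, 0], [1, 1, 1, 1, 1]])  # second row forced
        rng = np.random.default_rng(11)
        hits = np.zeros(5)
        for _ in range(10_000):
            hits += fixed_equiprobable_randomize(m, rng).data[0]
        stat, p = sps.chisquare(hits)
        assert p > 0.01


# --- null model -------------------------------------------------------------

class TestNullModel:
    def test_shared_host_column_is_aggregated(self):
        m = generate_feeding_scenario("aggregated", 6, 6, seed=1)
        res = run_null_model(m, NullModelConfig(seed=5, n_iterations=5000))
        assert res.pattern == "aggregated"
        assert res.p_low < 0.05

    def test_checkerboard_is_segregated(self):
        m = pam([[1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]])
        res = run_null_model(m, NullModelConfig(seed=5, n_iterations=5000))
        assert res.pattern == "segregated"
        # exact upper tail is 18/1296; the MC estimate must sit nearby
        assert res.p_high == pytest.approx(oracle_exact_tails(m.data)[1], abs=0.02)

    def test_all_ones_null_is_degenerate_and_random(self):
        m = pam(np.ones((4, 4)))
        res = run_null_model(m, NullModelConfig(seed=5, n_iterations=200))
        assert res.observed_c_score == 0.0
        assert res.null_variance == 0.0
        assert res.p_low == res.p_high == 1.0
        assert res.pattern == "random"

    def test_same_seed_bit_identical(self):
        m = generate_feeding_scenario("random", 6, 6, seed=4)
        a = run_null_model(m, NullModelConfig(seed=9, n_iterations=500))
        b = run_null_model(m, NullModelConfig(seed=9, n_iterations=500))
        assert a == b

    def test_tails_match_exact_enumeration_on_small_matrices(self):
        """MC tails at n=20000 against the independent exhaustive oracle on a
        sample of 3x3 matrices with row sums <= 2 (full sweep in acceptance)."""
        rng = np.random.default_rng(0)
        for trial in range(12):
            m = np.zeros((3, 3), dtype=int)
            for i in range(3):
                k = int(rng.integers(1, 3))
                m[i, rng.choice(3, size=k, replace=False)] = 1
            exact_low, exact_high = oracle_exact_tails(m)
            res = run_null_model(pam(m), NullModelConfig(seed=100 + trial, n_iterations=20_000))
            assert res.p_low == pytest.approx(exact_low, abs=0.02)
            assert res.p_high == pytest.approx(exact_high, abs=0.02)

    def test_null_mean_invariant_to_column_permutation(self):
        rng = np.random.default_rng(8)
        m = (rng.random((5, 7)) < 0.4).astype(int)
        a = run_null_model(pam(m), NullModelConfig(seed=1, n_iterations=4000))
        b = run_null_model(pam(m[:, rng.permutation(7)]), NullModelConfig(seed=2, n_iterations=4000))
        assert a.null_mean == pytest.approx(b.null_mean, abs=4 * math.sqrt(
            a.null_variance / 4000 + b.null_variance / 4000) + 1e-6)


# --- matrix construction ----------------------------------------------------

class TestBuildMatrix:
    def test_two_disjoint_records_give_identity_matrix(self, taxonomy):
        import datetime as dt

        from bloodmeal.records import BloodMealRecord, SurveyDataset

        recs = [
            BloodMealRecord("a", "Aedes vexans", "Homo sapiens", "human", "s1",
                            dt.date(2014, 6, 1), "EVS", "rural"),
            BloodMealRecord("b", "Culex torrentium", "Turdus merula", "bird", "s2",
                            dt.date(2014, 6, 1), "EVS", "rural"),
        ]
        m = build_matrix(SurveyDataset(recs))
        assert m.shape == (2, 2)
        assert m.data.sum() == 2
        assert (m.data.sum(axis=0) == 1).all() and (m.data.sum(axis=1) == 1).all()

    def test_human_row_spans_18_of_20_named_species(self, survey):
        m = build_matrix(
            survey, rows="host_group", columns="mosquito_taxon",
            column_subset=tables.named_species(),
        )
        human = m.data[m.row_labels.index("human")]
        assert m.shape[1] == 20
        assert human.sum() == 18

    def test_single_site_per_taxon_matrix_is_degenerate(self, taxonomy):
        import datetime as dt

        from bloodmeal.records import BloodMealRecord, SurveyDataset

        recs = [
            BloodMealRecord(f"x{i}", "Ochlerotatus cantans", h, g, "s1",
                            dt.date(2014, 6, 1), "EVS", "rural")
            for i, (h, g) in enumerate(
                [("Homo sapiens", "human"), ("Capreolus capreolus", "non-human mammal")]
            )
        ]
        with pytest.raises(DegenerateMatrixError):
            build_matrix(SurveyDataset(recs), columns="site_id", taxon="Ochlerotatus cantans")

    def test_survey_wide_pattern_is_aggregated(self, survey):
        m = build_matrix(survey)
        res = run_null_model(m, NullModelConfig(seed=1, n_iterations=2000))
        assert res.pattern == "aggregated"
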