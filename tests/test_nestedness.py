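"""NODF metric against a brute-force oracle; matrix generators; ensembles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import phagenet as pn
from phagenet.nestedness import _nodf_array


def nodf_brute(A: np.ndarray) -> float:
    """Direct pairwise implementation of the overlap/decreasing-fill rule."""
    A = np.asarray(A, dtype=float)
    score, pairs = 0.0, 0
    for B in (A, A.T):
        for i, j in itertools.combinations(range(B.shape[0]), 2):
            ki, kj = B[i].sum(), B[j].sum()
            pairs += 1
            if ki != kj and min(ki, kj) > 0:
                score += (B[i] * B[j]).sum() / min(ki, kj)
    return score / pairs if pairs else 0.0


def all_valid_matrices(n_h, n_v, fill):
    """Every binary n_h x n_v matrix with given fill and no empty lines."""
    cells = list(itertools.product(range(n_h), range(n_v)))
    for combo in itertools.combinations(cells, fill):
        A = np.zeros((n_h, n_v), dtype=int)
        for i, j in combo:
            A[i, j] = 1
        if A.sum(axis=1).all() and A.sum(axis=0).all():
            yield A


class TestNodf:
    def test_matches_brute_force_on_small_matrices(self, rng):
        for _ in range(300):
            n_r, n_c = rng.integers(1, 5, size=2)
            A = rng.integers(0, 2, size=(n_r, n_c)).astype(float)
            if not A.any() or (n_r == 1 and n_c == 1):
                continue
            assert _nodf_array(A) == pytest.approx(nodf_brute(A), abs=1e-12)

    def test_maximally_nested_staircase_scores_one(self):
        S = pn.max_nested_matrix(10, 10, 55)
        assert pn.nodf(S) == pytest.approx(1.0, abs=1e-12)

    def test_equal_degree_pairs_contribute_zero(self):
        assert pn.nodf(np.eye(2)) == 0.0
        assert pn.nodf(np.ones((3, 3))) == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pn.nodf(np.zeros((3, 3)))

    @settings(max_examples=150, derandomize=True)
    @given(
        arrays(np.int8, st.tuples(st.integers(1, 5), st.integers(1, 5)), elements=st.integers(0, 1))
    )
    def test_bounded_in_unit_interval_and_matches_oracle(self, A):
        if not A.any() or A.size == 1:
            return
        val = _nodf_array(A.astype(float))
        assert 0.0 <= val <= 1.0
        assert val == pytest.approx(nodf_brute(A), abs=1e-12)

    def test_invariant_under_row_and_column_permutations(self, rng):
        A = pn.random_matrix(6, 5, 14, seed=3).entries.astype(float)
        base = _nodf_array(A)
        for _ in range(10):
            P = A[rng.permutation(6)][:, rng.permutation(5)]
            assert _nodf_array(P) == pytest.approx(base, abs=1e-12)


class TestMaxNested:
    @pytest.mark.parametrize(
        "shape_fill", [(2, 2, 3), (3, 3, 5), (3, 3, 7), (3, 3, 9), (2, 3, 4), (3, 2, 5)]
    )
    def test_attains_exhaustive_maximum_on_small_shapes(self, shape_fill):
        n_h, n_v, fill = shape_fill
        best = max(nodf_brute(A) for A in all_valid_matrices(n_h, n_v, fill))
        ours = pn.nodf(pn.max_nested_matrix(n_h, n_v, fill))
        assert ours == pytest.approx(best, abs=1e-12)

    def test_forced_shapes(self):
        M = pn.max_nested_matrix(2, 2, 3)
        assert sorted(M.entries.sum(axis=1).tolist()) == [1, 2]
        assert pn.max_nested_matrix(3, 3, 9).entries.sum() == 9

    def test_infeasible_fill_rejected(self):
        with pytest.raises(ValueError):
            pn.max_nested_matrix(3, 3, 2)
        with pytest.raises(ValueError):
            pn.max_nested_matrix(3, 3, 10)

    def test_upper_bounds_ensemble_matrices(self, ensemble20):
        bound = pn.nodf(pn.max_nested_matrix(10, 10, 20))
        assert (ensemble20.nodf_values <= bound + 1e-9).all()


class TestModular:
    def test_five_blocks_of_two(self):
        M = pn.modular_matrix(10, 10, 5)
        assert M.n_interactions == 20
        blocks = [M.entries[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] for k in range(5)]
        assert all((b == 1).all() for b in blocks)
        assert pn.nodf(M) < 0.4

    def test_two_blocks_of_two(self):
        M = pn.modular_matrix(4, 4, 2)
        assert M.n_interactions == 8

    def test_too_many_modules_rejected(self):
        with pytest.raises(ValueError):
            pn.modular_matrix(4, 4, 5)


class TestEnsemble:
    def test_spectrum_properties(self, ensemble20):
        v = ensemble20.nodf_values
        assert (np.diff(v) >= -1e-15).all()
        assert v[0] < 0.4
        # endpoint reaches the most-nested state achievable at this fill
        assert v[-1] == pytest.approx(pn.nodf(pn.max_nested_matrix(10, 10, 20)), abs=1e-9)

    def test_interaction_count_conserved(self, ensemble20):
        assert {m.n_interactions for m in ensemble20} == {20}

    def test_no_empty_rows_or_columns(self, ensemble20):
        for M in ensemble20:
            assert M.entries.sum(axis=0).all() and M.entries.sum(axis=1).all()

    def test_deterministic_given_seed(self, ensemble20):
        again = pn.nestedness_ensemble(10, 10, 5, 20, seed=0)
        assert all(
            (a.entries == b.entries).all() for a, b in zip(ensemble20, again)
        )

    def test_requires_at_least_two_matrices(self):
        with pytest.raises(ValueError):
            pn.nestedness_ensemble(10, 10, 5, 1, seed=0)


class TestRandomMatrix:
    def test_fill_and_no_empty_lines(self, rng):
        for _ in range(20):
            M = pn.random_matrix(8, 6, 17, seed=rng)
            assert M.n_interactions == 17
            assert M.entries.sum(axis=0).all() and M.entries.sum(axis=1).all()

    def test_distinct_rows_option(self):
        M = pn.random_matrix(10, 10, 20, seed=5, distinct_rows=True)
        assert len({r.tobytes() for r in M.entries}) == 10
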