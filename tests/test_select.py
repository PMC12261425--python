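"""Solver correctness: worked examples, oracle equivalence, invariants."""

import itertools

import numpy as np
import pytest

from falafl import (
    FalaflSelector,
    brute_force_select,
    decision_falafl,
    select,
    x3c_to_falafl,
)
from falafl.select import _ENUM_BOUND


def random_binary_instance(rng, n, m, density):
    return (rng.random((n, m)) < density).astype(np.uint8)


class TestWorkedExamples:
    def test_q_half_selects_everything(self, two_by_three):
        res = select(two_by_three, 0.5)
        assert sorted(res.selected) == [0, 1, 2]
        assert res.objective == 4
        assert res.per_patient_fraction == pytest.approx([2 / 3, 2 / 3])

    def test_q_three_quarters_selects_shared_site(self, two_by_three):
        res = select(two_by_three, 0.75)
        assert list(res.selected) == [0]
        assert res.objective == 2
        assert res.per_patient_fraction == pytest.approx([1.0, 1.0])

    def test_all_ones_selects_all(self):
        S = np.ones((3, 5), dtype=np.uint8)
        for q in (0.0, 0.5, 1.0):
            res = select(S, q)
            assert len(res.selected) == 5
            assert res.objective == 15

    def test_brute_force_agrees_on_worked_examples(self, two_by_three):
        for q in (0.5, 0.75):
            assert (
                brute_force_select(two_by_three, q).objective
                == select(two_by_three, q).objective
            )

    def test_empty_feasible_only(self):
        S = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        with pytest.warns(UserWarning, match="empty selection"):
            res = brute_force_select(S, 1.0)
        assert res.objective == 0 and len(res.selected) == 0
        with pytest.warns(UserWarning, match="empty selection"):
            res = select(S, 1.0)
        assert res.objective == 0 and len(res.selected) == 0

    def test_single_column_of_ones_q1(self):
        res = brute_force_select(np.ones((3, 1), dtype=np.uint8), 1.0)
        assert list(res.selected) == [0]


class TestOracleEquivalence:
    def test_objective_matches_enumeration(self):
        """ILP objective equals exhaustive enumeration on random instances."""
        rng = np.random.default_rng(42)
        cases = 0
        for density in (0.3, 0.5, 0.8):
            for q in (0.5, 0.75, 1.0):
                for _ in range(25):
                    n = rng.integers(2, 6)
                    m = rng.integers(3, 16)
                    S = random_binary_instance(rng, n, m, density)
                    exact = brute_force_select(S, q)
                    solved = select(S, q)
                    assert solved.objective == exact.objective
                    cases += 1
        assert cases >= 200

    def test_feasibility_of_returned_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            S = random_binary_instance(rng, rng.integers(2, 6), rng.integers(3, 16), 0.6)
            q = rng.choice([0.5, 0.75, 0.9])
            res = select(S, q)
            if len(res.selected):
                frac = S[:, res.selected].sum(axis=1) / len(res.selected)
                assert (frac >= q - 1e-9).all()
                np.testing.assert_allclose(frac, res.per_patient_fraction)
                assert res.objective == S[:, res.selected].sum()

    def test_objective_monotone_in_q(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            S = random_binary_instance(rng, 4, 12, 0.5)
            objs = [select(S, q).objective for q in (0.25, 0.5, 0.75, 1.0)]
            assert objs == sorted(objs, reverse=True)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        S = random_binary_instance(rng, 4, 12, 0.5)
        base = select(S, 0.75)
        for _ in range(5):
            perm = rng.permutation(S.shape[1])
            res = select(S[:, perm], 0.75)
            assert res.objective == base.objective
            frac = S[:, perm][:, res.selected].sum(axis=1) / max(len(res.selected), 1)
            if len(res.selected):
                assert (frac >= 0.75 - 1e-9).all()

    def test_compression_matches_uncompressed(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            S = random_binary_instance(rng, 3, 10, 0.5)
            assert (
                select(S, 0.75, compress=True).objective
                == select(S, 0.75, compress=False).objective
            )


class TestValidation:
    def test_rejects_bad_q(self, two_by_three):
        with pytest.raises(ValueError, match="q must be"):
            select(two_by_three, 1.5)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            select(np.array([[0.5, 1.0]]), 0.5)

    def test_brute_force_enumeration_bound(self):
        S = np.ones((2, _ENUM_BOUND + 1), dtype=np.uint8)
        with pytest.raises(ValueError, match="enumeration bound"):
            brute_force_select(S, 0.5)


class TestSelectorEstimator:
    def test_transform_keeps_selected_columns(self, two_by_three):
        sel = FalaflSelector(q=0.75).fit(two_by_three)
        assert sel.objective_ == 2
        assert list(sel.get_support(indices=True)) == [0]
        out = sel.transform(two_by_three)
        assert out.shape == (2, 1)
        np.testing.assert_array_equal(out.ravel(), [1, 1])

    def test_clone_and_params_roundtrip(self, two_by_three):
        from sklearn.base import clone

        sel = FalaflSelector(q=0.5, seed=3)
        params = sel.get_params()
        assert params["q"] == 0.5 and params["seed"] == 3
        clone(sel).fit(two_by_three)


def _x3c_oracle(universe_size, subsets):
    """Direct exact-cover enumeration, independent of the reduction."""
    t = universe_size // 3
    universe = frozenset(range(1, universe_size + 1))
    for combo in itertools.combinations(subsets, t):
        union = frozenset().union(*combo)
        if union == universe and sum(len(s) for s in combo) == universe_size:
            return True
    return False


class TestX3CReduction:
    def test_reduction_examples(self):
        binary, k, ell = x3c_to_falafl(6, [{1, 2, 3}, {4, 5, 6}, {1, 4, 5}])
        assert binary.values.shape == (6, 3) and (k, ell) == (2, 1)
        assert decision_falafl(binary.values, k, ell) is True

        binary, k, ell = x3c_to_falafl(3, [{1, 2, 3}])
        assert binary.values.shape == (3, 1) and k == 1
        assert decision_falafl(binary.values, k, ell) is True

        binary, k, _ = x3c_to_falafl(6, [{1, 2, 3}, {1, 2, 4}])
        assert decision_falafl(binary.values, k, 1) is False

    def test_reduction_agrees_with_exact_cover_oracle(self):
        rng = np.random.default_rng(5)
        agree = 0
        for _ in range(100):
            alpha = int(rng.choice([6, 9, 12]))
            beta = int(rng.integers(2, 7))
            subsets = [
                frozenset(rng.choice(np.arange(1, alpha + 1), 3, replace=False).tolist())
                for _ in range(beta)
            ]
            binary, k, ell = x3c_to_falafl(alpha, subsets)
            assert decision_falafl(binary.values, k, ell) == _x3c_oracle(alpha, subsets)
            agree += 1
        assert agree == 100

    def test_malformed_subsets_rejected(self):
        with pytest.raises(ValueError, match="exactly 3"):
            x3c_to_falafl(6, [{1, 2}])
        with pytest.raises(ValueError, match="multiple of 3"):
            x3c_to_falafl(7, [{1, 2, 3}])
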