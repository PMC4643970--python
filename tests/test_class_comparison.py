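"""Class-comparison engine: t statistics, permutation p, BH, Korn step-down."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pantcl.class_comparison import (
    DECriteria,
    bh_qvalues,
    fold_change,
    korn_stepdown,
    permutation_test,
)
from tests.conftest import two_group_matrix

positive_floats = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestFoldChange:
    def test_sign_convention_examples(self):
        assert fold_change([10.0], [381.7]) == pytest.approx(38.17)
        assert fold_change([8.0], [2.0]) == pytest.approx(-4.0)
        assert fold_change([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1.0, 0.0], [2.0])

    @given(
        h=st.lists(positive_floats, min_size=1, max_size=6),
        m=st.lists(positive_floats, min_size=1, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_magnitude_at_least_one_and_antisymmetric(self, h, m):
        fc = fold_change(h, m)
        assert abs(fc) >= 1.0
        flipped = fold_change(m, h)
        if fc != 1.0:
            assert flipped == pytest.approx(-fc, rel=1e-9)


class TestPermutationTest:
    def test_exhaustive_enumeration_two_sided_p(self):
        """3-vs-3 separation enumerates C(6,3)=20 assignments -> p = 2/20."""
        m, lab = two_group_matrix({"g": [2, 4, 8, 1024, 2048, 4096]}, 3)
        r = permutation_test(m, lab, DECriteria(n_permutations=1000), seed=0, reference="g1")
        assert r.exhaustive
        assert r.table.loc["g", "p_perm"] == pytest.approx(0.1)

    def test_identical_gene_has_p_one(self):
        m, lab = two_group_matrix({"g": [3, 5, 7, 3, 5, 7], "h": [1, 1, 1, 1, 1, 1]}, 3)
        r = permutation_test(m, lab, DECriteria(n_permutations=50), seed=0)
        assert r.table.loc["g", "p_perm"] == 1.0
        assert r.table.loc["h", "p_perm"] == 1.0
        assert bool(r.table.loc["h", "constant"])
        assert r.table.loc["h", "t"] == 0.0

    def test_label_swap_flips_t_and_keeps_p(self, rng):
        values = {f"g{i}": rng.uniform(1, 100, 8).tolist() for i in range(5)}
        m, lab = two_group_matrix(values, 4)
        a = permutation_test(m, lab, DECriteria(n_permutations=100), seed=1, reference="g1")
        b = permutation_test(m, lab, DECriteria(n_permutations=100), seed=1, reference="g2")
        assert a.exhaustive and b.exhaustive
        np.testing.assert_allclose(a.table["t"], -b.table["t"], rtol=1e-10)
        np.testing.assert_allclose(a.table["p_perm"], b.table["p_perm"], rtol=1e-12)
        np.testing.assert_allclose(
            a.table["fold_change"],
            np.where(b.table["fold_change"] == 1.0, 1.0, -b.table["fold_change"]),
            rtol=1e-10,
        )

    def test_small_class_rejected(self):
        m, lab = two_group_matrix({"g": [1, 2, 3, 4]}, 1)
        with pytest.raises(ValueError):
            permutation_test(m, lab, DECriteria(n_permutations=10))

    def test_p_floor_is_one_over_b_plus_one(self, rng):
        g1 = rng.uniform(1, 2, 10)
        g2 = rng.uniform(1000, 2000, 10)
        m, lab = two_group_matrix({"g": np.concatenate([g1, g2]).tolist()}, 10)
        r = permutation_test(m, lab, DECriteria(n_permutations=999), seed=2)
        assert not r.exhaustive
        assert r.table.loc["g", "p_perm"] == pytest.approx(1.0 / 1000.0)

    def test_welch_mode_runs_and_differs(self, rng):
        # unequal group sizes: Welch and pooled t coincide only at n1 == n2
        values = {f"g{i}": rng.uniform(1, 50, 10).tolist() for i in range(4)}
        m, lab = two_group_matrix(values, 4)
        a = permutation_test(m, lab, DECriteria(n_permutations=200), seed=3)
        b = permutation_test(m, lab, DECriteria(n_permutations=200, equal_var=False), seed=3)
        assert not np.allclose(a.table["t"], b.table["t"])


class TestBenjaminiHochberg:
    def test_matches_direct_stepup_oracle(self, rng):
        p = rng.uniform(0, 1, 200)
        q = bh_qvalues(p)
        # independent naive implementation
        order = np.argsort(p)
        m = len(p)
        raw = p[order] * m / np.arange(1, m + 1)
        mono = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(mono, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_never_below_p(self, rng):
        p = rng.uniform(0, 1, 50)
        assert (bh_qvalues(p) >= p - 1e-12).all()


class TestKornStepdown:
    def test_single_extreme_gene_rejected(self):
        t_obs = np.array([10.0])
        t_perm = np.random.default_rng(0).normal(0, 1, (500, 1))
        assert korn_stepdown(t_obs, t_perm, gamma=0.1, confidence=0.99).tolist() == [True]

    def test_unseparated_gene_not_rejected(self):
        rng = np.random.default_rng(1)
        t_obs = np.array([0.5])
        t_perm = rng.normal(0, 1, (500, 1))
        assert korn_stepdown(t_obs, t_perm, gamma=0.1, confidence=0.99).tolist() == [False]

    def test_global_null_any_rejection_rate_controlled(self):
        """With u(r)=0 the step-down behaves like FWER control at 1 - confidence."""
        any_rejection = 0
        n_rep = 150
        for s in range(n_rep):
            rng = np.random.default_rng(10_000 + s)
            x = rng.normal(0, 1, (200, 24))
            m = pd.DataFrame(2.0**x, index=[f"g{i}" for i in range(200)],
                             columns=[f"s{i}" for i in range(24)])
            lab = pd.Series(["a"] * 12 + ["b"] * 12, index=m.columns)
            r = permutation_test(
                m, lab, DECriteria(n_permutations=300, mode="korn"), seed=s
            )
            any_rejection += r.table["korn_pass"].any()
        rate = any_rejection / n_rep
        se = np.sqrt(0.01 * 0.99 / n_rep)
        assert rate <= 0.01 + 3 * se

    @pytest.mark.parametrize("gamma,conf", [(0.0, 0.9), (1.0, 0.9), (0.1, 0.0), (0.1, 1.0)])
    def test_invalid_parameters_rejected(self, gamma, conf):
        with pytest.raises(ValueError):
            korn_stepdown(np.array([1.0]), np.zeros((10, 1)), gamma=gamma, confidence=conf)


class TestCriteria:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha_p": 0.0},
            {"alpha_fdr": 1.5},
            {"n_permutations": 0},
            {"mode": "bogus"},
        ],
    )
    def test_invalid_criteria(self, kwargs):
        with pytest.raises(ValueError):
            DECriteria(**kwargs).validate()
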