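"""Dissimilarity index and allocation model: worked values and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idiseg.core import (
    AllocationModel,
    CutoffError,
    SegregationError,
    city_dissimilarity,
    conditional_population_dissimilarity,
    cumulate_brackets,
    dissimilarity_index,
    estimate_allocation,
    log_likelihood,
    population_dissimilarity,
)

from conftest import make_table


class TestCumulateBrackets:
    @pytest.mark.parametrize(
        "mode,expected",
        [("complement", (8, 2)), ("total", (8, 10))],
    )
    def test_worked_example(self, mode, expected):
        table = make_table(
            [[5, 3, 2]], brackets=((0.0, 1.0), (1.0, 2.0), (2.0, 3.0))
        )
        minority, reference = cumulate_brackets(table, 2.0, mode)
        assert (minority[0], reference[0]) == expected

    def test_invalid_cutoff_lists_boundaries(self):
        table = make_table(
            [[5, 3, 2]], brackets=((0.0, 1.0), (1.0, 2.0), (2.0, 3.0))
        )
        with pytest.raises(CutoffError) as exc:
            cumulate_brackets(table, 1.5)
        assert exc.value.boundaries == (1.0, 2.0, 3.0)

    def test_counts_conserved_and_nested(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.integers(0, 50, size=(6, 5)))
        prev = np.zeros(6)
        for cutoff in (0.5, 1.0, 2.0, 3.0):
            minority, reference = cumulate_brackets(table, cutoff)
            assert ((minority + reference) == table.totals).all()
            assert (minority >= prev).all()  # nested minority groups
            prev = minority


class TestDissimilarityIndex:
    def test_hand_computed_value(self):
        d = dissimilarity_index(np.array([10, 30]), np.array([40, 20]))
        assert d == pytest.approx(0.41667, abs=5e-6)

    def test_equal_proportions_give_zero(self):
        assert dissimilarity_index(np.array([7, 7]), np.array([3, 3])) == 0.0

    def test_complete_segregation_gives_one(self):
        assert dissimilarity_index(np.array([10, 0]), np.array([0, 40])) == 1.0

    @pytest.mark.parametrize("bad", [np.array([0, 0]), np.array([-1, 5])])
    def test_rejects_zero_total_and_negatives(self, bad):
        with pytest.raises(SegregationError):
            dissimilarity_index(bad, np.array([1, 1]))

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 100), st.integers(0, 100)),
            min_size=2, max_size=12,
        ).filter(lambda c: sum(a for a, _ in c) > 0 and sum(b for _, b in c) > 0)
    )
    def test_bounds_over_random_tables(self, counts):
        m = np.array([a for a, _ in counts])
        r = np.array([b for _, b in counts])
        d = dissimilarity_index(m, r)
        assert 0.0 <= d <= 1.0

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 60), st.integers(0, 60)),
            min_size=2, max_size=8,
        ).filter(lambda c: sum(a for a, _ in c) > 0 and sum(b for _, b in c) > 0),
        scale=st.integers(2, 17),
    )
    def test_scale_invariance_exact(self, counts, scale):
        m = np.array([a for a, _ in counts])
        r = np.array([b for _, b in counts])
        assert dissimilarity_index(m, r) == dissimilarity_index(m * scale, r * scale)

    def test_zero_iff_equal_proportions(self, rng):
        # equal proportions -> exactly 0
        base = rng.integers(1, 40, size=6)
        assert dissimilarity_index(base * 3, base * 5) <= 1e-12
        # any deviation -> strictly positive
        m = base.copy()
        m[0] += 1
        assert dissimilarity_index(m, base * 5) > 1e-12

    def test_merge_invariance_same_sign(self):
        # tracts 0 and 1 both over-represent the minority: merging them
        # leaves D unchanged; merging opposite-sign tracts 1 and 2 shrinks it.
        m = np.array([30, 30, 10, 30])
        r = np.array([10, 10, 40, 40])
        d0 = dissimilarity_index(m, r)
        merged_same = dissimilarity_index(np.array([60, 10, 30]), np.array([20, 40, 40]))
        assert merged_same == pytest.approx(d0, abs=1e-15)
        merged_opp = dissimilarity_index(np.array([30, 40, 30]), np.array([10, 50, 40]))
        assert merged_opp <= d0 + 1e-15


class TestAllocationModel:
    def test_mle_probabilities_are_tract_shares(self):
        model = estimate_allocation(np.array([10, 30]), np.array([40, 20]))
        assert model.p1 == pytest.approx([0.25, 0.75])
        assert model.p0 == pytest.approx([2 / 3, 1 / 3])
        assert model.n1 + model.n0 == 100

    def test_plugin_identity_with_population_form(self, rng):
        m = rng.integers(0, 50, size=8) + 1
        r = rng.integers(0, 50, size=8) + 1
        model = estimate_allocation(m, r)
        assert population_dissimilarity(model) == pytest.approx(
            dissimilarity_index(m, r), abs=1e-14
        )

    def test_population_dissimilarity_degenerate_cases(self):
        same = AllocationModel(np.array([0.5, 0.5]), np.array([0.5, 0.5]), 1, 1)
        assert population_dissimilarity(same) == 0.0
        apart = AllocationModel(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1, 1)
        assert population_dissimilarity(apart) == 1.0


class TestConditionalForm:
    def test_homogeneous_city_is_zero(self):
        d = conditional_population_dissimilarity(
            np.array([50.0, 50.0]), np.array([0.2, 0.2]), 0.2
        )
        assert d == pytest.approx(0.0, abs=1e-15)

    def test_rejects_boundary_overall_probability(self):
        with pytest.raises(SegregationError):
            conditional_population_dissimilarity(
                np.array([1.0, 1.0]), np.array([0.5, 0.5]), 1.0
            )

    def test_agrees_with_unconditional_form(self):
        # sizes [60, 40], conditionals [0.5, 0], p = 0.3: convert via Bayes.
        sizes = np.array([60.0, 40.0])
        q = np.array([0.5, 0.0])
        p = 0.3
        w = sizes / sizes.sum()
        p1 = w * q / p
        p0 = w * (1 - q) / (1 - p)
        model = AllocationModel(p1, p0, 3, 7)
        assert conditional_population_dissimilarity(sizes, q, p) == pytest.approx(
            population_dissimilarity(model), abs=1e-14
        )

    def test_equivalence_on_random_instances(self, rng):
        """Both D_pop forms agree to 1e-12 on 1000 random consistent inputs."""
        for _ in range(1000):
            J = rng.integers(2, 10)
            p1 = rng.dirichlet(np.ones(J))
            p0 = rng.dirichlet(np.ones(J))
            p = float(rng.uniform(0.05, 0.95))
            w = p * p1 + (1 - p) * p0
            q = p * p1 / w
            d_cond = conditional_population_dissimilarity(w, q, p)
            d_pop = population_dissimilarity(AllocationModel(p1, p0, 1, 1))
            assert abs(d_cond - d_pop) < 1e-12
            assert 0.0 <= d_cond <= 1.0 + 1e-12


class TestLogLikelihood:
    def test_degenerate_single_tract(self):
        model = AllocationModel(np.array([1.0]), np.array([1.0]), 3, 4)
        assert log_likelihood(model, np.array([3]), np.array([4])) == 0.0

    def test_closed_form_two_by_two(self):
        m = np.array([1, 1])
        model = estimate_allocation(m, m)
        assert log_likelihood(model, m, m) == pytest.approx(-2 * math.log(2))

    def test_positive_count_on_zero_probability_is_minus_inf(self):
        model = AllocationModel(np.array([1.0, 0.0]), np.array([0.5, 0.5]), 2, 2)
        assert log_likelihood(model, np.array([1, 1]), np.array([1, 1])) == -math.inf

    def test_maximized_at_mle(self, rng):
        m = rng.integers(1, 20, size=4)
        r = rng.integers(1, 20, size=4)
        model = estimate_allocation(m, r)
        ll_mle = log_likelihood(model, m, r)
        for _ in range(20):
            eps = rng.normal(0, 0.02, size=4)
            p1 = np.clip(model.p1 + eps, 1e-9, None)
            p0 = np.clip(model.p0 - eps, 1e-9, None)
            perturbed = AllocationModel(p1 / p1.sum(), p0 / p0.sum(),
                                        model.n1, model.n0)
            assert log_likelihood(perturbed, m, r) <= ll_mle + 1e-9


class TestCityDissimilarity:
    def test_empty_tracts_dropped_with_result_intact(self):
        table = make_table(
            [[5, 3, 2], [0, 0, 0], [2, 3, 5]],
            brackets=((0.0, 1.0), (1.0, 2.0), (2.0, 3.0)),
        )
        res = city_dissimilarity(table, 1.0)
        assert res.n_tracts == 2
        assert res.comparison_mode == "complement"
        assert 0.0 <= res.D <= 1.0

    def test_consistency_plugin_converges_to_dpop(self, rng):
        """Plug-in D approaches D_pop as both group sizes grow."""
        from idiseg.synthetic import calibrate_allocation

        model = calibrate_allocation(10, 0.3, 0.4)
        errs = []
        for n in (10**2, 10**3, 10**4, 10**5):
            n1, n0 = int(0.4 * n), n - int(0.4 * n)
            reps = []
            for _ in range(30):
                m = rng.multinomial(n1, model.p1)
                r = rng.multinomial(n0, model.p0)
                reps.append(abs(dissimilarity_index(m, r) - 0.3))
            errs.append(np.mean(reps))
        assert errs[0] > errs[-1]
        assert all(errs[i + 1] < errs[i] * 0.9 for i in range(3))
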