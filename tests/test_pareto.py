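"""Dominance, Pareto fronts, scalarization, relaxed and constrained selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paretodock import (
    DomainError,
    ObjectivePair,
    constrained_front,
    dominates,
    epsilon_front,
    front_members,
    lambda_sweep,
    oracle_front_members,
    pareto_front,
    rank_single_objective,
    scalarize,
    select_top_hits,
)


def random_points(rng, n):
    return [
        ObjectivePair(f"L{i}", f1=float(a), f2=float(b))
        for i, (a, b) in enumerate(
            zip(rng.uniform(4, 12, n), rng.uniform(4, 12, n))
        )
    ]


def ids(points_or_results):
    return {p.ligand_id for p in points_or_results}


class TestDominates:
    def test_better_in_both_dominates(self, reference_opioids):
        by_id = {p.ligand_id: p for p in reference_opioids}
        assert dominates(by_id["CHEMBL3139481"], by_id["NFEPP"])

    def test_never_dominates_itself(self, reference_opioids):
        for p in reference_opioids:
            assert not dominates(p, p)

    def test_incomparable_pair(self, reference_opioids):
        by_id = {p.ligand_id: p for p in reference_opioids}
        c, fm = by_id["CHEMBL3139481"], by_id["Fluoromorphine beta-C2"]
        assert not dominates(c, fm) and not dominates(fm, c)


class TestParetoFront:
    def test_reference_opioid_front(self, reference_opioids):
        results = pareto_front(reference_opioids)
        assert ids(r for r in results if r.on_front) == {
            "CHEMBL3139481", "Fluoromorphine beta-C2"
        }

    def test_single_point_is_front(self):
        (r,) = pareto_front([ObjectivePair("only", 9.0, 8.0)])
        assert r.on_front and r.layer == 1

    def test_duplicate_coordinates_share_the_front(self):
        points = [ObjectivePair("a", 9.0, 8.0), ObjectivePair("b", 9.0, 8.0)]
        results = pareto_front(points)
        assert all(r.on_front for r in results)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            pareto_front([])

    def test_matches_pairwise_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(1, 501))
            points = random_points(rng, n)
            assert ids(front_members(points)) == ids(oracle_front_members(points))

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 2**16), c=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        points = random_points(rng, 30)
        scaled = [
            ObjectivePair(p.ligand_id, p.f1 * c, p.f2 * c) for p in points
        ]
        original = {r.ligand_id: r.layer for r in pareto_front(points)}
        after = {r.ligand_id: r.layer for r in pareto_front(scaled)}
        assert original == after


class TestScalarize:
    def test_balanced_weight_selects_most_specific(self, reference_opioids):
        argmax, value = scalarize(reference_opioids, 0.5)
        assert ids(argmax) == {"CHEMBL3139481"}
        assert value == pytest.approx(0.4)  # 0.5*9.4 - 0.5*8.6

    def test_extreme_weights_select_per_objective_optima(self, reference_opioids):
        assert ids(scalarize(reference_opioids, 1.0)[0]) == {"CHEMBL3139481"}
        assert ids(scalarize(reference_opioids, 0.0)[0]) == {
            "Fluoromorphine beta-C2"
        }

    def test_out_of_range_lambda_rejected(self):
        with pytest.raises(DomainError):
            scalarize([ObjectivePair("a", 1.0, 1.0)], 1.5)


class TestLambdaSweep:
    def test_union_is_subset_of_front(self, reference_opioids):
        _, union = lambda_sweep(reference_opioids, grid_size=101)
        assert ids(union) <= {"CHEMBL3139481", "Fluoromorphine beta-C2"}

    def test_single_point_wins_every_lambda(self):
        by_lambda, union = lambda_sweep([ObjectivePair("only", 5.0, 5.0)], 11)
        assert all(ids(v) == {"only"} for v in by_lambda.values())
        assert ids(union) == {"only"}

    def test_every_sweep_output_is_non_dominated(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            points = random_points(rng, int(rng.integers(2, 60)))
            front = ids(front_members(points))
            _, union = lambda_sweep(points, grid_size=101)
            assert ids(union) <= front

    def test_unsupported_front_point_never_returned_by_sweep(self):
        # B is non-dominated but lies strictly inside the convex hull of
        # the front, so no scalarization weight selects it.
        points = [
            ObjectivePair("A", f1=10.0, f2=10.0),
            ObjectivePair("B", f1=4.0, f2=5.0),
            ObjectivePair("C", f1=0.0, f2=0.0),
        ]
        assert ids(front_members(points)) == {"A", "B", "C"}
        _, union = lambda_sweep(points, grid_size=1001)
        assert "B" not in ids(union)


class TestEpsilonFront:
    def test_reference_opioid_layers(self, reference_opioids):
        results = epsilon_front(reference_opioids, mode="layers", k=2)
        by_layer = {}
        for r in results:
            by_layer.setdefault(r.layer, set()).add(r.ligand_id)
        assert by_layer[1] == {"CHEMBL3139481", "Fluoromorphine beta-C2"}
        assert by_layer[2] == {"NFEPP"}  # NFEPP dominates fentanyl

    def test_k1_and_eps0_reduce_to_plain_front(self, reference_opioids):
        front = ids(r for r in pareto_front(reference_opioids) if r.on_front)
        assert ids(epsilon_front(reference_opioids, "layers", k=1)) == front
        assert ids(epsilon_front(reference_opioids, "additive", eps=0.0)) == front

    def test_invalid_mode_rejected(self, reference_opioids):
        with pytest.raises(DomainError):
            epsilon_front(reference_opioids, mode="multiplicative")

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 2**16))
    def test_layers_partition_and_nest(self, seed):
        rng = np.random.default_rng(seed)
        points = random_points(rng, 40)
        results = pareto_front(points)
        layers = {}
        for r in results:
            layers.setdefault(r.layer, []).append(r)
        # disjoint + exhaustive by construction; check domination structure
        for layer_idx in sorted(layers)[1:]:
            prev = [
                ObjectivePair(r.ligand_id, r.f1, r.f2)
                for r in layers[layer_idx - 1]
            ]
            for r in layers[layer_idx]:
                point = ObjectivePair(r.ligand_id, r.f1, r.f2)
                assert any(dominates(p, point) for p in prev)
        # nesting in k
        for k in range(1, max(layers) + 1):
            inner = ids(epsilon_front(points, "layers", k=k))
            outer = ids(epsilon_front(points, "layers", k=k + 1))
            assert inner <= outer

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 2**16),
        eps1=st.floats(0.0, 2.0),
        eps2=st.floats(0.0, 2.0),
    )
    def test_additive_fronts_nest_in_eps(self, seed, eps1, eps2):
        lo, hi = sorted((eps1, eps2))
        rng = np.random.default_rng(seed)
        points = random_points(rng, 30)
        assert ids(epsilon_front(points, "additive", eps=lo)) <= ids(
            epsilon_front(points, "additive", eps=hi)
        )


class TestConstrainedFront:
    def test_threshold_prunes_weak_acidic_binders(self, reference_opioids):
        results = constrained_front(reference_opioids, alpha=9.0)
        assert ids(results) == {"CHEMBL3139481"}

    def test_zero_threshold_equals_plain_front(self, reference_opioids):
        plain = ids(r for r in pareto_front(reference_opioids) if r.on_front)
        assert ids(constrained_front(reference_opioids, 0.0)) == plain

    def test_infeasible_threshold_warns_and_returns_empty(self, reference_opioids):
        with pytest.warns(UserWarning, match="no ligand"):
            assert constrained_front(reference_opioids, 20.0) == []

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 2**16), a1=st.floats(0, 12), a2=st.floats(0, 12))
    def test_fronts_shrink_monotonically_in_alpha(self, seed, a1, a2):
        lo, hi = sorted((a1, a2))
        rng = np.random.default_rng(seed)
        points = random_points(rng, 30)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            outer = ids(constrained_front(points, lo))
            inner = ids(constrained_front(points, hi))
        # any dominator of an eligible point is itself eligible (it has the
        # larger f1), so raising alpha can only remove front members
        assert inner <= outer


class TestSelection:
    def test_neutral_cap_then_specificity_rank(self, reference_opioids):
        with pytest.warns(UserWarning, match="only 1"):
            hits = select_top_hits(reference_opioids, neutral_max=8.0, k=3)
        assert [p.ligand_id for p in hits] == ["Fluoromorphine beta-C2"]

    def test_unbounded_cap_picks_global_max_specificity(self, reference_opioids):
        hits = select_top_hits(reference_opioids, neutral_max=float("inf"), k=1)
        assert [p.ligand_id for p in hits] == ["CHEMBL3139481"]

    def test_short_list_warns(self, reference_opioids):
        with pytest.warns(UserWarning, match="only"):
            select_top_hits(reference_opioids, neutral_max=8.0, k=10)

    def test_single_objective_relaxation_keeps_near_optimal(
        self, reference_opioids
    ):
        selected = rank_single_objective(reference_opioids, "f2",
                                         theta_relax=0.05)
        assert ids(selected) == {"fentanyl", "NFEPP", "CHEMBL3139481"}

    def test_zero_relaxation_is_argmax_only(self, reference_opioids):
        # conventional screening at neutral pH prefers fentanyl
        selected = rank_single_objective(reference_opioids, "f2",
                                         theta_relax=0.0)
        assert ids(selected) == {"fentanyl"}
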