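import numpy as np
import pytest

from pdrwh import (
    DriverRanking,
    RunConfig,
    TransitionMatrix,
    WalkConfig,
    prepare_cohort,
    random_hypergraph,
    random_walk_with_restart,
    rank_cohort,
    rank_patient,
    restart_vector,
    score_and_rank,
    solve_stationary_direct,
    transition_matrix,
)
from pdrwh.hypergraph import PersonalizedHypergraph

from conftest import brute_force_transition, simulate_two_stage_walk


def _single_edge_hypergraph(weights):
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    return PersonalizedHypergraph(
        target_sample="T",
        vertices=[f"G{i}" for i in range(n)],
        hyperedges=["T"],
        H=np.ones((n, 1)),
        rho=np.ones(1),
        w_e=np.ones(1),
        Wv=weights[:, None],
        d_v=np.ones(n),
        delta_e=np.array([weights.sum()]),
        bandwidth=0.1,
    )


class TestTransitionMatrix:
    def test_single_hyperedge_uniform_weights(self):
        T = transition_matrix(_single_edge_hypergraph([1, 1, 1, 1]))
        assert np.allclose(T.P, 0.25)

    def test_single_hyperedge_weighted(self):
        T = transition_matrix(_single_edge_hypergraph([2, 1, 1]))
        assert np.allclose(T.P, np.tile([0.5, 0.25, 0.25], (3, 1)))

    def test_two_hyperedge_toy_against_scalar_loop(self):
        # V={A,B,C}; e0 all with weights (1,1,1), w=1; e1={A,C}, w=0.5
        hg = PersonalizedHypergraph(
            target_sample="T",
            vertices=["A", "B", "C"],
            hyperedges=["T", "S1"],
            H=np.array([[1, 1], [1, 0], [1, 1]], dtype=float),
            rho=np.array([1.0, 0.9]),
            w_e=np.array([1.0, 0.5]),
            Wv=np.array([[1, 1], [1, 0], [1, 1]], dtype=float),
            d_v=np.array([1.5, 1.0, 1.5]),
            delta_e=np.array([3.0, 2.0]),
            bandwidth=0.1,
        )
        T = transition_matrix(hg)
        assert np.allclose(T.P[1], [1 / 3, 1 / 3, 1 / 3])
        # row A by hand: e0 picked with 1/1.5, e1 with 0.5/1.5
        pA = (1 / 1.5) * np.array([1 / 3, 1 / 3, 1 / 3]) + (0.5 / 1.5) * np.array(
            [0.5, 0.0, 0.5]
        )
        assert np.allclose(T.P[0], pA)
        assert np.allclose(T.P, brute_force_transition(hg), atol=1e-14)

    def test_random_hypergraphs_rows_sum_to_one_and_match_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            hg = random_hypergraph(int(rng.integers(2, 30)),
                                   int(rng.integers(1, 12)), rng)
            T = transition_matrix(hg)
            assert np.allclose(T.P.sum(axis=1), 1.0, atol=1e-12)
            assert np.max(np.abs(T.P - brute_force_transition(hg))) < 1e-12

    def test_nonstochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            TransitionMatrix(["A", "B"], np.array([[0.5, 0.4], [0.5, 0.5]]))


class TestRestartWalk:
    def test_rank_one_matrix_has_closed_form_fixed_point(self):
        u = np.array([0.5, 0.3, 0.2])
        P = np.tile(u, (3, 1))
        T = TransitionMatrix(["A", "B", "C"], P)
        v0 = np.array([1.0, 0.0, 0.0])
        v, it, conv = random_walk_with_restart(T, v0, WalkConfig())
        assert conv and it <= 3
        assert np.allclose(v, 0.85 * u + 0.15 * v0, atol=1e-6)

    def test_alpha_to_zero_returns_restart_vector(self):
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(4), size=4)
        T = TransitionMatrix(list("ABCD"), P)
        v0 = np.array([0.25, 0.25, 0.25, 0.25])
        v, _, _ = random_walk_with_restart(T, v0, WalkConfig(alpha=1e-12))
        assert np.allclose(v, v0, atol=1e-9)

    def test_iterative_matches_direct_solve(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            P = rng.dirichlet(np.ones(n), size=n)
            T = TransitionMatrix([f"G{i}" for i in range(n)], P)
            v0 = rng.dirichlet(np.ones(n))
            v, _, conv = random_walk_with_restart(
                T, v0, WalkConfig(epsilon=1e-12, max_iter=5000)
            )
            ref = solve_stationary_direct(T, v0, 0.85)
            assert conv
            assert np.abs(v - ref).sum() < 1e-8

    def test_direct_solve_identity_and_iteration_oracle(self):
        T = TransitionMatrix(list("ABC"), np.eye(3))
        v0 = np.array([0.2, 0.5, 0.3])
        assert np.allclose(solve_stationary_direct(T, v0, 0.85), v0)
        rng = np.random.default_rng(4)
        P = rng.dirichlet(np.ones(5), size=5)
        T5 = TransitionMatrix([f"G{i}" for i in range(5)], P)
        v0 = rng.dirichlet(np.ones(5))
        v = v0.copy()
        for _ in range(10000):
            v = 0.85 * (P.T @ v) + 0.15 * v0
        assert np.abs(solve_stationary_direct(T5, v0, 0.85) - v).max() < 1e-12

    def test_mass_conserved_and_l1_deltas_decrease(self):
        rng = np.random.default_rng(7)
        hg = random_hypergraph(20, 6, rng)
        T = transition_matrix(hg)
        v0 = restart_vector(T.vertex_order, set(T.vertex_order[:5]))
        v = v0.copy()
        deltas = []
        for _ in range(30):
            v_next = 0.85 * (T.P.T @ v) + 0.15 * v0
            assert abs(v_next.sum() - 1.0) < 1e-12
            deltas.append(np.abs(v_next - v).sum())
            v = v_next
        assert all(d2 <= d1 + 1e-15 for d1, d2 in zip(deltas, deltas[1:]))

    def test_invalid_restart_vector_rejected(self):
        T = TransitionMatrix(["A", "B"], np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            random_walk_with_restart(T, np.array([0.7, 0.7]), WalkConfig())

    def test_monte_carlo_two_stage_walk_matches_stationary(self):
        """Simulating the walk as literally described (pick a
        hyperedge by weight, then a vertex by its in-edge weight, restart
        with prob 1-alpha) reproduces the analytic stationary vector."""
        rng = np.random.default_rng(2024)
        hg = random_hypergraph(8, 4, rng)
        T = transition_matrix(hg)
        v0 = restart_vector(T.vertex_order, set(T.vertex_order[:3]))
        exact = solve_stationary_direct(T, v0, 0.85)
        emp, se = simulate_two_stage_walk(hg, v0, alpha=0.85,
                                      steps=200_000, rng=rng)
        assert np.all(np.abs(emp - exact) <= 3 * se + 1e-12)




class TestScoreAndRank:
    def test_tied_scores_split_evenly_and_sort_alphabetically(self):
        r = score_and_rank(np.array([0.2, 0.2, 0.6]), ["B", "A", "C"],
                           {"A", "B"}, "S1")
        assert r.entries == [("A", 0.5), ("B", 0.5)]

    def test_l1_normalization(self):
        r = score_and_rank(np.array([0.3, 0.1, 0.6]), ["A", "B", "C"],
                           {"A", "B"}, "S1")
        assert [g for g, _ in r.entries] == ["A", "B"]
        assert [s for _, s in r.entries] == [pytest.approx(0.75),
                                             pytest.approx(0.25)]

    def test_max_normalization_switch(self):
        r = score_and_rank(np.array([0.3, 0.1]), ["A", "B"], {"A", "B"},
                           "S1", normalization="max")
        assert r.entries[0] == ("A", 1.0)

    def test_single_mutated_gene_scores_one(self):
        r = score_and_rank(np.array([0.05, 0.95]), ["A", "B"], {"A"}, "S1")
        assert r.entries == [("A", 1.0)]

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(0)
        v = rng.dirichlet(np.ones(10))
        r = score_and_rank(v, [f"G{i}" for i in range(10)],
                           {f"G{i}" for i in range(4)}, "S1")
        assert sum(s for _, s in r.entries) == pytest.approx(1.0, abs=1e-9)


class TestRankPatient:
    def test_cohort_sample_order_does_not_change_rankings(self, small_synthetic):
        from pdrwh import ExpressionMatrix, MutationProfile

        _, (X, M, net, _) = small_synthetic
        cohort1 = prepare_cohort(X, M, net, RunConfig(min_mutations=1))
        perm = list(reversed(X.sample_ids))
        cohort2 = prepare_cohort(
            ExpressionMatrix(X.values[perm]),
            MutationProfile(M.calls[perm]),
            net,
            RunConfig(min_mutations=1),
        )
        target = X.sample_ids[0]
        r1 = rank_cohort(cohort1, [target])[0]
        r2 = rank_cohort(cohort2, [target])[0]
        assert r1.genes == r2.genes
        for (g1, s1), (g2, s2) in zip(r1.entries, r2.entries):
            assert g1 == g2 and s1 == pytest.approx(s2, abs=1e-12)

    def test_planted_drivers_mostly_rank_first(self, small_prepared):
        cohort, truth = small_prepared
        rankings = rank_cohort(cohort)
        hits = sum(
            r.entries[0][0] in truth.carried[r.sample_id] for r in rankings
        )
        assert hits / len(rankings) >= 0.7

    def test_unknown_target_rejected(self, small_prepared):
        cohort, _ = small_prepared
        with pytest.raises(KeyError, match="NOPE"):
            rank_cohort(cohort, ["NOPE"])
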