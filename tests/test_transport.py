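"""Transport: Sinkhorn solver vs an exact LP oracle, marginal contracts,
growth learning, composition and pushforward/pullback semantics."""

import numpy as np
import pytest
from scipy.optimize import linprog

from fatecourse.simulate import simulate_timecourse
from fatecourse.transport import (
    GrowthRates,
    TransportConfig,
    TransportMap,
    collapse_timepoints,
    compose_maps,
    cost_matrix,
    learn_growth_rates,
    push,
    unbalanced_sinkhorn,
)

from conftest import GRID

BALANCED = dict(lambda_source=np.inf, lambda_target=np.inf, normalize_cost=False)


def lp_transport(C: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact balanced optimal transport by linear programming (oracle)."""
    n, m = C.shape
    A_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1
        A_eq.append(row.ravel())
    for j in range(m):
        row = np.zeros((n, m))
        row[:, j] = 1
        A_eq.append(row.ravel())
    res = linprog(
        C.ravel(), A_eq=np.array(A_eq), b_eq=np.concatenate([a, b]), bounds=(0, None)
    )
    assert res.success
    return res.x.reshape(n, m)


class TestCostMatrix:
    def test_identical_sets_zero_diagonal(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        C = cost_matrix(pts, pts, normalize=False)
        np.testing.assert_allclose(np.diag(C), 0.0, atol=1e-10)

    def test_squared_euclidean_arithmetic(self):
        C = cost_matrix(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]), normalize=False)
        assert C[0, 0] == pytest.approx(25.0)

    def test_symmetric_when_source_is_target(self):
        pts = np.random.default_rng(1).normal(size=(8, 4))
        C = cost_matrix(pts, pts, normalize=False)
        np.testing.assert_allclose(C, C.T, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            cost_matrix(np.ones((3, 2)), np.ones((3, 4)))


class TestUnbalancedSinkhorn:
    def test_constant_cost_gives_outer_product(self):
        a = np.array([0.2, 0.3, 0.5])
        b = np.array([0.6, 0.4])
        tm = unbalanced_sinkhorn(np.ones((3, 2)), a, b, TransportConfig(**BALANCED))
        np.testing.assert_allclose(tm.gamma, np.outer(a, b), atol=1e-8)

    @pytest.mark.parametrize(
        "C",
        [
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]),
            np.array([[0.3, 0.9, 0.2], [0.8, 0.1, 0.7], [0.4, 0.6, 0.5]]),
        ],
        ids=["2x2", "3x3-band", "3x3-random"],
    )
    def test_matches_lp_oracle_at_small_epsilon(self, C):
        n, m = C.shape
        a, b = np.full(n, 1 / n), np.full(m, 1 / m)
        cfg = TransportConfig(epsilon=1e-3, max_iterations=50_000, **BALANCED)
        tm = unbalanced_sinkhorn(C, a, b, cfg)
        assert np.abs(tm.gamma - lp_transport(C, a, b)).max() < 1e-3

    def test_balanced_marginals_reproduced(self):
        rng = np.random.default_rng(2)
        C = rng.random((6, 5))
        a = rng.random(6)
        a /= a.sum()
        b = rng.random(5)
        b /= b.sum()
        tm = unbalanced_sinkhorn(C, a, b, TransportConfig(epsilon=0.1, **BALANCED))
        np.testing.assert_allclose(tm.gamma.sum(axis=1), a, atol=1e-7)
        np.testing.assert_allclose(tm.gamma.sum(axis=0), b, atol=1e-7)

    def test_epsilon_to_zero_approaches_lp_cost_monotonically(self):
        C = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        a = b = np.full(3, 1 / 3)
        lp_cost = float((lp_transport(C, a, b) * C).sum())
        costs = []
        for eps in (0.5, 0.2, 0.08, 0.03, 0.01):
            tm = unbalanced_sinkhorn(
                C, a, b, TransportConfig(epsilon=eps, max_iterations=50_000, **BALANCED)
            )
            costs.append(float((tm.gamma * C).sum()))
        assert np.all(np.diff(costs) <= 1e-9)
        assert costs[-1] == pytest.approx(lp_cost, abs=1e-3)

    def test_nonnegative_and_finite(self):
        rng = np.random.default_rng(3)
        C = rng.random((20, 25)) * 4
        a = rng.random(20) + 0.1
        b = rng.random(25) + 0.1
        tm = unbalanced_sinkhorn(C, a / a.sum(), b / b.sum())
        assert np.all(tm.gamma >= 0)
        assert np.isfinite(tm.gamma).all()
        assert tm.diagnostics["converged"]

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            unbalanced_sinkhorn(np.ones((2, 2)), np.array([1.0, 0.0]), np.ones(2))


class TestLearnGrowth:
    def test_symmetric_fixture_learns_unit_growth(self):
        pts = np.random.default_rng(0).normal(size=(200, 5))
        C = cost_matrix(pts, pts)
        g, _ = learn_growth_rates(
            C, GrowthRates(np.ones(200), dt=0.75), TransportConfig(epsilon=0.02)
        )
        assert np.abs(g.rates - 1.0).max() < 0.05

    def test_zero_iterations_returns_initial(self):
        pts = np.random.default_rng(1).normal(size=(30, 3))
        C = cost_matrix(pts, pts)
        init = GrowthRates(np.full(30, 1.7), dt=0.5)
        g, tm = learn_growth_rates(C, init, TransportConfig(growth_iterations=0))
        np.testing.assert_array_equal(g.rates, init.rates)
        assert tm.growth is g

    def test_expanding_branch_learns_higher_growth(self):
        # branch A triples its cell mass over dt=0.25, branch B halves
        rng = np.random.default_rng(1)
        nA = nB = 250
        src = np.vstack([rng.normal(0, 1, (nA, 5)), rng.normal(0, 1, (nB, 5)) + 8.0])
        tgt = np.vstack(
            [rng.normal(0, 1, (3 * nA // 2, 5)), rng.normal(0, 1, (nB // 2, 5)) + 8.0]
        )
        g, _ = learn_growth_rates(cost_matrix(src, tgt), GrowthRates(np.ones(nA + nB), 0.25))
        assert g.rates[:nA].mean() > g.rates[nA:].mean()

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            GrowthRates(np.ones(3), dt=0.0)


def _map_from(gamma, source_ids=None, target_ids=None):
    n, m = gamma.shape
    return TransportMap(
        gamma=gamma,
        source_ids=np.arange(n) if source_ids is None else source_ids,
        target_ids=np.arange(m) if target_ids is None else target_ids,
        config=TransportConfig(),
    )


class TestComposePush:
    def test_identity_coupling_is_neutral(self):
        rng = np.random.default_rng(0)
        gamma = rng.random((4, 4))
        eye = _map_from(np.eye(4) * 0.25)
        left = compose_maps([_map_from(gamma), eye])
        np.testing.assert_allclose(left, _map_from(gamma).transition_matrix(), atol=1e-12)

    def test_composition_associative(self):
        rng = np.random.default_rng(1)
        A, B, C = (_map_from(rng.random((5, 5))) for _ in range(3))
        ab_c = compose_maps([A, B]) @ C.transition_matrix()
        a_bc = A.transition_matrix() @ compose_maps([B, C])
        np.testing.assert_allclose(ab_c, a_bc, atol=1e-10)

    def test_rows_stochastic_regardless_of_scaling(self):
        rng = np.random.default_rng(2)
        maps = [_map_from(rng.random((6, 6)) * 10 ** rng.integers(-3, 3)) for _ in range(3)]
        out = compose_maps(maps)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_chain_mismatch_named(self):
        with pytest.raises(ValueError, match="chain break"):
            compose_maps([_map_from(np.ones((3, 4))), _map_from(np.ones((5, 3)))])

    def test_point_mass_through_identity(self):
        eye = _map_from(np.eye(3))
        d = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(push(d, [eye], "forward"), d)
        np.testing.assert_allclose(push(d, [eye], "backward"), d)

    def test_push_conserves_mass(self):
        rng = np.random.default_rng(3)
        maps = [_map_from(rng.random((5, 7))), _map_from(rng.random((7, 4)))]
        d = rng.random(5)
        d /= d.sum()
        assert push(d, maps, "forward").sum() == pytest.approx(1.0, abs=1e-9)

    def test_wrong_support_rejected(self):
        with pytest.raises(ValueError, match="entries"):
            push(np.array([1.0]), [_map_from(np.ones((3, 3)))], "forward")

    def test_forward_backward_roundtrip_near_uniform(self):
        # symmetric fixture: the same point cloud at both ends of each interval
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(150, 5))
        C = cost_matrix(pts, pts)
        maps = [
            unbalanced_sinkhorn(
                C,
                np.full(150, 1 / 150),
                np.full(150, 1 / 150),
                TransportConfig(epsilon=0.05, lambda_source=np.inf, lambda_target=np.inf),
            )
            for _ in range(2)
        ]
        uniform = np.full(150, 1.0 / 150)
        back = push(push(uniform, maps, "forward"), maps, "backward")
        tv = 0.5 * np.abs(back - uniform).sum()
        assert tv < 0.05

    def test_backward_push_finds_true_ancestors(self, small_results):
        """Pulling a terminal branch's indicator back one interval lands most
        mass on that branch's true cells."""
        ds = small_results.dataset
        ct = ds.cell_table
        idx_last = ds.cells_at(3.0)
        is_a = (ct.iloc[idx_last]["state_label"] == "A").to_numpy()
        d = is_a / is_a.sum()
        back = push(d, small_results.maps[-1:], "backward")
        idx_prev = ds.cells_at(2.25)
        is_a_prev = (ct.iloc[idx_prev]["state_label"] == "A").to_numpy()
        assert back[is_a_prev].sum() >= 0.70


class TestCollapse:
    def test_merges_adjacent_timepoints(self, symmetric_tree):
        ds = simulate_timecourse(symmetric_tree, GRID, 30, seed=0)
        out = collapse_timepoints(ds, {2.25: 3.0, 3.0: 3.0})
        assert sorted(out.cell_table["time_point"].unique()) == [0.0, 0.75, 1.5, 3.0]
        assert out.time_grid == [0.0, 0.75, 1.5, 3.0]
        assert (out.counts != ds.counts).nnz == 0

    def test_empty_groups_identity(self, symmetric_tree):
        ds = simulate_timecourse(symmetric_tree, GRID, 10, seed=0)
        out = collapse_timepoints(ds, {})
        assert out.time_grid == ds.time_grid

    def test_self_collapse_identity(self, symmetric_tree):
        ds = simulate_timecourse(symmetric_tree, GRID, 10, seed=0)
        out = collapse_timepoints(ds, {3.0: 3.0})
        assert out.time_grid == ds.time_grid

    def test_non_adjacent_collapse_warns(self, symmetric_tree):
        ds = simulate_timecourse(symmetric_tree, GRID, 10, seed=0)
        with pytest.warns(UserWarning, match="non-adjacent"):
            collapse_timepoints(ds, {0.0: 3.0, 3.0: 3.0})
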