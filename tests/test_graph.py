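"""Delay-weighted shortest paths, betweenness, network comparison."""

import itertools

import networkx as nx
import numpy as np
import pytest

from delaynet.errors import GraphError
from delaynet.graph import (
    betweenness,
    block_summary,
    compare_path_matrices,
    path_analysis,
    shortest_paths,
)

from conftest import delay_net, random_delay_net, roi_table


def enumerate_paths_oracle(tau, rel_tol=1e-9):
    """Exhaustive simple-path enumeration: shortest delays, multiplicities
    and betweenness by direct application of the proportion formula."""
    n = len(tau)
    best = np.full((n, n), np.inf)
    paths = {}
    for h in range(n):
        for j in range(n):
            if h == j:
                best[h, j] = 0.0
                continue
            found = []
            for k in range(n - 2 + 1):
                inner = [x for x in range(n) if x not in (h, j)]
                for mid in itertools.permutations(inner, k):
                    route = (h, *mid, j)
                    w = 0.0
                    ok = True
                    for a, b in zip(route, route[1:]):
                        if tau[a, b] == 0:
                            ok = False
                            break
                        w += tau[a, b]
                    if ok:
                        found.append((w, route))
            if found:
                wmin = min(w for w, _ in found)
                best[h, j] = wmin
                paths[h, j] = [r for w, r in found
                               if abs(w - wmin) <= rel_tol * wmin]
    bc = np.zeros(n)
    for i in range(n):
        total = 0.0
        for h in range(n):
            for j in range(n):
                if h == j or h == i or j == i or (h, j) not in paths:
                    continue
                rho = len(paths[h, j])
                rho_i = sum(1 for r in paths[h, j] if i in r[1:-1])
                total += rho_i / rho
        bc[i] = total / ((n - 1) * (n - 2))
    return best, bc


def test_single_edge_and_triangle():
    net = delay_net([[0, 5e-3], [5e-3, 0]])
    sp = shortest_paths(net)
    assert sp[0, 1] == sp[1, 0] == 5e-3
    tau = np.array([[0, 1.0, 3.0], [1.0, 0, 1.0], [3.0, 1.0, 0]])
    sp = shortest_paths(delay_net(tau))
    assert sp[0, 2] == 2.0  # detour via the middle node wins


def test_disconnected_components_are_infinite():
    tau = np.zeros((4, 4))
    tau[0, 1] = tau[1, 0] = 1.0
    tau[2, 3] = tau[3, 2] = 1.0
    sp = shortest_paths(delay_net(tau))
    assert np.isinf(sp[0, 2]) and np.isinf(sp[1, 3])
    assert sp[0, 1] == 1.0


def test_betweenness_closed_forms():
    # 3-node path: all traffic crosses the middle node
    tau = np.zeros((3, 3))
    tau[0, 1] = tau[1, 0] = tau[1, 2] = tau[2, 1] = 1e-3
    np.testing.assert_allclose(betweenness(delay_net(tau)), [0, 1, 0],
                               atol=1e-15)
    # 5-node star: hub carries all 12 ordered leaf pairs
    tau = np.zeros((5, 5))
    tau[0, 1:] = tau[1:, 0] = 2e-3
    np.testing.assert_allclose(betweenness(delay_net(tau)),
                               [1, 0, 0, 0, 0], atol=1e-15)
    # complete graph with equal delays: direct edges always win
    tau = np.full((6, 6), 1e-3)
    np.fill_diagonal(tau, 0)
    np.testing.assert_allclose(betweenness(delay_net(tau)), 0.0, atol=1e-15)


def test_enumeration_oracle_agreement(rng):
    for _ in range(40):
        net = random_delay_net(rng, n_min=4, n_max=7)
        sp_oracle, bc_oracle = enumerate_paths_oracle(net.tau)
        pa = path_analysis(net)
        fin = np.isfinite(sp_oracle)
        assert np.array_equal(fin, np.isfinite(pa.sp))
        np.testing.assert_allclose(pa.sp[fin], sp_oracle[fin], rtol=1e-12)
        np.testing.assert_allclose(pa.bc, bc_oracle, atol=1e-9)


def test_networkx_cross_check(rng):
    """Independent library route agrees on betweenness and path counts."""
    for _ in range(25):
        net = random_delay_net(rng, n_min=5, n_max=8)
        pa = path_analysis(net)
        G = nx.from_numpy_array(net.tau)
        bc_nx = nx.betweenness_centrality(G, weight="weight", normalized=True)
        np.testing.assert_allclose(
            pa.bc, [bc_nx[i] for i in range(net.n_rois)], atol=1e-9)


def test_tied_paths_counted():
    """Two exactly tied routes halve each intermediate node's share."""
    # square: 0-1-2 and 0-3-2 tie between corners 0 and 2
    tau = np.zeros((4, 4))
    for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        tau[a, b] = tau[b, a] = 1.0
    pa = path_analysis(delay_net(tau))
    assert pa.path_counts[0, 2] == 2
    np.testing.assert_allclose(pa.bc, [1 / 6] * 4)  # (0.5+0.5)/(3*2)


def test_scale_invariance(rng):
    net = random_delay_net(rng, n_min=6, n_max=8)
    pa = path_analysis(net)
    scaled = delay_net(net.tau * 7.3, rois=net.rois)
    pa2 = path_analysis(scaled)
    fin = np.isfinite(pa.sp)
    np.testing.assert_allclose(pa2.sp[fin], 7.3 * pa.sp[fin], rtol=1e-12)
    np.testing.assert_allclose(pa2.bc, pa.bc, atol=1e-12)


def test_compare_path_matrices():
    sp = np.array([[0, 1.0], [1.0, 0]])
    np.testing.assert_array_equal(compare_path_matrices(sp, sp), 0.0)
    diff = compare_path_matrices(sp, 0.75 * sp)
    assert diff[0, 1] == pytest.approx(-25.0)
    with pytest.raises(GraphError):
        compare_path_matrices(sp, np.array([[0, np.inf], [np.inf, 0]]))
    with pytest.raises(GraphError):
        compare_path_matrices(np.zeros((2, 2)), sp)  # degenerate zero


def test_block_summary_partition():
    rois = roi_table(4, hemispheres=["L", "L", "R", "R"])
    diff = np.array([
        [0, -10.0, 4.0, 6.0],
        [-10.0, 0, 8.0, 10.0],
        [4.0, 8.0, 0, -20.0],
        [6.0, 10.0, -20.0, 0],
    ])
    blocks = block_summary(diff, rois).set_index("block")
    assert blocks.loc["LH", "mean_pct"] == pytest.approx(-10.0)
    assert blocks.loc["RH", "mean_pct"] == pytest.approx(-20.0)
    assert blocks.loc["inter", "mean_pct"] == pytest.approx(7.0)
    assert blocks.loc["SC", "n"] == 0 and np.isnan(blocks.loc["SC", "mean_pct"])
    uniform = block_summary(np.where(np.eye(4), 0, -30.0), rois)
    assert (uniform[uniform["n"] > 0]["mean_pct"] == -30.0).all()


def test_subcortical_block_takes_precedence():
    rois = roi_table(4, hemispheres=["L", "L", "R", "R"],
                     subcortical=[False, True, False, False])
    diff = np.where(np.eye(4), 0, 1.0)
    blocks = block_summary(diff, rois).set_index("block")
    assert blocks.loc["SC", "n"] == 6      # all ordered pairs touching node 1
    assert blocks.loc["LH", "n"] == 0
    with pytest.raises(GraphError):
        block_summary(diff, rois.drop(columns=["hemisphere"]))


def test_nonpositive_weight_rejected():
    tau = np.array([[0, 1.0], [1.0, 0]])
    net = delay_net(tau)
    net.tau[0, 1] = net.tau[1, 0] = 0.0  # mutate behind validation
    net.coupling[0, 1] = net.coupling[1, 0] = True
    with pytest.raises(GraphError):
        shortest_paths(net)
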