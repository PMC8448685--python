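"""Delay-weighted graph analysis.

Treats the conduction-delay matrix as a distance matrix: shortest paths
(Dijkstra) give the minimal total delay between every pair of regions, and
betweenness centrality

    C_B(i) = 1/((N-1)(N-2)) * sum_{h != i, h != j, j != i} rho_hj(i)/rho_hj

quantifies the share of all-pairs shortest paths passing through a region
(endpoints excluded; ordered pairs, matching the (N-1)(N-2) normalisation).
Shortest-path multiplicities are counted with a configurable relative
tolerance on path delays, since floating-point sums make exact tie equality
fragile.

The module also compares an estimated-delay network against its
constant-velocity approximation: a signed percent-difference matrix of
shortest-path delays, and block summaries over left/right intra-hemispheric,
inter-hemispheric and subcortical connection blocks.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .errors import GraphError
from .network import DelayNetwork

DEFAULT_TIE_TOL = 1e-9

__all__ = [
    "PathAnalysis",
    "shortest_paths",
    "betweenness",
    "path_analysis",
    "compare_path_matrices",
    "block_summary",
]


@dataclass
class PathAnalysis:
    """All-pairs shortest-path structure of a delay network.

    ``sp``: shortest-path delay matrix (s; inf for disconnected pairs).
    ``bc``: per-node betweenness centrality in [0, 1].
    ``path_counts``: rho_hj, shortest-path multiplicity per ordered pair.
    ``through_counts``: rho_hj(i) (pair h, pair j, node i), only populated
    on request — it is an N^3 array.
    """

    sp: np.ndarray
    bc: np.ndarray
    n: int
    path_counts: np.ndarray
    through_counts: Optional[np.ndarray] = None


def _check_positive_weights(net: DelayNetwork) -> None:
    if np.any(net.tau[net.coupling] <= 0):
        raise GraphError("Dijkstra requires strictly positive edge weights")


def shortest_paths(net: DelayNetwork) -> np.ndarray:
    """Exact all-pairs shortest-path delays; inf where no path exists."""
    _check_positive_weights(net)
    w = np.where(net.coupling, net.tau, 0.0)
    return _sp_dijkstra(csr_matrix(w), directed=False)


def _sssp_counts(adj, tau, source, tie_tol):
    """Single-source Dijkstra with tolerance-aware multiplicity counting.

    Returns (dist, sigma): shortest delay and number of distinct shortest
    paths from ``source`` to every node.  Two path delays within relative
    ``tie_tol`` of each other are treated as tied.
    """
    n = len(adj)
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0.0
    sigma[source] = 1.0
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v, w in adj[u]:
            nd = dist[u] + w
            tol = tie_tol * max(nd, dist[v] if np.isfinite(dist[v]) else nd)
            if nd < dist[v] - tol:
                dist[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= tol:
                sigma[v] += sigma[u]
    return dist, sigma


def _adjacency_list(net: DelayNetwork):
    n = net.n_rois
    adj = [[] for _ in range(n)]
    rows, cols = np.where(np.triu(net.coupling, k=1))
    for i, j in zip(rows, cols):
        w = net.tau[i, j]
        adj[i].append((j, w))
        adj[j].append((i, w))
    return adj


def path_analysis(net: DelayNetwork, tie_tol: float = DEFAULT_TIE_TOL, *,
                  with_through_counts: bool = False) -> PathAnalysis:
    """Shortest paths, multiplicities and betweenness in one pass.

    Betweenness is evaluated directly from the printed proportion formula:
    node ``i`` lies on a shortest h-j path iff
    ``dist(h,i) + dist(i,j) == dist(h,j)`` (within tolerance), in which case
    ``rho_hj(i) = sigma(h,i) * sigma(i,j)``.
    """
    n = net.n_rois
    if n < 3:
        raise GraphError("betweenness requires at least 3 nodes")
    _check_positive_weights(net)
    adj = _adjacency_list(net)
    dist = np.empty((n, n))
    sigma = np.empty((n, n))
    for s in range(n):
        dist[s], sigma[s] = _sssp_counts(adj, net.tau, s, tie_tol)

    bc = np.zeros(n)
    through = np.zeros((n, n, n)) if with_through_counts else None
    finite = np.isfinite(dist)
    offdiag = ~np.eye(n, dtype=bool)
    for i in range(n):
        via = dist[:, i][:, None] + dist[i, :][None, :]
        # tie tolerance scaled to the path delay magnitude; inf - inf at
        # disconnected pairs is masked out below
        with np.errstate(invalid="ignore"):
            on_path = np.abs(via - dist) <= tie_tol * np.maximum(via, dist)
        mask = on_path & finite & offdiag
        mask[i, :] = False
        mask[:, i] = False
        rho_i = np.where(mask, sigma[:, i][:, None] * sigma[i, :][None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mask, rho_i / sigma, 0.0)
        bc[i] = ratio.sum() / ((n - 1) * (n - 2))
        if with_through_counts:
            through[:, :, i] = rho_i
    return PathAnalysis(sp=dist, bc=bc, n=n, path_counts=sigma,
                        through_counts=through)


def betweenness(net: DelayNetwork,
                tie_tol: float = DEFAULT_TIE_TOL) -> np.ndarray:
    """Normalised betweenness centrality per node, in [0, 1]."""
    return path_analysis(net, tie_tol).bc


def compare_path_matrices(sp_est: np.ndarray,
                          sp_cv: np.ndarray) -> np.ndarray:
    """Signed percent difference ``100 * (sp_cv - sp_est) / sp_est``.

    Negative entries mean the constant-velocity network has *shorter*
    shortest paths than the estimated-delay network.  Finite off-diagonal
    entries only; disconnected pairs (inf in both inputs) become NaN, the
    diagonal 0.  The two matrices must share shape and infinity pattern.
    """
    sp_est = np.asarray(sp_est, dtype=float)
    sp_cv = np.asarray(sp_cv, dtype=float)
    if sp_est.shape != sp_cv.shape:
        raise GraphError("shortest-path matrices differ in shape")
    inf_e, inf_c = ~np.isfinite(sp_est), ~np.isfinite(sp_cv)
    if not np.array_equal(inf_e, inf_c):
        raise GraphError("shortest-path matrices differ in infinity pattern")
    offdiag = ~np.eye(sp_est.shape[0], dtype=bool)
    if np.any((sp_est == 0) & offdiag & ~inf_e):
        raise GraphError("degenerate zero off-diagonal entry in sp_est")
    diff = np.zeros_like(sp_est)
    finite = ~inf_e & offdiag
    diff[finite] = 100.0 * (sp_cv[finite] - sp_est[finite]) / sp_est[finite]
    diff[inf_e & offdiag] = np.nan
    return diff


def block_summary(diff: np.ndarray, rois: pd.DataFrame) -> pd.DataFrame:
    """Mean/median percent difference per connection block.

    Blocks partition the off-diagonal entries: ``SC`` (either endpoint
    subcortical), then ``LH``/``RH`` intra-hemispheric and ``inter``
    (cortico-cortical only).  NaN entries (disconnected pairs) are ignored;
    an empty block is reported with n = 0, not an error.
    """
    for col in ("hemisphere", "is_subcortical"):
        if col not in rois.columns:
            raise GraphError(f"ROI table lacks required column '{col}'")
    diff = np.asarray(diff, dtype=float)
    n = diff.shape[0]
    if len(rois) != n:
        raise GraphError("ROI table size does not match matrix")
    hemi = rois["hemisphere"].to_numpy()
    sc = rois["is_subcortical"].to_numpy(dtype=bool)
    offdiag = ~np.eye(n, dtype=bool)
    sc_block = (sc[:, None] | sc[None, :]) & offdiag
    same = hemi[:, None] == hemi[None, :]
    lh = same & (hemi == "L")[:, None] & ~sc_block & offdiag
    rh = same & (hemi == "R")[:, None] & ~sc_block & offdiag
    inter = ~same & ~sc_block & offdiag
    rows = []
    for name, mask in (("LH", lh), ("RH", rh), ("inter", inter),
                       ("SC", sc_block)):
        vals = diff[mask]
        vals = vals[np.isfinite(vals)]
        rows.append({
            "block": name,
            "n": int(vals.size),
            "mean_pct": float(np.mean(vals)) if vals.size else np.nan,
            "median_pct": float(np.median(vals)) if vals.size else np.nan,
        })
    return pd.DataFrame(rows)
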