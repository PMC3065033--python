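"""Global network statistics.

Weighted clustering coefficients (the Zhang–Horvath and Onnela forms),
assortative mixing in its symmetric and directed-weighted forms, and global
efficiency.  Conventions:

* Edge values are normalized by the network maximum before entering either
  clustering coefficient, so both are invariant to a uniform rescaling of
  all weights.
* Vertices where a clustering coefficient is structurally undefined (degree
  below 2, or a zero denominator) score 0 and are still included in the
  network mean.
* An assortativity coefficient whose Pearson denominator vanishes (a regular
  graph, say) is *undefined* and returned as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, InputFormatError
from .network import EdgeLengthFunction, WeightedNetwork, shortest_path_distances

__all__ = [
    "GlobalMetrics",
    "clustering_zhang",
    "clustering_onnela",
    "assortativity_symmetric",
    "assortativity_directed",
    "global_efficiency",
    "compute_global_metrics",
]


@dataclass(frozen=True)
class GlobalMetrics:
    clustering_zhang_mean: float
    clustering_onnela_mean: float
    assortativity: float  # NaN when undefined
    global_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {
            "clustering_zhang_mean": self.clustering_zhang_mean,
            "clustering_onnela_mean": self.clustering_onnela_mean,
            "assortativity": self.assortativity,
            "global_efficiency": self.global_efficiency,
        }


def _require_undirected(net: WeightedNetwork, what: str) -> None:
    if net.directed:
        raise InputFormatError(f"{what} is defined for undirected networks only")


def _normalized_weights(net: WeightedNetwork) -> np.ndarray:
    W = net.weights
    w_max = W.max()
    if w_max <= 0:
        raise ComputationError("clustering requires at least one edge (max weight > 0)")
    return W / w_max


def clustering_zhang(net: WeightedNetwork, v: int | None = None):
    """Zhang–Horvath weighted clustering coefficient.

    c_Z(v) = sum_{i != j != v} w^_vi w^_ij w^_jv / sum_{i != j != v} w^_vi w^_jv
    with w^ the max-normalized weights.  Vertices with a zero denominator
    (fewer than two weighted neighbours) score 0.  Returns the per-vertex
    array, or a scalar when ``v`` is given.
    """
    _require_undirected(net, "Zhang clustering")
    Wn = _normalized_weights(net)
    # diagonal is zero, so (Wn^3)_vv sums exactly over ordered pairs i != j,
    # i, j != v, and the denominator is (row sum)^2 minus the square terms
    numer = np.diag(Wn @ Wn @ Wn)
    s1 = Wn.sum(axis=1)
    s2 = (Wn**2).sum(axis=1)
    denom = s1**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return c if v is None else float(c[v])


def clustering_onnela(
    net: WeightedNetwork,
    v: int | None = None,
    binary_threshold: float | None = None,
):
    """Onnela weighted clustering coefficient (subgraph-intensity form).

    c_O(v) = (1 / (deg(v) (deg(v) - 1))) sum_{i != j != v}
             (w^_vi w^_ij w^_jv)^(1/3)
    where deg(v) is taken on the binary skeleton.  By default the skeleton
    is the support of the (already thresholded) network; pass
    ``binary_threshold`` to re-threshold the weights for the degree count.
    Vertices of degree < 2 score 0.
    """
    _require_undirected(net, "Onnela clustering")
    Wn = _normalized_weights(net)
    if binary_threshold is None:
        skeleton = net.support()
    else:
        skeleton = (net.weights >= binary_threshold).astype(float)
        np.fill_diagonal(skeleton, 0.0)
    deg = skeleton.sum(axis=1)
    C = np.cbrt(Wn)
    numer = np.diag(C @ C @ C)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return c if v is None else float(c[v])


def _endpoint_properties(net: WeightedNetwork, rho: np.ndarray):
    """Per-edge endpoint property values (rho_u, rho_v, omega)."""
    triples = list(net.edges())
    if not triples:
        raise ComputationError("assortativity requires a non-empty edge set")
    u = np.array([t[0] for t in triples])
    v = np.array([t[1] for t in triples])
    w = np.array([t[2] for t in triples])
    return rho[u], rho[v], w


def _default_rho(net: WeightedNetwork) -> np.ndarray:
    """Degree for binary networks, strength for greyscale ones."""
    if net.mode == "binary":
        return net.support().sum(axis=1) if not net.directed else (
            net.support().sum(axis=0) + net.support().sum(axis=1)
        )
    W = net.weights
    return W.sum(axis=1) if not net.directed else W.sum(axis=0) + W.sum(axis=1)


def assortativity_symmetric(net: WeightedNetwork, rho: np.ndarray | None = None) -> float:
    """Assortativity coefficient of an undirected network (symmetric form).

    r = (4m S_uv - S_plus^2) / (2m S_sq - S_plus^2) with sums over the edge
    set, S_uv = sum rho(u) rho(v), S_plus = sum (rho(u) + rho(v)),
    S_sq = sum (rho(u)^2 + rho(v)^2), m the edge count.  This equals the
    Pearson correlation of the property over the 2m ordered edge-endpoint
    pairs; r is NaN when the denominator vanishes (zero property variance).
    """
    _require_undirected(net, "symmetric assortativity")
    rho = _default_rho(net) if rho is None else np.asarray(rho, dtype=float)
    ru, rv, _ = _endpoint_properties(net, rho)
    m = len(ru)
    if m < 2:
        raise ComputationError("assortativity needs at least 2 edges")
    s_uv = float(np.sum(ru * rv))
    s_plus = float(np.sum(ru + rv))
    s_sq = float(np.sum(ru**2 + rv**2))
    denom = 2 * m * s_sq - s_plus**2
    if abs(denom) < 1e-300:
        return float("nan")
    return (4 * m * s_uv - s_plus**2) / denom


def assortativity_directed(net: WeightedNetwork, rho: np.ndarray | None = None) -> float:
    """Weighted assortativity of a directed network.

    With H = sum of edge values, A = sum omega rho(u), B = sum omega rho(v):
    r = (H sum omega rho(u) rho(v) - A B)
        / (sqrt(H sum omega rho(u)^2 - A^2) sqrt(H sum omega rho(v)^2 - B^2)).
    This is the omega-weighted Pearson correlation between source and target
    properties over edges; NaN when either variance vanishes.
    """
    if not net.directed:
        raise InputFormatError("directed assortativity requires a directed network")
    rho = _default_rho(net) if rho is None else np.asarray(rho, dtype=float)
    ru, rv, w = _endpoint_properties(net, rho)
    H = float(w.sum())
    if H <= 0:
        raise ComputationError("directed assortativity requires positive total edge value")
    A = float(np.sum(w * ru))
    B = float(np.sum(w * rv))
    var_u = H * float(np.sum(w * ru**2)) - A**2
    var_v = H * float(np.sum(w * rv**2)) - B**2
    if var_u <= 1e-300 or var_v <= 1e-300:
        return float("nan")
    cov = H * float(np.sum(w * ru * rv)) - A * B
    return cov / (np.sqrt(var_u) * np.sqrt(var_v))


def global_efficiency(
    net: WeightedNetwork, fn: EdgeLengthFunction | str = "inverse"
) -> float:
    """Average inverse shortest-path distance over ordered vertex pairs.

    ef(G) = (1 / (n (n - 1))) sum_v sum_{u != v} 1 / d_G(v, u); unreachable
    pairs contribute 0, so the measure is well defined on disconnected
    graphs.  In [0, 1] because all edge lengths are >= 1.
    """
    n = net.n_vertices
    if n < 2:
        raise InputFormatError("global efficiency needs at least 2 vertices")
    D = shortest_path_distances(net, fn)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & off, 1.0 / np.where(D > 0, D, np.inf), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def compute_global_metrics(
    net: WeightedNetwork,
    fn: EdgeLengthFunction | str = "inverse",
    rho: np.ndarray | None = None,
) -> GlobalMetrics:
    """All global metrics in one pass (clustering on undirected nets only)."""
    if net.directed:
        cz = co = float("nan")
        r = assortativity_directed(net, rho)
    else:
        cz = float(np.mean(clustering_zhang(net)))
        co = float(np.mean(clustering_onnela(net)))
        r = assortativity_symmetric(net, rho)
    return GlobalMetrics(
        clustering_zhang_mean=cz,
        clustering_onnela_mean=co,
        assortativity=r,
        global_efficiency=global_efficiency(net, fn),
    )
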