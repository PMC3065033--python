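"""Per-vertex centrality measures and network entropy.

Neighbourhood measures (degree/strength), distance measures (closeness,
shortest-path efficiency, betweenness), spectral measures (Bonacich
eigenvector, Hubbell, subgraph centrality) and the entropy rate of the
random walk the weighted network induces.

Distance-based measures run on transformed edge lengths (see
:mod:`neurosync.network`), so they apply unchanged to greyscale networks.
Undefined values (closeness on a disconnected graph, for instance) are
reported as NaN rather than silently replaced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .errors import ComputationError, ConfigError, InputFormatError
from .network import (
    EdgeLengthFunction,
    WeightedNetwork,
    edge_lengths,
    shortest_path_distances,
)

__all__ = [
    "degree_strength",
    "closeness",
    "efficiency",
    "betweenness",
    "eigenvector_centrality",
    "hubbell_centrality",
    "subgraph_centrality",
    "network_entropy",
    "NetworkEntropy",
    "compute_vertex_metrics",
]

#: relative tolerance for treating two path lengths as tied
_TIE_RTOL = 1e-12


# -- neighbourhood ---------------------------------------------------------


def degree_strength(
    net: WeightedNetwork,
    v: int | None = None,
    direction: str = "total",
    normalized: bool = False,
):
    """Degree (binary) or strength (greyscale) centrality.

    ``direction`` is ``"in"``, ``"out"`` or ``"total"``; for undirected
    networks all three coincide.  ``normalized=True`` divides by n - 1, the
    maximum possible degree/strength when edge values are at most 1.
    """
    W = net.weights
    if direction == "in":
        vals = W.sum(axis=0)
    elif direction == "out":
        vals = W.sum(axis=1)
    elif direction == "total":
        vals = W.sum(axis=1) if not net.directed else W.sum(axis=0) + W.sum(axis=1)
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    if normalized:
        vals = vals / max(net.n_vertices - 1, 1)
    return vals if v is None else float(vals[v])


# -- distances -------------------------------------------------------------


def closeness(
    net: WeightedNetwork,
    v: int | None = None,
    fn: EdgeLengthFunction | str = "inverse",
):
    """Inverse mean geodesic distance; NaN where any vertex is unreachable."""
    D = shortest_path_distances(net, fn)
    n = net.n_vertices
    sums = np.where(np.isfinite(D), D, np.nan)[:, :].copy()
    np.fill_diagonal(sums, 0.0)
    totals = sums.sum(axis=1)  # NaN propagates from unreachable pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (n - 1) / totals
    c = np.where(np.isnan(totals), np.nan, c)
    return c if v is None else float(c[v])


def efficiency(
    net: WeightedNetwork,
    v: int | None = None,
    fn: EdgeLengthFunction | str = "inverse",
):
    """Shortest-path efficiency c_Ef(v) = (1/(n-1)) sum_{u != v} 1/d(v, u).

    Unreachable vertices contribute 0, so the measure is defined on
    disconnected graphs; values lie in [0, 1] since lengths are >= 1.
    """
    n = net.n_vertices
    if n < 2:
        raise InputFormatError("efficiency needs at least 2 vertices")
    D = shortest_path_distances(net, fn)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & off, 1.0 / np.where(D > 0, D, np.inf), 0.0)
    c = inv.sum(axis=1) / (n - 1)
    return c if v is None else float(c[v])


def _path_counts(L: np.ndarray, D: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of shortest s->t paths, ties within _TIE_RTOL."""
    n = L.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(D[s])
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(D[s, v]):
                continue
            # predecessors u with d(s,u) + l(u,v) == d(s,v) up to rel. tol.
            through = D[s] + L[:, v]
            tol = _TIE_RTOL * max(D[s, v], 1.0)
            preds = np.isfinite(through) & (np.abs(through - D[s, v]) <= tol)
            sigma[s, v] = sigma[s, preds].sum()
    return sigma


def betweenness(
    net: WeightedNetwork,
    v: int | None = None,
    fn: EdgeLengthFunction | str = "inverse",
):
    """Shortest-path betweenness, normalized by n_B = (n-1)(n-2).

    c_B(v) = (1/n_B) sum over ordered pairs (s, t), s != v != t, of
    sigma_st(v) / sigma_st, where sigma_st counts shortest s-t paths and
    sigma_st(v) those passing through v.  Unreachable pairs contribute 0.
    Path length is the sum of transformed edge lengths, so greyscale
    networks are handled by the same formula.
    """
    n = net.n_vertices
    if n < 3:
        raise InputFormatError("betweenness needs at least 3 vertices")
    L = edge_lengths(net, fn)
    D = shortest_path_distances(net, fn)
    sigma = _path_counts(L, D)
    scores = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or sigma[s, t] == 0:
                continue
            d_st = D[s, t]
            # sigma_st(v) = sigma_sv * sigma_vt when v lies on a geodesic
            through = D[s] + D[:, t]
            tol = _TIE_RTOL * max(d_st, 1.0)
            on_path = np.isfinite(through) & (np.abs(through - d_st) <= tol)
            on_path[s] = on_path[t] = False
            contrib = np.where(on_path, sigma[s] * sigma[:, t] / sigma[s, t], 0.0)
            scores += contrib
    scores /= (n - 1) * (n - 2)
    return scores if v is None else float(scores[v])


# -- spectral --------------------------------------------------------------


def _p_norm(x: np.ndarray, p: float) -> float:
    if p == np.inf:
        return float(np.max(np.abs(x)))
    return float(np.sum(np.abs(x) ** p) ** (1.0 / p))


def eigenvector_centrality(
    net: WeightedNetwork, p_norm: float = 2.0
) -> np.ndarray:
    """Bonacich eigenvector centrality.

    Solves lambda c = W^T c for the principal (largest-modulus) eigenpair
    and returns |s_i| / ||s||_p, so every score is at most 1 for any
    p in [1, inf].
    """
    if p_norm < 1:
        raise ConfigError("p-norm must satisfy p >= 1")
    W = net.weights
    if not W.any():
        raise ComputationError("eigenvector centrality undefined on an edgeless network")
    vals, vecs = np.linalg.eig(W.T)
    order = np.argsort(-np.abs(vals))
    lead = order[0]
    if len(vals) > 1 and np.isclose(
        np.abs(vals[order[0]]), np.abs(vals[order[1]]), rtol=1e-10
    ):
        logging.getLogger(__name__).warning(
            "dominant eigenvalue is not simple; eigenvector centrality may "
            "not be unique"
        )
    s = np.abs(np.real_if_close(vecs[:, lead]))
    s = np.abs(s.astype(float))
    return s / _p_norm(s, p_norm)


def hubbell_centrality(
    net: WeightedNetwork,
    alpha: float | None = None,
    e: np.ndarray | None = None,
) -> np.ndarray:
    """Hubbell centrality: the solution of c = alpha W^T c + e.

    The exogenous vector ``e`` defaults to all-ones.  ``alpha`` must satisfy
    |alpha| < 1 / lambda_1 with lambda_1 the spectral radius of W (so the
    Neumann series converges); the default is 0.5 / lambda_1, or 0.5 on an
    edgeless network.
    """
    W = net.weights
    n = net.n_vertices
    lam1 = float(np.max(np.abs(np.linalg.eigvals(W)))) if W.any() else 0.0
    if alpha is None:
        alpha = 0.5 / lam1 if lam1 > 0 else 0.5
    if lam1 > 0 and not abs(alpha) < 1.0 / lam1:
        raise ConfigError(
            f"alpha = {alpha} violates |alpha| < 1/lambda_1 = {1.0 / lam1:.6g}"
        )
    e = np.ones(n) if e is None else np.asarray(e, dtype=float)
    if e.shape != (n,):
        raise InputFormatError("exogenous vector e must have one entry per vertex")
    A = np.eye(n) - alpha * W.T
    try:
        c = np.linalg.solve(A, e)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - alpha guard prevents
        raise ComputationError(f"Hubbell system is singular: {exc}") from exc
    return c


def subgraph_centrality(net: WeightedNetwork, use_weights: bool = True) -> np.ndarray:
    """Subgraph centrality: c_SG(v_i) = sum_k (A^k)_ii / k! = diag(expm(A)).

    Closed walks of length k are weighted by 1/k!.  ``use_weights=False``
    runs on the 0/1 support instead of the weight matrix (the greyscale
    generalization substitutes W for A).
    """
    A = net.weights if use_weights else net.support()
    if not net.directed and np.allclose(A, A.T):
        # symmetric route: eigendecomposition is exact and cheap
        vals, vecs = np.linalg.eigh(A)
        return np.einsum("ij,j,ij->i", vecs, np.exp(vals), vecs)
    return np.diag(expm(A)).copy()


# -- network entropy -------------------------------------------------------


@dataclass(frozen=True)
class NetworkEntropy:
    """Entropy rate of the walk, plus its per-vertex decomposition."""

    entropy: float  # H = sum_i pi_i H_i
    stationary: np.ndarray  # pi, sums to 1
    vertex_entropy: np.ndarray  # H_i, entropy of row i of P
    contribution: np.ndarray  # pi_i * H_i (removal-impact quantity)
    log_base: float = 2.0


def network_entropy(net: WeightedNetwork, log_base: float = 2.0) -> NetworkEntropy:
    """Kolmogorov–Sinai entropy rate of the random walk induced by W.

    The transition matrix is the row-normalization p_ij = w_ij / sum_k w_ik;
    pi is its stationary distribution (pi P = pi, sum pi = 1) and
    H = -sum_ij pi_i p_ij log p_ij = sum_i pi_i H_i.  Requires every vertex
    to have positive out-strength and the support to be strongly connected
    (so pi is unique).
    """
    W = net.weights
    n = net.n_vertices
    out = W.sum(axis=1)
    dangling = np.nonzero(out <= 0)[0]
    if dangling.size:
        raise ComputationError(
            f"vertex {net.labels[dangling[0]]!r} has zero out-strength; the "
            "walk is undefined — remove isolated/dangling vertices or lower "
            "the threshold"
        )
    n_comp, _ = connected_components(csr_matrix(net.support()), connection="strong")
    if n_comp > 1:
        raise ComputationError(
            "the network support is not strongly connected; the stationary "
            "distribution is not unique — analyse the largest component or "
            "lower the threshold"
        )
    P = W / out[:, None]
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)) / np.log(log_base), 0.0)
    h_i = -(P * logp).sum(axis=1)
    contrib = pi * h_i
    return NetworkEntropy(
        entropy=float(contrib.sum()),
        stationary=pi,
        vertex_entropy=h_i,
        contribution=contrib,
        log_base=log_base,
    )


# -- table assembly --------------------------------------------------------

_ALL_METRICS = (
    "degree",
    "closeness",
    "efficiency",
    "betweenness",
    "eigenvector",
    "hubbell",
    "subgraph",
    "entropy",
)


def compute_vertex_metrics(
    net: WeightedNetwork,
    metrics: tuple[str, ...] = _ALL_METRICS,
    fn: EdgeLengthFunction | str = "inverse",
    normalized_degree: bool = False,
    p_norm: float = 2.0,
    alpha: float | None = None,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-vertex metric table, one column per requested metric.

    Metrics whose preconditions fail on this network (entropy on a
    non-strongly-connected support, for instance) are filled with NaN
    rather than aborting the whole table.
    """
    cols: dict[str, np.ndarray] = {}
    nan = np.full(net.n_vertices, np.nan)
    for name in metrics:
        try:
            if name == "degree":
                if net.directed:
                    cols["in_degree"] = degree_strength(
                        net, direction="in", normalized=normalized_degree
                    )
                    cols["out_degree"] = degree_strength(
                        net, direction="out", normalized=normalized_degree
                    )
                else:
                    cols["degree"] = degree_strength(
                        net, normalized=normalized_degree
                    )
            elif name == "closeness":
                cols["closeness"] = closeness(net, fn=fn)
            elif name == "efficiency":
                cols["efficiency"] = efficiency(net, fn=fn)
            elif name == "betweenness":
                cols["betweenness"] = betweenness(net, fn=fn)
            elif name == "eigenvector":
                cols["eigenvector"] = eigenvector_centrality(net, p_norm)
            elif name == "hubbell":
                cols["hubbell"] = hubbell_centrality(net, alpha)
            elif name == "subgraph":
                cols["subgraph"] = subgraph_centrality(net)
            elif name == "entropy":
                ent = network_entropy(net, log_base)
                cols["entropy_rate_contribution"] = ent.contribution
                cols["vertex_entropy"] = ent.vertex_entropy
            else:
                raise ConfigError(
                    f"unknown vertex metric {name!r}; choose from {_ALL_METRICS}"
                )
        except ComputationError:
            if name == "entropy":
                cols["entropy_rate_contribution"] = nan
                cols["vertex_entropy"] = nan
            else:
                cols[name] = nan
    df = pd.DataFrame(cols, index=pd.Index(net.labels, name="label"))
    return df
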