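"""Network layout geometries.

Three complementary views of a synchronization network:

* **static** — electrodes at their montage positions, affinely rescaled
  into a unit oval representing the scalp (deterministic, never re-drawn
  when metrics change);
* **mds** — classical multidimensional scaling of the shortest-path
  distance matrix over transformed edge lengths, so strongly synchronized
  channels appear close together;
* **bstress** — a binary-stress force-directed layout that pulls adjacent
  vertices to unit distance while spreading non-adjacent ones uniformly,
  minimized by iterative majorization (cost never increases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, InputFormatError
from .io import Montage
from .network import EdgeLengthFunction, WeightedNetwork, shortest_path_distances

logger = logging.getLogger(__name__)

__all__ = ["Layout", "static_layout", "mds_layout", "bstress_layout"]

#: semi-axes of the scalp oval used by the static layout
OVAL_A = 1.0
OVAL_B = 0.8


@dataclass(frozen=True)
class Layout:
    """Per-vertex 2-D coordinates with provenance."""

    labels: tuple[str, ...]
    coords: np.ndarray
    method: str  # static | mds | bstress
    cost: float | None = None
    n_iter: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise InputFormatError("layout coordinates must be n x 2")
        if not np.all(np.isfinite(coords)):
            raise ComputationError("layout produced non-finite coordinates")
        if coords.shape[0] != len(self.labels):
            raise InputFormatError("layout label count does not match coordinates")
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))


def static_layout(montage: Montage) -> Layout:
    """Scalp-shaped placement: montage positions rescaled into the unit oval.

    3-D montages are projected onto their first two coordinates.  The map is
    a translation (to the centroid) plus one uniform scale, so relative
    positions are preserved and the layout is idempotent: points already
    centred and touching the oval are returned unchanged.
    """
    if montage.n_electrodes < 1:
        raise InputFormatError("static layout needs at least one electrode")
    xy = montage.coords[:, :2].astype(float)
    xy = xy - xy.mean(axis=0)
    oval_norm = (xy[:, 0] / OVAL_A) ** 2 + (xy[:, 1] / OVAL_B) ** 2
    peak = float(np.max(oval_norm))
    if peak > 0:
        xy = xy / np.sqrt(peak)
    return Layout(labels=montage.labels, coords=xy, method="static")


def _classical_mds(D: np.ndarray, dim: int) -> tuple[np.ndarray, float]:
    """Torgerson's classical scaling: top-``dim`` eigenpairs of -J D^2 J / 2.

    Returns the embedding and the residual strain ||B - XX^T||_F / ||B||_F,
    which is non-increasing in ``dim`` by Eckart–Young.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    take = vals[:dim].clip(min=0.0)
    X = vecs[:, :dim] * np.sqrt(take)[None, :]
    # deterministic orientation: make the largest-|x| entry of each axis positive
    for d in range(X.shape[1]):
        i = int(np.argmax(np.abs(X[:, d])))
        if X[i, d] < 0:
            X[:, d] = -X[:, d]
    b_norm = float(np.linalg.norm(B))
    if b_norm == 0:
        return X, 0.0
    strain = float(np.linalg.norm(B - X @ X.T)) / b_norm
    return X, strain


def mds_layout(
    net: WeightedNetwork,
    fn: EdgeLengthFunction | str = "inverse",
) -> Layout:
    """Classical MDS embedding of the shortest-path distance matrix.

    Unreachable pairs get a finite connection distance of twice the largest
    finite distance (logged), so disconnected networks still embed.  The
    reported cost is the residual strain of the 2-D truncation;
    deterministic up to the fixed sign convention.
    """
    D = shortest_path_distances(net, fn)
    off = ~np.eye(net.n_vertices, dtype=bool)
    finite = np.isfinite(D[off])
    if not finite.any():
        raise ComputationError("all vertex pairs are unreachable; MDS has no distances")
    if not finite.all():
        cap = 2.0 * float(D[off][finite].max())
        logger.info(
            "disconnected network: substituting connection distance %.4g for "
            "unreachable pairs", cap,
        )
        D = np.where(np.isfinite(D), D, cap)
    X, strain = _classical_mds(D, 2)
    return Layout(labels=net.labels, coords=X, method="mds", cost=strain)


def mds_strain_profile(
    net: WeightedNetwork,
    fn: EdgeLengthFunction | str = "inverse",
    dims: tuple[int, ...] = (1, 2, 3),
) -> list[float]:
    """Residual strain of the classical embedding for each dimensionality."""
    D = shortest_path_distances(net, fn)
    if not np.all(np.isfinite(D)):
        off = ~np.eye(net.n_vertices, dtype=bool)
        cap = 2.0 * float(D[off][np.isfinite(D[off])].max())
        D = np.where(np.isfinite(D), D, cap)
    return [_classical_mds(D, d)[1] for d in dims]


def _bstress_cost(
    X: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> float:
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(X.shape[0], k=1)
    return float(np.sum(weights[iu] * (dist[iu] - targets[iu]) ** 2))


def bstress_layout(
    net: WeightedNetwork,
    alpha: float | None = None,
    spread_distance: float | None = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> Layout:
    """Binary-stress layout by iterative (SMACOF-style) majorization.

    Minimizes  sum_{edges} (|p_i - p_j| - 1)^2
             + alpha * sum_{non-edges} (|p_i - p_j| - M)^2,
    i.e. adjacent vertices are pulled to unit distance while non-adjacent
    ones spread towards the target M.  Defaults: alpha = 1/n^2 (so the many
    spread terms do not drown the few edge terms) and M = sqrt(n) (a disc
    of about unit area per vertex).  Majorization guarantees the cost is
    non-increasing per iteration; the start is a seeded random scatter, so
    identical seeds give identical layouts.
    """
    n = net.n_vertices
    if n < 2:
        raise InputFormatError("binary-stress layout needs at least 2 vertices")
    adj = net.support()
    adj = np.maximum(adj, adj.T)  # layout ignores edge direction
    alpha = 1.0 / n**2 if alpha is None else alpha
    M = float(np.sqrt(n)) if spread_distance is None else spread_distance

    targets = np.where(adj > 0, 1.0, M)
    weights = np.where(adj > 0, 1.0, alpha)
    np.fill_diagonal(targets, 0.0)
    np.fill_diagonal(weights, 0.0)

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2)) * M / 2.0

    # weighted-stress majorization: V is the weight Laplacian (fixed),
    # each step solves V X = B(X) X in the least-squares sense
    V = np.diag(weights.sum(axis=1)) - weights
    V_pinv = np.linalg.pinv(V)

    cost = _bstress_cost(X, targets, weights)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, weights * targets / np.where(dist > 0, dist, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = V_pinv @ (B @ X)
        new_cost = _bstress_cost(X_new, targets, weights)
        if new_cost > cost + 1e-12:  # pragma: no cover - majorization guarantee
            logger.warning("binary-stress cost increased; stopping early")
            break
        X = X_new
        if cost - new_cost <= tol * max(cost, 1e-30):
            cost = new_cost
            converged = True
            break
        cost = new_cost
    if not converged:
        logger.warning(
            "binary-stress layout did not converge in %d iterations "
            "(relative tolerance %.1e); returning last iterate", max_iter, tol,
        )
    return Layout(
        labels=net.labels,
        coords=X - X.mean(axis=0),
        method="bstress",
        cost=cost,
        n_iter=it,
        seed=seed,
    )
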