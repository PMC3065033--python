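"""Synchronization-network data model.

A synchronization network is a simple weighted graph on the recording
channels: edge values live in (0, 1] and encode strength of statistical
dependence, and the value 0 is reserved for "no edge".  Networks come in two
flavours: *binary* (edge values thresholded to {0, 1}) and *greyscale*
(values at or above the threshold kept as-is).

Distance-based metrics need edge *lengths* rather than strengths, so the
module also provides the two monotone decreasing transforms
``g(x) = 1/x`` and ``g(x) = 1 - log2(x)``, both mapping (0, 1] onto
[1, +inf), and exact shortest-path distances over the transformed lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ComputationError, ConfigError, InputFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "EdgeLengthFunction",
    "threshold_network",
    "edge_lengths",
    "shortest_path_distances",
    "default_labels",
]


def default_labels(n: int) -> tuple[str, ...]:
    """Auto-generated channel labels ``ch01 ... chNN``."""
    width = max(2, len(str(n)))
    return tuple(f"ch{i + 1:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class WeightedNetwork:
    """Simple weighted graph with non-negative edge values.

    Parameters
    ----------
    weights
        Square ``(n, n)`` array; ``weights[i, j]`` is the value of edge
        ``i -> j`` (``j -> i`` too when undirected) and 0 encodes absence.
    labels
        Vertex names, one per row/column of ``weights``.
    directed
        Whether edge orientation is meaningful.
    mode
        ``"binary"`` (values in {0, 1}) or ``"greyscale"`` (values in [0, 1]).
    """

    weights: np.ndarray
    labels: tuple[str, ...] = ()
    directed: bool = False
    mode: str = "greyscale"

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InputFormatError(f"weight matrix must be square, got shape {W.shape}")
        labels = tuple(self.labels) if self.labels else default_labels(W.shape[0])
        if len(labels) != W.shape[0]:
            raise InputFormatError(
                f"{len(labels)} labels for a {W.shape[0]}-vertex network"
            )
        if len(set(labels)) != len(labels):
            raise InputFormatError("vertex labels must be unique")
        if self.mode not in ("binary", "greyscale"):
            raise InputFormatError(f"unknown mode {self.mode!r}")
        bad = np.argwhere((W < 0) | (W > 1))
        if bad.size:
            i, j = bad[0]
            raise InputFormatError(
                f"edge values must lie in [0, 1]; offending cell ({i}, {j}) = {W[i, j]}"
            )
        if self.mode == "binary" and not np.all((W == 0) | (W == 1)):
            raise InputFormatError("binary network contains values other than 0 and 1")
        W = W.copy()
        np.fill_diagonal(W, 0.0)  # simple graphs: no self-loops
        if not self.directed and not np.allclose(W, W.T):
            logger.warning(
                "asymmetric matrix with directed=False; symmetrizing by the mean "
                "of w_ij and w_ji"
            )
            W = 0.5 * (W + W.T)
        W.setflags(write=False)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "labels", labels)

    # -- convenience -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of edges (unordered pairs when undirected)."""
        nz = int(np.count_nonzero(self.weights))
        return nz if self.directed else nz // 2

    def edges(self):
        """Yield ``(u, v, w)`` index triples; ``u < v`` when undirected."""
        rows, cols = np.nonzero(self.weights)
        for u, v in zip(rows, cols):
            if not self.directed and u > v:
                continue
            yield int(u), int(v), float(self.weights[u, v])

    def support(self) -> np.ndarray:
        """0/1 adjacency matrix of present edges."""
        return (self.weights > 0).astype(float)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no vertex labelled {label!r}") from None


@dataclass(frozen=True)
class EdgeLengthFunction:
    """Edge value -> edge length transform on (0, 1] -> [1, +inf).

    ``kind="inverse"`` uses g(x) = 1/x; ``kind="log2"`` uses g(x) = 1 - log2(x).
    Both satisfy g(1) = 1 and are strictly decreasing; 1/x diverges faster as
    x -> 0+, so weak edges become comparatively longer under it.
    """

    kind: str = "inverse"

    def __post_init__(self) -> None:
        if self.kind not in ("inverse", "log2"):
            raise ConfigError(
                f"unknown edge length transform {self.kind!r}; use 'inverse' or 'log2'"
            )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any((x <= 0) | (x > 1)):
            raise ComputationError(
                "edge length transform is defined on (0, 1] only"
            )
        if self.kind == "inverse":
            return 1.0 / x
        return 1.0 - np.log2(x)


def threshold_network(
    matrix: np.ndarray,
    threshold: float,
    mode: str = "binary",
    directed: bool = False,
    labels: tuple[str, ...] | None = None,
) -> WeightedNetwork:
    """Build a binary or greyscale network from a synchronization matrix.

    An edge ``i -> j`` survives iff ``w_ij >= threshold`` (non-strict, so
    threshold 1.0 still keeps perfect-synchrony edges).  Binary mode maps
    surviving edges to 1; greyscale mode keeps their values.  Diagonal
    entries are ignored and forced to zero.
    """
    W = np.asarray(matrix, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InputFormatError(f"synchronization matrix must be square, got {W.shape}")
    if not (0.0 <= threshold <= 1.0):
        raise InputFormatError(f"threshold must lie in [0, 1], got {threshold}")
    bad = np.argwhere((W < 0) | (W > 1))
    bad = bad[bad[:, 0] != bad[:, 1]] if bad.size else bad
    if bad.size:
        i, j = bad[0]
        raise InputFormatError(
            f"synchronization values must lie in [0, 1]; cell ({i}, {j}) = {W[i, j]}"
        )
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    keep = W >= threshold
    if mode == "binary":
        out = np.where(keep & (W > 0), 1.0, 0.0)
    elif mode == "greyscale":
        out = np.where(keep, W, 0.0)
    else:
        raise InputFormatError(f"unknown mode {mode!r}; use 'binary' or 'greyscale'")
    return WeightedNetwork(out, labels or (), directed=directed, mode=mode)


def edge_lengths(net: WeightedNetwork, fn: EdgeLengthFunction | str = "inverse") -> np.ndarray:
    """Length matrix: present edges mapped through ``fn``, absent edges +inf.

    Present edges must carry values in (0, 1]; the transform guarantees all
    finite lengths are >= 1.  The diagonal is +inf (no self-loops), which the
    shortest-path routine treats as distance 0 from a vertex to itself.
    """
    if isinstance(fn, str):
        fn = EdgeLengthFunction(fn)
    W = net.weights
    present = W > 0
    L = np.full(W.shape, np.inf)
    if present.any():
        L[present] = fn(W[present])
    return L


def shortest_path_distances(
    net: WeightedNetwork, fn: EdgeLengthFunction | str = "inverse"
) -> np.ndarray:
    """All-pairs shortest-path distances over transformed edge lengths.

    Exact Dijkstra on the length matrix; unreachable pairs get the +inf
    sentinel and the diagonal is zero.
    """
    L = edge_lengths(net, fn)
    finite = np.isfinite(L)
    n = net.n_vertices
    graph = csr_matrix((L[finite], np.nonzero(finite)), shape=(n, n))
    return dijkstra(graph, directed=net.directed)
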