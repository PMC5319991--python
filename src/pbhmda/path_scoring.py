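"""Bounded simple-path enumeration and exponential-decay path scoring.

For every microbe-disease pair, all cycle-free paths of at most ``L`` edges
through the heterogeneous network are collected; a path with edge weights
``w_1..w_k`` scores

    S(p) = (w_1 * ... * w_k) ** (alpha * k),

and the pair's total score ``TS`` is the sum of its path scores.  Short
paths through heavy edges dominate; ``alpha`` tunes how fast confidence
decays with path length (all weights lie in (0, 1], so the score does too).

Two equivalent engines compute the full score matrix:

* a recursive depth-first search that marks nodes on entry and unmarks them
  on return, visiting neighbours in ascending node order so paths (and the
  summation) come out in a fixed lexicographic order; and
* for ``L <= 3``, a closed-form aggregation over powered adjacency matrices:
  the sum of ``(prod w)^(alpha*k)`` over length-``k`` walks is an entry of
  the ``k``-th matrix power of ``B_k = W^(alpha*k)`` (elementwise power),
  and for ``k <= 3`` the non-simple walks (those revisiting an endpoint; no
  other repeats are possible without self-loops) are removed exactly by
  inclusion-exclusion.

The closed form turns full-matrix prediction into a handful of dense matrix
products, which is what makes leave-one-out protocols on HMDAD-scale data
(hundreds of kernel/score recomputations) cheap.  Both engines are
deterministic; their agreement is enforced by tests against a brute-force
path oracle.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any

import numpy as np

from .association_data import AssociationMatrix
from .config import RunConfig
from .gip_similarity import DISEASE, MICROBE, gip_kernel
from .hetnet import HeteroNetwork, build_network

__all__ = [
    "Path",
    "ScoreMatrix",
    "enumerate_paths",
    "path_score",
    "total_score",
    "score_matrix",
    "predict_all",
]


@dataclasses.dataclass(frozen=True)
class Path:
    """A repeat-free microbe-to-disease path with its edge weights."""

    nodes: tuple[tuple[str, str], ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        nodes = tuple((str(k), str(n)) for k, n in self.nodes)
        weights = tuple(float(w) for w in self.weights)
        if len(nodes) < 2:
            raise ValueError("a path needs at least two nodes")
        if nodes[0][0] != MICROBE or nodes[-1][0] != DISEASE:
            raise ValueError("paths run from a microbe to a disease")
        if len(set(nodes)) != len(nodes):
            raise ValueError("paths may not repeat nodes")
        if len(weights) != len(nodes) - 1:
            raise ValueError("need exactly one weight per edge")
        if any(not 0.0 < w <= 1.0 for w in weights):
            raise ValueError("edge weights must lie in (0, 1]")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.weights)


# -- depth-first enumeration ----------------------------------------------


def _index_paths(
    net: HeteroNetwork, source: int, target: int, max_length: int
) -> list[tuple[tuple[int, ...], tuple[float, ...]]]:
    """All simple source->target paths with <= max_length edges, lexicographic.

    Classic recursive DFS: a node is marked visited on entry and the mark is
    removed before the recursive call returns, so every simple path is
    emitted exactly once.  Neighbours are scanned in ascending index order,
    which makes the output (and any sum over it) reproducible.
    """
    W = net.weights
    visited = np.zeros(net.n_nodes, dtype=bool)
    visited[source] = True
    nodes = [source]
    weights: list[float] = []
    out: list[tuple[tuple[int, ...], tuple[float, ...]]] = []

    def dfs(u: int, depth: int) -> None:
        for v in net.neighbors(u):
            if v == target:
                out.append((tuple(nodes) + (target,), tuple(weights) + (W[u, v],)))
                # a simple path cannot revisit the target, so never descend
                continue
            if depth + 1 < max_length and not visited[v]:
                visited[v] = True
                nodes.append(v)
                weights.append(W[u, v])
                dfs(v, depth + 1)
                weights.pop()
                nodes.pop()
                visited[v] = False

    dfs(source, 0)
    return out


def enumerate_paths(
    net: HeteroNetwork, microbe: str, disease: str, max_length: int
) -> list[Path]:
    """All simple paths from ``microbe`` to ``disease`` with <= max_length edges."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    s = net.node_index(MICROBE, microbe)
    t = net.node_index(DISEASE, disease)
    paths = []
    for idx, w in _index_paths(net, s, t, max_length):
        nodes = tuple((net.node_kind(i), net.node_name(i)) for i in idx)
        paths.append(Path(nodes, w))
    return paths


def path_score(path: Path, alpha: float) -> float:
    """Exponential-decay score ``(prod weights) ** (alpha * length)``."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    return math.prod(path.weights) ** (alpha * path.length)


def total_score(
    net: HeteroNetwork, microbe: str, disease: str, max_length: int, alpha: float
) -> float:
    """Sum of path scores over all qualifying paths for one pair."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    s = net.node_index(MICROBE, microbe)
    t = net.node_index(DISEASE, disease)
    W = net.weights
    return float(
        sum(math.prod(w) ** (alpha * len(w)) for _, w in _index_paths(net, s, t, max_length))
    )


# -- full-matrix scoring ---------------------------------------------------


def _dense_scores(W: np.ndarray, nm: int, max_length: int, alpha: float) -> np.ndarray:
    """Closed-form TS for L <= 3 via inclusion-exclusion over powered walks.

    With zero diagonal, a length-1 or length-2 walk is automatically simple.
    A length-3 walk m->x->y->d fails simplicity only when x = d or y = m
    (x = y would need a self-loop); the doubly-bad walk m->d->m->d is
    restored once after being subtracted twice.
    """
    total = np.zeros_like(W)
    for k in range(1, max_length + 1):
        B = W ** (alpha * k)
        B[W == 0.0] = 0.0
        if k == 1:
            P = B
        elif k == 2:
            P = B @ B
        else:  # k == 3
            B2 = B @ B
            d = np.diag(B2)
            P = B2 @ B - B * (d[:, None] + d[None, :]) + B**3
        total += P
    # inclusion-exclusion is exact, but guard against tiny negative residue
    return np.maximum(total[:nm, nm:], 0.0)


def _dfs_scores(net: HeteroNetwork, max_length: int, alpha: float) -> np.ndarray:
    nm, nd = net.n_microbes, net.n_diseases
    W = net.weights
    out = np.zeros((nm, nd))
    for i in range(nm):
        for j in range(nd):
            out[i, j] = sum(
                math.prod(w) ** (alpha * len(w))
                for _, w in _index_paths(net, i, nm + j, max_length)
            )
    return out


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    """Aggregated prediction scores TS with parameter provenance."""

    values: np.ndarray
    microbe_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    params: dict[str, Any]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.microbe_names), len(self.disease_names)):
            raise ValueError("score matrix shape does not match name registries")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("scores must be finite and non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "microbe_names", tuple(self.microbe_names))
        object.__setattr__(self, "disease_names", tuple(self.disease_names))


def score_matrix(
    net: HeteroNetwork, max_length: int, alpha: float, method: str = "auto"
) -> np.ndarray:
    """TS values for every (microbe, disease) pair of the network.

    ``method`` is ``"dense"`` (closed form, L <= 3 only), ``"dfs"`` (naive
    per-pair enumeration), or ``"auto"`` (dense when available).  Both
    methods return identical matrices up to floating-point roundoff.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if method == "auto":
        method = "dense" if max_length <= 3 else "dfs"
    if method == "dense":
        if max_length > 3:
            raise ValueError("the closed-form engine supports max_length <= 3")
        return _dense_scores(net.weights, net.n_microbes, max_length, alpha)
    if method == "dfs":
        return _dfs_scores(net, max_length, alpha)
    raise ValueError(f"unknown method {method!r}")


def predict_all(
    Y: AssociationMatrix, config: RunConfig | None = None, method: str = "auto"
) -> ScoreMatrix:
    """Kernels -> network -> path scores for every pair, in one call.

    Known pairs are scored like any other (their direct weight-1 edge
    contributes a length-1 path of score 1); evaluation protocols decide
    which pairs count as candidates.
    """
    cfg = config if config is not None else RunConfig()
    KM = gip_kernel(Y, MICROBE, cfg.gamma_prime_m)
    KD = gip_kernel(Y, DISEASE, cfg.gamma_prime_d)
    net = build_network(Y, KM, KD, cfg.T)
    values = score_matrix(net, cfg.L, cfg.alpha, method=method)
    return ScoreMatrix(
        values=values,
        microbe_names=Y.microbe_names,
        disease_names=Y.disease_names,
        params=cfg.to_dict(),
    )
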