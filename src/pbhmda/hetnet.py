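"""Heterogeneous interlinked network assembly.

One undirected weighted graph over two typed node sets (microbes M, diseases
D) joins three relations: microbe-disease edges with weight exactly 1 where
Y=1; microbe-microbe edges weighted by the microbe GIP kernel KM; and
disease-disease edges weighted by the disease kernel KD.  Similarity edges
whose weight falls below a threshold T are dropped (comparison is ``>= T``
keeps, so equality survives); known-association edges have weight 1 and are
immune to any valid T.  Self-loops are never materialised.

Internally the graph is a dense symmetric weight matrix over the
``nm + nd`` nodes (microbes first), which both the depth-first path
enumerator and the closed-form score aggregation consume directly; a
:mod:`networkx` view is available for interoperability.
"""

from __future__ import annotations

import os
from functools import cached_property
from typing import Iterator

import numpy as np

from .association_data import AssociationMatrix
from .gip_similarity import DISEASE, MICROBE, KernelSimilarityMatrix

__all__ = ["HeteroNetwork", "build_network"]

#: relation labels used in edge exports
_REL_MD = "md"
_REL_MM = "mm"
_REL_DD = "dd"


class HeteroNetwork:
    """Typed, weighted, undirected graph over microbes and diseases.

    Nodes 0..nm-1 are microbes, nodes nm..nm+nd-1 diseases.  ``weights`` is
    the dense symmetric weight matrix with zero diagonal; a zero entry means
    "no edge" (every retained edge has weight in ``[T, 1] ∩ (0, 1]``).
    """

    def __init__(
        self,
        microbe_names: tuple[str, ...],
        disease_names: tuple[str, ...],
        weights: np.ndarray,
        threshold: float,
    ) -> None:
        self.microbe_names = tuple(microbe_names)
        self.disease_names = tuple(disease_names)
        n = len(self.microbe_names) + len(self.disease_names)
        W = np.asarray(weights, dtype=float)
        if W.shape != (n, n):
            raise ValueError(f"weight matrix shape {W.shape}, expected {(n, n)}")
        if not np.array_equal(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.diag(W).any():
            raise ValueError("self-loops are not allowed")
        if W.min() < 0 or W.max() > 1:
            raise ValueError("edge weights must lie in [0, 1]")
        self.weights = W
        self.threshold = float(threshold)

    # -- node bookkeeping --------------------------------------------------

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_nodes(self) -> int:
        return self.n_microbes + self.n_diseases

    def node_kind(self, index: int) -> str:
        return MICROBE if index < self.n_microbes else DISEASE

    def node_name(self, index: int) -> str:
        if index < self.n_microbes:
            return self.microbe_names[index]
        return self.disease_names[index - self.n_microbes]

    @cached_property
    def _index(self) -> dict[tuple[str, str], int]:
        idx = {(MICROBE, n): i for i, n in enumerate(self.microbe_names)}
        idx.update(
            {(DISEASE, n): self.n_microbes + j for j, n in enumerate(self.disease_names)}
        )
        return idx

    def node_index(self, kind: str, name: str) -> int:
        try:
            return self._index[(kind, name)]
        except KeyError:
            raise KeyError(f"unknown node ({kind!r}, {name!r})") from None

    @cached_property
    def _neighbors(self) -> list[np.ndarray]:
        """Ascending-index neighbour lists (fixed DFS visitation order)."""
        return [np.flatnonzero(row) for row in self.weights]

    def neighbors(self, index: int) -> np.ndarray:
        return self._neighbors[index]

    # -- edges -------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edges(self) -> Iterator[tuple[tuple[str, str], tuple[str, str], str, float]]:
        """Yield ((kind, name), (kind, name), relation, weight) per edge."""
        nm = self.n_microbes
        rows, cols = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(rows.tolist(), cols.tolist()):
            rel = _REL_MM if j < nm else (_REL_MD if i < nm else _REL_DD)
            yield (
                (self.node_kind(i), self.node_name(i)),
                (self.node_kind(j), self.node_name(j)),
                rel,
                float(self.weights[i, j]),
            )

    def to_networkx(self):
        """Export as a ``networkx.Graph`` with ``kind`` node attributes."""
        import networkx as nx

        g = nx.Graph(threshold=self.threshold)
        for i in range(self.n_nodes):
            g.add_node((self.node_kind(i), self.node_name(i)), kind=self.node_kind(i))
        for a, b, rel, w in self.edges():
            g.add_edge(a, b, relation=rel, weight=w)
        return g

    def write_edge_list(self, path: str | os.PathLike[str]) -> None:
        """Export edges as TSV: node_a, node_b, relation in {md, mm, dd}, weight."""
        lines = ["node_a\tnode_b\trelation\tweight"]
        for (ka, na), (kb, nb), rel, w in self.edges():
            lines.append(f"{ka}:{na}\t{kb}:{nb}\t{rel}\t{w:.12g}")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")


def build_network(
    Y: AssociationMatrix,
    KM: KernelSimilarityMatrix,
    KD: KernelSimilarityMatrix,
    T: float = 0.0,
) -> HeteroNetwork:
    """Assemble the heterogeneous network from Y, KM, KD at threshold T.

    Microbe-disease edges (weight 1) exist exactly where Y=1; similarity
    edges are kept iff their kernel weight is ``>= T``.  Raises on shape or
    axis mismatches and on T outside [0, 1].
    """
    if not 0.0 <= T <= 1.0:
        raise ValueError(f"threshold T must lie in [0, 1], got {T}")
    if KM.axis != MICROBE or KD.axis != DISEASE:
        raise ValueError("KM must be a microbe kernel and KD a disease kernel")
    nm, nd = Y.n_microbes, Y.n_diseases
    if KM.n != nm or KD.n != nd:
        raise ValueError(
            f"kernel sizes ({KM.n}, {KD.n}) inconsistent with Y shape {(nm, nd)}"
        )
    if KM.names != Y.microbe_names or KD.names != Y.disease_names:
        raise ValueError("kernel name registries do not match the association matrix")

    W = np.zeros((nm + nd, nm + nd))
    mm = np.where(KM.values >= T, KM.values, 0.0)
    dd = np.where(KD.values >= T, KD.values, 0.0)
    np.fill_diagonal(mm, 0.0)
    np.fill_diagonal(dd, 0.0)
    W[:nm, :nm] = mm
    W[nm:, nm:] = dd
    W[:nm, nm:] = Y.values
    W[nm:, :nm] = Y.values.T
    return HeteroNetwork(Y.microbe_names, Y.disease_names, W, T)
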