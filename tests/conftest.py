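"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's vectorised code paths:
the kernel oracle is a scalar double loop, and the path oracle enumerates
node permutations.  They exist so the implementation can be checked against
something that cannot share its bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from pbhmda import (
    DISEASE,
    MICROBE,
    AssociationMatrix,
    HeteroNetwork,
    build_network,
    gip_kernel,
)

# -- independent oracles ---------------------------------------------------


def naive_gip_kernel(values: np.ndarray, axis: str, gamma_prime: float = 1.0) -> np.ndarray:
    """Scalar, per-pair evaluation of the GIP kernel (no vectorisation)."""
    profiles = values.T if axis == DISEASE else values
    n = len(profiles)
    mean_sq = sum(sum(int(x) ** 2 for x in p) for p in profiles) / n
    gamma = gamma_prime / mean_sq
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d2 = sum((int(a) - int(b)) ** 2 for a, b in zip(profiles[i], profiles[j]))
            K[i, j] = math.exp(-gamma * d2)
    return K


def brute_force_paths(
    W: np.ndarray, source: int, target: int, max_length: int
) -> set[tuple[int, ...]]:
    """All simple source->target paths (as node tuples) by permutation search."""
    n = W.shape[0]
    others = [v for v in range(n) if v not in (source, target)]
    found: set[tuple[int, ...]] = set()
    for k in range(1, max_length + 1):  # k edges -> k - 1 intermediates
        for mids in itertools.permutations(others, k - 1):
            seq = (source, *mids, target)
            if all(W[seq[e], seq[e + 1]] > 0 for e in range(k)):
                found.add(seq)
    return found


def brute_force_total_score(
    W: np.ndarray, source: int, target: int, max_length: int, alpha: float
) -> float:
    """Sum of (prod weights)^(alpha*len) over brute-force paths."""
    total = 0.0
    for seq in sorted(brute_force_paths(W, source, target, max_length)):
        prod = math.prod(W[seq[e], seq[e + 1]] for e in range(len(seq) - 1))
        total += prod ** (alpha * (len(seq) - 1))
    return total


# -- random instance helpers ----------------------------------------------


def random_association_matrix(
    rng: np.random.Generator, n_microbes: int, n_diseases: int, density: float = 0.4
) -> AssociationMatrix:
    Y = (rng.random((n_microbes, n_diseases)) < density).astype(np.int8)
    if Y.sum() == 0:
        Y[rng.integers(n_microbes), rng.integers(n_diseases)] = 1
    return AssociationMatrix(
        Y,
        tuple(f"m{i}" for i in range(n_microbes)),
        tuple(f"d{j}" for j in range(n_diseases)),
    )


def random_hetnet(rng: np.random.Generator, max_nodes: int = 8) -> HeteroNetwork:
    """Random small heterogeneous network built through the real pipeline."""
    nm = int(rng.integers(1, max_nodes))
    nd = int(rng.integers(1, max_nodes + 1 - nm)) if nm < max_nodes else 1
    Y = random_association_matrix(rng, nm, nd)
    T = float(rng.choice([0.0, 0.1, 0.3, 0.7]))
    return build_network(Y, gip_kernel(Y, MICROBE), gip_kernel(Y, DISEASE), T)


# -- fixtures --------------------------------------------------------------


@pytest.fixture
def toy_Y() -> AssociationMatrix:
    """The 2x2 worked example: m1-d1, m2-d1, m2-d2."""
    return AssociationMatrix([[1, 0], [1, 1]], ("m1", "m2"), ("d1", "d2"))


@pytest.fixture
def identity2_Y() -> AssociationMatrix:
    return AssociationMatrix(np.eye(2, dtype=int), ("m1", "m2"), ("d1", "d2"))


@pytest.fixture
def triangle_net() -> HeteroNetwork:
    """Hand-built 3-node network: m1-d1 (1.0), m1-m2 (0.5), m2-d1 (1.0)."""
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[0, 2] = W[2, 0] = 1.0
    W[1, 2] = W[2, 1] = 1.0
    return HeteroNetwork(("m1", "m2"), ("d1",), W, 0.0)
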