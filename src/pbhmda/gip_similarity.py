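"""Gaussian interaction profile (GIP) kernel similarity.

Each disease is described by its *interaction profile*: the binary vector of
its associations over all microbes (a column of Y); each microbe by its row.
Similarity between two nodes of the same class is the Gaussian kernel on
their profiles,

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2),

with bandwidth ``gamma`` obtained by normalising a user-set ``gamma'``
(default 1) by the mean squared profile norm of that class — for binary
profiles, the average number of associations per node:

    gamma = gamma' / ( (1/n) * sum_i ||IP(i)||^2 ).

Squared norms and squared distances of binary profiles are integer counts and
are computed in integer arithmetic before any division, so the kernel is
reproducible bit-for-bit.  A node whose profile is all-zero (possible inside
cross-validation after edge removal) is handled normally — the kernel is well
defined for zero vectors; only the all-profiles-zero case is degenerate,
because the bandwidth denominator vanishes.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np

from .association_data import AssociationMatrix

__all__ = [
    "MICROBE",
    "DISEASE",
    "DegenerateNetworkError",
    "KernelSimilarityMatrix",
    "interaction_profile",
    "kernel_bandwidth",
    "gip_kernel",
    "write_kernel",
]

MICROBE = "microbe"
DISEASE = "disease"
_AXES = (MICROBE, DISEASE)


class DegenerateNetworkError(ValueError):
    """The GIP kernel is undefined: every interaction profile is empty."""


@dataclasses.dataclass(frozen=True)
class KernelSimilarityMatrix:
    """Symmetric GIP similarity matrix for one node class.

    Attributes
    ----------
    values
        ``(n, n)`` symmetric matrix; unit diagonal; entries in ``(0, 1]``.
    bandwidth
        The effective gamma actually used in the exponent.
    bandwidth_prime
        The user-set gamma' it was derived from.
    axis
        ``"microbe"`` or ``"disease"``.
    names
        Node names in matrix order.
    """

    values: np.ndarray
    bandwidth: float
    bandwidth_prime: float
    axis: str
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {self.axis!r}")
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} names")
        if not np.array_equal(v, v.T):
            raise ValueError("similarity matrix must be exactly symmetric")
        if not np.array_equal(np.diag(v), np.ones(n)):
            raise ValueError("similarity diagonal must be exactly 1")
        if v.size and (v.min() <= 0.0 or v.max() > 1.0):
            raise ValueError("similarities must lie in (0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n(self) -> int:
        return len(self.names)


def _profiles(Y: AssociationMatrix, axis: str) -> np.ndarray:
    """Interaction profiles as rows of an int64 matrix."""
    if axis == DISEASE:
        return Y.values.T.astype(np.int64)
    if axis == MICROBE:
        return Y.values.astype(np.int64)
    raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")


def interaction_profile(Y: AssociationMatrix, axis: str, index: int) -> np.ndarray:
    """Binary profile of one node: a row (microbe) or column (disease) of Y."""
    P = _profiles(Y, axis)
    n = P.shape[0]
    if not (0 <= index < n):
        raise IndexError(f"{axis} index {index} out of range [0, {n})")
    return P[index].copy()


def kernel_bandwidth(Y: AssociationMatrix, axis: str, gamma_prime: float = 1.0) -> float:
    """Effective bandwidth gamma = gamma' / mean squared profile norm.

    For binary profiles the squared norm of a profile is its association
    count, so the denominator is the average number of associations per node
    of the given class.
    """
    if gamma_prime < 0:
        raise ValueError("gamma_prime must be non-negative")
    P = _profiles(Y, axis)
    total = int(P.sum())  # sum of ||IP(i)||^2 over binary profiles
    if total == 0:
        raise DegenerateNetworkError(
            "all interaction profiles are empty: the GIP kernel bandwidth is "
            "undefined on a network with no associations"
        )
    n = P.shape[0]
    return float(gamma_prime) * n / total


def gip_kernel(
    Y: AssociationMatrix, axis: str, gamma_prime: float = 1.0
) -> KernelSimilarityMatrix:
    """GIP kernel similarity matrix for all nodes of one class.

    Squared distances ``||IP(i) - IP(j)||^2 = c_i + c_j - 2 * G_ij`` (with
    ``G = P P^T`` and counts ``c = diag G``) are integers; the kernel is
    ``exp(-gamma * D)`` elementwise, giving an exactly symmetric matrix with
    an exactly unit diagonal.
    """
    gamma = kernel_bandwidth(Y, axis, gamma_prime)
    P = _profiles(Y, axis)
    G = P @ P.T
    counts = np.diag(G)
    D = counts[:, None] + counts[None, :] - 2 * G
    K = np.exp(-gamma * D.astype(float))
    names = Y.disease_names if axis == DISEASE else Y.microbe_names
    return KernelSimilarityMatrix(
        values=K,
        bandwidth=gamma,
        bandwidth_prime=float(gamma_prime),
        axis=axis,
        names=names,
    )


def write_kernel(kernel: KernelSimilarityMatrix, path: str | os.PathLike[str]) -> None:
    """Export a similarity matrix as a square TSV with name headers."""
    lines = ["\t".join(("", *kernel.names))]
    for name, row in zip(kernel.names, kernel.values):
        lines.append("\t".join((name, *(f"{x:.12g}" for x in row))))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
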