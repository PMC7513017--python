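"""Weighted connectivity graphs and the stationary random walk defined on them.

A connectome is represented by a symmetric, nonnegative connectivity matrix
``C`` with zero diagonal.  Neural traffic is modelled as a random walk on the
graph: from node *i* the walker moves to node *j* with probability
proportional to the edge weight ``C_ij``.  For an undirected graph this chain
is reversible and its stationary distribution has the closed form

    mu_i = C_i / C_T,

where ``C_i = sum_j C_ij`` is the node strength and ``C_T = sum_ij C_ij`` is
the total (bidirectional) weight.  Every information measure in this package
is a functional of the pair ``(mu, P)`` built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "MarkovModel",
    "build_model",
    "symmetrize",
    "ATOL",
]

#: absolute tolerance for stochasticity / normalization checks
ATOL = 1e-12


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency over ``n`` labelled nodes.

    Invariants (validated on construction): ``C`` is square and symmetric,
    has zero diagonal (no self-loops) and no negative weights.
    """

    C: np.ndarray
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got shape {C.shape}")
        if not np.isfinite(C).all():
            raise ValueError("connectivity matrix contains non-finite entries")
        neg = np.argwhere(C < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative weight C[{i},{j}] = {C[i, j]}; "
                "threshold or clip negative weights before building a model"
            )
        asym = np.argwhere(~np.isclose(C, C.T, rtol=0.0, atol=ATOL))
        if asym.size:
            i, j = asym[0]
            raise ValueError(
                f"asymmetric input: C[{i},{j}] = {C[i, j]} != C[{j},{i}] = {C[j, i]}; "
                "use symmetrize() for directed or triangular input"
            )
        if np.any(np.abs(np.diagonal(C)) > 0):
            raise ValueError("self-loops are not allowed; use symmetrize() to zero the diagonal")
        object.__setattr__(self, "C", C)
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(str(i + 1) for i in range(C.shape[0])))
        else:
            labels = tuple(str(l) for l in self.labels)
            if len(labels) != C.shape[0]:
                raise ValueError(f"{len(labels)} labels for {C.shape[0]} nodes")
            object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (nonzero upper-triangle entries)."""
        return int(np.count_nonzero(np.triu(self.C, k=1)))

    @property
    def density(self) -> float:
        """Fraction of possible undirected edges present, 2m / (n(n-1))."""
        n = self.n
        return 2.0 * self.n_edges / (n * (n - 1)) if n > 1 else 0.0


def symmetrize(M: np.ndarray, labels: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Build a :class:`ConnectivityMatrix` from a square nonnegative matrix.

    Upper-triangle values are copied below the diagonal (the standard
    treatment of directed or triangular generator output) and the diagonal
    is zeroed.

    Parameters
    ----------
    M:
        Square matrix with nonnegative entries.  Only the strict upper
        triangle is read.
    labels:
        Optional node labels.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    upper = np.triu(M, k=1)
    return ConnectivityMatrix(upper + upper.T, labels=tuple(labels) if labels is not None else None)


@dataclass(frozen=True)
class MarkovModel:
    """Stationary random-walk Markov chain derived from a connectivity matrix.

    Attributes
    ----------
    P:
        Row-stochastic transition matrix, ``P_ij = C_ij / C_i``.  Rows of
        isolated nodes (strength zero) are identically zero.
    mu:
        Stationary distribution, ``mu_i = C_i / C_T``.
    strengths:
        Node strengths ``C_i``.
    C_T:
        Total bidirectional weight ``sum_ij C_ij`` (each undirected edge
        counted twice).
    connectivity:
        The source matrix.
    """

    P: np.ndarray
    mu: np.ndarray
    strengths: np.ndarray
    C_T: float
    connectivity: ConnectivityMatrix

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.connectivity.labels

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of nodes with zero strength (mu_i = 0)."""
        return self.strengths == 0.0

    def validate(self, atol: float = ATOL) -> None:
        """Check stochasticity, normalization and detailed balance."""
        row_sums = self.P.sum(axis=1)
        connected = ~self.isolated
        if not np.allclose(row_sums[connected], 1.0, rtol=0.0, atol=atol):
            raise AssertionError("transition matrix rows do not sum to 1")
        if np.any(row_sums[self.isolated] != 0.0):
            raise AssertionError("isolated nodes must have all-zero transition rows")
        if abs(self.mu.sum() - 1.0) > atol:
            raise AssertionError("stationary distribution does not sum to 1")
        flux = self.mu[:, None] * self.P
        if not np.allclose(flux, flux.T, rtol=0.0, atol=atol):
            raise AssertionError("detailed balance violated")


def build_model(C: ConnectivityMatrix) -> MarkovModel:
    """Derive the stationary random-walk chain from a connectivity matrix.

    Raises
    ------
    ValueError
        If the graph has no edges (``C_T = 0``), for which no stationary
        walk exists.
    """
    strengths = C.C.sum(axis=1)
    C_T = float(strengths.sum())
    if C_T == 0.0:
        raise ValueError("no edges: cannot define a random walk on an empty graph")
    mu = strengths / C_T
    # isolated nodes keep an all-zero row; every measure uses 0 log 0 = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(strengths[:, None] > 0, C.C / strengths[:, None], 0.0)
    return MarkovModel(P=P, mu=mu, strengths=strengths, C_T=C_T, connectivity=C)
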