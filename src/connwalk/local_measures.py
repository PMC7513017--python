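"""Per-node decompositions of the global information measures.

Each global measure is an expectation over the stationary distribution of a
node-level quantity; the node-level quantities are the local measures:

* entropic surprise ``E_i = -log2 mu_i`` — high for weakly connected nodes
  (``sum_i mu_i E_i = H``);
* mutual surprise ``I1_i = sum_j P_ij log2(P_ij / mu_j)`` — the KL
  divergence from node *i*'s outgoing transition distribution to the
  stationary distribution; always nonnegative, high when a node connects
  to globally unlikely nodes (``sum_i mu_i I1_i = MI``);
* mutual predictability ``I2_i = H(mu) + sum_j P_ij log2 P_ij`` — how much
  observing the walker at node *i* reduces uncertainty about the next
  state; can be negative, and is the additive decomposition of MI
  (``sum_i mu_i I2_i = MI``);
* erasure surprise ``I1e_i`` — the KL divergence from the (past, future)
  pair distribution conditioned on the present node *i* to its
  unconditioned counterpart; nonnegative and high for bridge-like nodes
  lying on unique paths (``sum_i mu_i I1e_i = EMI``).

Isolated nodes (``mu_i = 0``) contribute nothing to the global measures;
their local values are not defined and are reported as NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MarkovModel
from .global_measures import entropy

__all__ = [
    "entropic_surprise",
    "mutual_surprise",
    "mutual_predictability",
    "erasure_surprise",
    "compute_local",
]


def _na_isolated(model: MarkovModel, values: np.ndarray) -> np.ndarray:
    values = values.astype(float)
    values[model.isolated] = np.nan
    return values


def entropic_surprise(model: MarkovModel) -> np.ndarray:
    """``E_i = -log2 mu_i`` in bits; NaN for isolated nodes.

    Equals ``log2(C_T) - log2(strength_i)``, i.e. an exact log transform
    of the classical node strength.
    """
    with np.errstate(divide="ignore"):
        E = -np.log2(model.mu)
    return _na_isolated(model, E)


def mutual_surprise(model: MarkovModel) -> np.ndarray:
    """``I1_i = sum_j P_ij log2(P_ij / mu_j)`` in bits; NaN for isolated nodes.

    For a connected node every reachable neighbour has positive stationary
    mass, so the KL divergence is finite and nonnegative.
    """
    P, mu = model.P, model.mu
    nz = P > 0
    # P_ij > 0 implies mu_j > 0 on an undirected graph
    ratio = np.where(nz, P / np.where(nz, mu[None, :], 1.0), 1.0)
    I1 = (np.where(nz, P * np.log2(ratio), 0.0)).sum(axis=1)
    return _na_isolated(model, I1)


def mutual_predictability(model: MarkovModel) -> np.ndarray:
    """``I2_i = H(mu) + sum_j P_ij log2 P_ij`` in bits; NaN for isolated nodes.

    The stationary entropy minus the entropy of node *i*'s outgoing
    transition distribution; negative when a node's connections are more
    uncertain than the network average.
    """
    P = model.P
    nz = P > 0
    row_ent = -(np.where(nz, P * np.log2(np.where(nz, P, 1.0)), 0.0)).sum(axis=1)
    return _na_isolated(model, entropy(model) - row_ent)


def erasure_surprise(model: MarkovModel) -> np.ndarray:
    """Erasure surprise ``I1e_i`` in bits; NaN for isolated nodes.

    ``I1e_i = sum_jk p(j, k | i) log2( p(j, k | i) / p(j, k) )`` where
    ``p(j, k | i)`` is the probability that the walk sat at *j* one step
    before and at *k* one step after a visit to *i*, and
    ``p(j, k) = mu_j Q_jk`` with ``Q_jk = sum_i P_ji P_ik`` is the
    two-step pair marginal.  The backward step distribution follows from
    Bayes' rule, ``p(Xt-1 = j | Xt = i) = mu_j P_ji / mu_i``, which by
    detailed balance equals the forward row ``P_ij`` — so
    ``p(j, k | i) = P_ij P_ik``.  Pairs with ``Q_jk = 0`` necessarily have
    zero conditional probability and contribute nothing.
    """
    P, mu = model.P, model.mu
    n = model.n
    Q = P @ P
    # log2 of the pair marginal p(j, k) = mu_j Q_jk, zero-filled where empty
    marg_nz = (mu[:, None] > 0) & (Q > 0)
    log_marg = np.where(
        marg_nz, np.log2(np.where(marg_nz, mu[:, None] * Q, 1.0)), 0.0
    )
    I1e = np.zeros(n)
    for i in range(n):
        if model.isolated[i]:
            continue
        cond = np.outer(P[i], P[i])  # p(j, k | i) = P_ij P_ik by detailed balance
        nz = cond > 0
        log_cond = np.where(nz, np.log2(np.where(nz, cond, 1.0)), 0.0)
        I1e[i] = float((cond * np.where(nz, log_cond - log_marg, 0.0)).sum())
    return _na_isolated(model, I1e)


def compute_local(model: MarkovModel) -> pd.DataFrame:
    """Per-node table of strength and the four local measures.

    Returns a DataFrame indexed by node label with columns
    ``strength, E, I1, I2, I1e`` (measures in bits, NaN for isolated
    nodes).
    """
    return pd.DataFrame(
        {
            "strength": model.strengths,
            "E": entropic_surprise(model),
            "I1": mutual_surprise(model),
            "I2": mutual_predictability(model),
            "I1e": erasure_surprise(model),
        },
        index=pd.Index(model.labels, name="node_label"),
    )
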