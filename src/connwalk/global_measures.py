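"""Whole-network information measures of the stationary random walk.

Three scalars, all in bits, summarize the network at three temporal levels:

* stationary — the Shannon entropy of the stationary distribution,
  ``H(mu) = -sum_i mu_i log2 mu_i``;
* causal — the mutual information between consecutive walk states,
  ``I(Xt; Xt+1) = H(mu) - H(Xt+1 | Xt)``, which for a stationary Markov
  chain equals the excess entropy and hence quantifies structure;
* contextual — the erasure mutual information
  ``I-(X) = H(mu) - H(Xt | Xt-1, Xt+1)``, the information gained about the
  present state from knowing both its past and its future neighbours in
  the walk.  High values indicate networks whose paths are unique.

The ordering ``0 <= MI <= EMI <= H`` always holds: conditioning on the
future in addition to the past cannot increase the conditional entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import MarkovModel

__all__ = [
    "GlobalMeasures",
    "entropy",
    "conditional_entropy_past",
    "mutual_information",
    "conditional_entropy_context",
    "erasure_mutual_information",
    "compute_global",
]

# negative results below this magnitude are floating-point cancellation; any
# larger negative value indicates an internal inconsistency and is raised
_CLAMP = 1e-9


def _xlog2x(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the convention 0 log 0 = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _clamp_nonneg(value: float, name: str) -> float:
    if value < 0.0:
        if value < -_CLAMP:
            raise FloatingPointError(f"{name} = {value}: negative beyond cancellation tolerance")
        return 0.0
    return value


@dataclass(frozen=True)
class GlobalMeasures:
    """Record of the three global measures and their conditional entropies.

    All fields are in bits.
    """

    H: float
    MI: float
    EMI: float
    H_cond_past: float
    H_cond_context: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def entropy(model: MarkovModel) -> float:
    """Stationary entropy ``H(mu)`` in bits; lies in ``[0, log2 n]``."""
    return _clamp_nonneg(-float(_xlog2x(model.mu).sum()), "H")


def conditional_entropy_past(model: MarkovModel) -> float:
    """Entropy rate ``H(Xt+1 | Xt) = -sum_i mu_i sum_j P_ij log2 P_ij``."""
    row_ent = -_xlog2x(model.P).sum(axis=1)
    return _clamp_nonneg(float(model.mu @ row_ent), "H(Xt+1|Xt)")


def mutual_information(model: MarkovModel) -> float:
    """Mutual information ``I(Xt; Xt+1)`` between consecutive states, in bits."""
    return _clamp_nonneg(entropy(model) - conditional_entropy_past(model), "MI")


def conditional_entropy_context(model: MarkovModel) -> float:
    """Erasure entropy of the chain, ``H(Xt | Xt-1, Xt+1)``, in bits.

    Computed from the triple joint ``p(j, i, k) = mu_j P_ji P_ik`` over
    (past, present, future) without materializing the n^3 array: summing
    the ``log2 P_ji`` and ``log2 P_ik`` factors over the free indices
    reduces each to the entropy rate, leaving only the two-step marginal
    ``Q_jk = sum_i P_ji P_ik``:

        H(Xt | Xt-1, Xt+1) = 2 h + sum_jk mu_j Q_jk log2 Q_jk,

    with ``h = H(Xt+1 | Xt)``.  The reduction uses stationarity
    (``mu P = mu``) and row-stochasticity, both exact for the chain built
    from a nonempty graph.
    """
    h = conditional_entropy_past(model)
    Q = model.P @ model.P
    two_step = float((model.mu[:, None] * _xlog2x(Q)).sum())
    return _clamp_nonneg(2.0 * h + two_step, "H(Xt|Xt-1,Xt+1)")


def erasure_mutual_information(model: MarkovModel) -> float:
    """Erasure mutual information ``I-(X) = H(mu) - H(Xt | Xt-1, Xt+1)``, bits."""
    return _clamp_nonneg(entropy(model) - conditional_entropy_context(model), "EMI")


def compute_global(model: MarkovModel) -> GlobalMeasures:
    """Compute all global measures in one pass."""
    H = entropy(model)
    h = conditional_entropy_past(model)
    hcc = conditional_entropy_context(model)
    return GlobalMeasures(
        H=H,
        MI=_clamp_nonneg(H - h, "MI"),
        EMI=_clamp_nonneg(H - hcc, "EMI"),
        H_cond_past=h,
        H_cond_context=hcc,
    )
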