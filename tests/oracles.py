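"""Brute-force oracles used to cross-check the measure implementations.

Everything here materializes full joint distributions (pairs for the
one-step measures, the n^3 triple array for the context measures) and
applies the defining entropy/KL sums term by term, independently of the
algebraic shortcuts used in the package.
"""

from __future__ import annotations

import numpy as np


def walk_distributions(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stationary distribution and transition matrix by plain loops."""
    n = C.shape[0]
    strengths = [sum(C[i]) for i in range(n)]
    total = sum(strengths)
    mu = np.array([s / total for s in strengths])
    P = np.zeros((n, n))
    for i in range(n):
        if strengths[i] > 0:
            for j in range(n):
                P[i, j] = C[i, j] / strengths[i]
    return mu, P


def _plogp(p: float) -> float:
    return p * np.log2(p) if p > 0 else 0.0


def global_measures(C: np.ndarray) -> dict[str, float]:
    """All five global quantities from explicit pair/triple joints."""
    mu, P = walk_distributions(C)
    n = C.shape[0]
    H = -sum(_plogp(m) for m in mu)

    # pair joint p(i, j) = mu_i P_ij
    pair = np.array([[mu[i] * P[i, j] for j in range(n)] for i in range(n)])
    MI = 0.0
    for i in range(n):
        for j in range(n):
            if pair[i, j] > 0:
                MI += pair[i, j] * np.log2(pair[i, j] / (mu[i] * mu[j]))
    H_cond_past = 0.0
    for i in range(n):
        for j in range(n):
            if pair[i, j] > 0:
                H_cond_past -= pair[i, j] * np.log2(P[i, j])

    # triple joint p(j, i, k) = mu_j P_ji P_ik over (past, present, future)
    triple = np.zeros((n, n, n))
    for j in range(n):
        for i in range(n):
            for k in range(n):
                triple[j, i, k] = mu[j] * P[j, i] * P[i, k]
    pair_jk = triple.sum(axis=1)  # p(past, future)
    H_cond_context = 0.0
    for j in range(n):
        for i in range(n):
            for k in range(n):
                t = triple[j, i, k]
                if t > 0:
                    H_cond_context -= t * np.log2(t / pair_jk[j, k])
    return {
        "H": H,
        "MI": MI,
        "EMI": H - H_cond_context,
        "H_cond_past": H_cond_past,
        "H_cond_context": H_cond_context,
    }


def local_measures(C: np.ndarray) -> dict[str, np.ndarray]:
    """All four local vectors from term-by-term enumeration (NaN when isolated)."""
    mu, P = walk_distributions(C)
    n = C.shape[0]
    E = np.full(n, np.nan)
    I1 = np.full(n, np.nan)
    I2 = np.full(n, np.nan)
    I1e = np.full(n, np.nan)
    H = -sum(_plogp(m) for m in mu)

    triple = np.zeros((n, n, n))
    for j in range(n):
        for i in range(n):
            for k in range(n):
                triple[j, i, k] = mu[j] * P[j, i] * P[i, k]
    pair_jk = triple.sum(axis=1)

    for i in range(n):
        if mu[i] == 0:
            continue
        E[i] = -np.log2(mu[i])
        I1[i] = sum(
            P[i, j] * np.log2(P[i, j] / mu[j]) for j in range(n) if P[i, j] > 0
        )
        row_ent = -sum(_plogp(P[i, j]) for j in range(n))
        I2[i] = H - row_ent
        acc = 0.0
        for j in range(n):
            for k in range(n):
                cond = triple[j, i, k] / mu[i]  # p(j, k | present = i)
                if cond > 0:
                    acc += cond * np.log2(cond / pair_jk[j, k])
        I1e[i] = acc
    return {"E": E, "I1": I1, "I2": I2, "I1e": I1e}
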