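"""Classical node measures and their comparison with the information measures.

Strength, eccentricity and weighted clustering are the standard descriptors
that the information measures are benchmarked against.  ``correlate_measures``
fits the logarithmic curve ``f(x) = a + b log2(x)`` of a local information
measure against a classical measure and reports the coefficient of
determination R^2, the form used to compare node measures on connectome data.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .core import ConnectivityMatrix

__all__ = [
    "strength",
    "eccentricity",
    "clustering",
    "compute_reference",
    "LogFit",
    "fit_log_curve",
    "correlate_measures",
]


def strength(C: ConnectivityMatrix) -> np.ndarray:
    """Node strength: sum of incident edge weights, ``C_i = sum_j C_ij``."""
    return C.C.sum(axis=1)


def eccentricity(C: ConnectivityMatrix, weighted: bool = True) -> np.ndarray:
    """Maximal shortest-path distance from each node to any reachable node.

    With ``weighted=True`` (default) edge length is the inverse of the
    connection weight, the usual connectivity-to-length mapping; with
    ``weighted=False`` every edge has unit length (binarized graph).
    Nodes in graphs that are not connected get NaN: their eccentricity
    over the whole node set is not defined.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(C.C > 0, 1.0 / np.where(C.C > 0, C.C, 1.0), 0.0)
    if not weighted:
        lengths = (C.C > 0).astype(float)
    dist = dijkstra(lengths, directed=False, unweighted=False)
    np.fill_diagonal(dist, 0.0)
    ecc = dist.max(axis=1)
    ecc[~np.isfinite(ecc)] = np.nan
    return ecc


def _graph(C: ConnectivityMatrix) -> nx.Graph:
    G = nx.from_numpy_array(C.C)
    return G


def clustering(C: ConnectivityMatrix) -> np.ndarray:
    """Weighted clustering coefficient per node, in [0, 1].

    Uses the geometric-mean-of-triangle-weights formulation with weights
    normalized by the maximum weight in the graph (the standard weighted
    undirected variant); nodes with degree < 2 score 0.
    """
    cc = nx.clustering(_graph(C), weight="weight")
    return np.array([cc[i] for i in range(C.n)], dtype=float)


def compute_reference(C: ConnectivityMatrix, weighted_ecc: bool = True) -> pd.DataFrame:
    """Table of the three classical measures, indexed by node label."""
    return pd.DataFrame(
        {
            "strength": strength(C),
            "eccentricity": eccentricity(C, weighted=weighted_ecc),
            "clustering": clustering(C),
        },
        index=pd.Index(C.labels, name="node_label"),
    )


@dataclass(frozen=True)
class LogFit:
    """Least-squares fit of ``y = a + b log2(x)`` with determination R^2."""

    a: float
    b: float
    r2: float
    n_points: int


def fit_log_curve(x: np.ndarray, y: np.ndarray) -> LogFit:
    """Fit ``y = a + b log2(x)`` by least squares; R^2 = 1 - SS_res / SS_tot.

    Pairs with NaN in either coordinate or with ``x <= 0`` (where the log
    curve is undefined) are dropped.  Raises ``ValueError`` with fewer
    than 3 valid pairs.  A constant ``y`` yields R^2 = 0 by convention
    (no variance to explain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 valid (x, y) pairs, got {x.size}")
    lx = np.log2(x)
    if np.ptp(lx) == 0.0:
        # degenerate abscissa: only the intercept is identifiable
        b, a = 0.0, float(y.mean())
    else:
        b, a = np.polyfit(lx, y, deg=1)
    resid = y - (a + b * lx)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return LogFit(a=float(a), b=float(b), r2=r2, n_points=int(x.size))


def correlate_measures(local: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Fit every (local measure, classical measure) pair on a log curve.

    Parameters
    ----------
    local:
        Per-node local-measure table (columns such as E, I1, I2, I1e).
    ref:
        Per-node classical-measure table (strength, eccentricity,
        clustering) on the same node index.

    Returns
    -------
    DataFrame with one row per pair and columns
    ``local, reference, a, b, r2, n_points``.  A pair without enough
    valid points (for example clustering on a triangle-free graph, where
    every abscissa is 0) is reported with NaN coefficients; if no pair
    can be fitted at all, ``ValueError`` is raised.
    """
    if not local.index.equals(ref.index):
        raise ValueError("local and reference tables must share the same node index")
    rows = []
    fitted = 0
    local_cols = [c for c in local.columns if c != "strength"]
    for lc in local_cols:
        for rc in ref.columns:
            try:
                fit = fit_log_curve(ref[rc].to_numpy(), local[lc].to_numpy())
                fitted += 1
            except ValueError:
                fit = LogFit(a=np.nan, b=np.nan, r2=np.nan, n_points=0)
            rows.append(
                {"local": lc, "reference": rc, "a": fit.a, "b": fit.b,
                 "r2": fit.r2, "n_points": fit.n_points}
            )
    if rows and fitted == 0:
        raise ValueError("no (local, reference) pair has at least 3 valid points")
    return pd.DataFrame(rows)
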