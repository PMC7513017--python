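"""Synthetic network families and the sweep experiments that characterize them.

Four weighted undirected families with an exact, user-chosen number of
undirected edges ``m``:

* ``random`` — ``m`` distinct node pairs sampled uniformly;
* ``lattice`` — edges placed as close to the matrix diagonal as possible,
  without wraparound, so end nodes have fewer connections;
* ``ring_lattice`` — the same band-filling on ring distance, with
  wraparound, giving a near-regular graph;
* ``small_world`` — contiguous fully connected modules of ``cluster_size``
  nodes plus uniformly random inter-module edges, combining the high
  clustering of a lattice with the short paths of a random graph.

Edge weights are drawn i.i.d. uniform on (0, 1) after the topology is
fixed, so edge presence and positive weight coincide.  Two sweep drivers
reproduce the canonical experiments: scanning the edge count at fixed
``n``, and scanning ``n`` at fixed edge density.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, build_model
from .global_measures import compute_global

__all__ = ["FAMILIES", "NetworkSpec", "generate", "edge_sweep", "node_sweep"]

FAMILIES = ("random", "lattice", "ring_lattice", "small_world")


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of one synthetic-network draw.

    ``m`` counts undirected edges; values above the complete-graph total
    ``n(n-1)/2`` are clamped to it (the canonical edge grids deliberately
    overshoot the complete graph).  ``cluster_size`` is the number of
    nodes per fully connected module and only applies to ``small_world``.
    """

    family: str
    n: int
    m: int
    cluster_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if self.m < 1:
            raise ValueError("need at least 1 edge")
        if self.family == "small_world" and self.cluster_size < 2:
            raise ValueError("cluster_size must be at least 2")

    @property
    def m_max(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def m_effective(self) -> int:
        return min(self.m, self.m_max)


def _random_edges(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    pairs = list(itertools.combinations(range(n), 2))
    idx = rng.choice(len(pairs), size=m, replace=False)
    return [pairs[i] for i in idx]


def _lattice_edges(n: int, m: int) -> list[tuple[int, int]]:
    # fill bands |i - j| = k for k = 1, 2, ... ; partial band in index order
    edges: list[tuple[int, int]] = []
    for k in range(1, n):
        for i in range(n - k):
            edges.append((i, i + k))
            if len(edges) == m:
                return edges
    return edges


def _ring_lattice_edges(n: int, m: int) -> list[tuple[int, int]]:
    # bands of ring distance k = 1, 2, ..., floor(n/2), wrapping around
    edges: list[tuple[int, int]] = []
    for k in range(1, n // 2 + 1):
        span = n // 2 if (n % 2 == 0 and k == n // 2) else n
        for i in range(span):
            j = (i + k) % n
            edges.append((min(i, j), max(i, j)))
            if len(edges) == m:
                return edges
    return edges


def _small_world_edges(
    n: int, m: int, cluster_size: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    modules = [
        list(range(start, min(start + cluster_size, n)))
        for start in range(0, n, cluster_size)
    ]
    module_of = np.empty(n, dtype=int)
    for mi, mod in enumerate(modules):
        module_of[mod] = mi
    intra = [
        (i, j) for mod in modules for i, j in itertools.combinations(mod, 2)
    ]
    if m <= len(intra):
        idx = rng.choice(len(intra), size=m, replace=False)
        return [intra[i] for i in idx]
    inter = [
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if module_of[i] != module_of[j]
    ]
    extra = m - len(intra)
    idx = rng.choice(len(inter), size=extra, replace=False)
    return intra + [inter[i] for i in idx]


def generate(spec: NetworkSpec) -> ConnectivityMatrix:
    """Draw one weighted undirected network from a :class:`NetworkSpec`.

    The same spec (including seed) always yields a bit-identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m_effective
    if spec.family == "random":
        edges = _random_edges(n, m, rng)
    elif spec.family == "lattice":
        edges = _lattice_edges(n, m)
    elif spec.family == "ring_lattice":
        edges = _ring_lattice_edges(n, m)
    else:
        edges = _small_world_edges(n, m, spec.cluster_size, rng)
    weights = rng.random(len(edges))
    while np.any(weights == 0.0):  # open interval (0, 1): presence == positive weight
        weights[weights == 0.0] = rng.random(int((weights == 0.0).sum()))
    C = np.zeros((n, n))
    rows, cols = zip(*edges)
    C[rows, cols] = weights
    return ConnectivityMatrix(C + C.T)


def _sweep_rows(specs, replicates: int, seed: int):
    """Run generate -> model -> global measures over a grid of (family, n, m)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(specs) * replicates) % (2**31)
    rows = []
    k = 0
    for family, n, m, cluster_size in specs:
        for rep in range(replicates):
            run_seed = int(child_seeds[k])
            k += 1
            spec = NetworkSpec(family=family, n=n, m=m,
                               cluster_size=cluster_size, seed=run_seed)
            model = build_model(generate(spec))
            g = compute_global(model)
            rows.append(
                {"family": family, "n": n, "m": spec.m_effective,
                 "replicate": rep, "seed": run_seed, **g.as_dict()}
            )
    return pd.DataFrame(rows)


def edge_sweep(
    family: str,
    n: int,
    m_values,
    replicates: int = 10,
    seed: int = 0,
    cluster_size: int = 2,
) -> pd.DataFrame:
    """Global measures across an edge-count grid at fixed node count.

    Returns a long-format table with one row per (m, replicate) and
    columns ``family, n, m, replicate, seed, H, MI, EMI, H_cond_past,
    H_cond_context``.
    """
    specs = [(family, n, int(m), cluster_size) for m in m_values]
    return _sweep_rows(specs, replicates, seed)


def node_sweep(
    family: str,
    n_values,
    density: float = 0.4,
    replicates: int = 10,
    seed: int = 0,
    cluster_size: int = 2,
) -> pd.DataFrame:
    """Global measures across a node-count grid at fixed edge density."""
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    specs = []
    for n in n_values:
        n = int(n)
        m = max(1, round(density * n * (n - 1) / 2))
        specs.append((family, n, m, cluster_size))
    return _sweep_rows(specs, replicates, seed)
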