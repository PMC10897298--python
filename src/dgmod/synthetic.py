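"""Seeded planted-partition benchmark generators.

:func:`generate_planted` emulates LFR-style benchmarks: community sizes
and node degrees drawn from truncated power laws (exponents ``beta`` and
``gamma``), and each node's edges split internal/external according to
the mixing parameter mu — the fraction of a node's edges that leave its
planted community (mu = 0: all edges internal; mu = 1: all external).
Wiring uses configuration-model stub pairing with rejection of
self-loops, duplicate edges and (for external stubs) same-community
pairs; a handful of unmatched stubs may be dropped, so the instance
reports its *realized* mixing fraction.

:func:`ring_of_cliques` is a small structured fixture: k cliques of size
s joined in a ring by single bridge edges, with the cliques as the
planted partition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GenerationError, ValidationError
from .evaluation import nmi
from .graph import ReferencePartition
from .greedy import run_greedy
from .search import DGMConfig, run_dgm

__all__ = ["LFRConfig", "PlantedGraph", "generate_planted", "ring_of_cliques", "mu_sweep"]


@dataclass(frozen=True)
class LFRConfig:
    """Planted-partition generator parameters.

    Defaults follow the benchmark conditions used throughout the tests:
    n = 250 nodes, degree exponent gamma = 3, community-size exponent
    beta = 1.5, communities of 20-50 nodes, mean degree ~10.
    """

    n: int = 250
    mu: float = 0.1
    gamma: float = 3.0
    beta: float = 1.5
    avg_degree: float = 10.0
    min_community: int = 20
    max_community: int = 50
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self):
        if self.n < 10:
            raise ValidationError("need n >= 10")
        if not 0.0 <= self.mu <= 1.0:
            raise ValidationError("mu must lie in [0, 1]")
        if self.gamma <= 1 or self.beta <= 1:
            raise ValidationError("power-law exponents must exceed 1")
        if not 2 <= self.min_community <= self.max_community:
            raise ValidationError("bad community size bounds")
        if self.avg_degree < 2:
            raise ValidationError("avg_degree must be >= 2")


@dataclass(frozen=True)
class PlantedGraph:
    graph: nx.Graph
    planted: ReferencePartition
    realized_mu: float


def _truncated_power_law(rng: np.random.Generator, size: int,
                         exponent: float, lo: float, hi: float) -> np.ndarray:
    """Continuous inverse-CDF sampling of x^-exponent on [lo, hi]."""
    u = rng.random(size)
    a = 1.0 - exponent
    return (lo ** a + u * (hi ** a - lo ** a)) ** (1.0 / a)


def _power_law_mean(exponent: float, lo: float, hi: float) -> float:
    a1, a2 = 1.0 - exponent, 2.0 - exponent
    if abs(a2) < 1e-12:
        return a1 * np.log(hi / lo) / (hi ** a1 - lo ** a1)
    return (a1 / a2) * (hi ** a2 - lo ** a2) / (hi ** a1 - lo ** a1)


def _degree_sequence(rng: np.random.Generator, cfg: LFRConfig) -> np.ndarray:
    """Integer degrees with power-law tail, truncated to [2, n/10]."""
    k_max = max(int(cfg.n / 10), 3)
    lo_floor = 1.5
    if _power_law_mean(cfg.gamma, lo_floor, k_max) >= cfg.avg_degree:
        lo = lo_floor
    elif _power_law_mean(cfg.gamma, k_max - 1e-6, k_max) <= cfg.avg_degree:
        lo = k_max - 1e-6
    else:
        lo = brentq(
            lambda x: _power_law_mean(cfg.gamma, x, k_max) - cfg.avg_degree,
            lo_floor, k_max - 1e-6,
        )
    raw = _truncated_power_law(rng, cfg.n, cfg.gamma, lo, k_max)
    return np.clip(np.rint(raw).astype(int), 2, k_max)


def _community_sizes(rng: np.random.Generator, cfg: LFRConfig) -> list[int]:
    sizes: list[int] = []
    while sum(sizes) < cfg.n:
        s = int(
            np.rint(
                _truncated_power_law(
                    rng, 1, cfg.beta, cfg.min_community, cfg.max_community
                )[0]
            )
        )
        sizes.append(int(np.clip(s, cfg.min_community, cfg.max_community)))
    excess = sum(sizes) - cfg.n
    # shave the excess off the largest communities, one node at a time
    while excess > 0:
        i = max(range(len(sizes)), key=lambda j: sizes[j])
        if sizes[i] <= cfg.min_community:
            break
        sizes[i] -= 1
        excess -= 1
    if excess > 0:  # still over: drop the last community, redistribute
        sizes.pop()
        deficit = cfg.n - sum(sizes)
        i = 0
        while deficit > 0 and sizes:
            if sizes[i % len(sizes)] < cfg.max_community:
                sizes[i % len(sizes)] += 1
                deficit -= 1
            i += 1
            if i > 10 * cfg.n:
                raise GenerationError("cannot fit community sizes to n")
    if len(sizes) < 2:
        half = cfg.n // 2
        sizes = [half, cfg.n - half]
    return sizes


def _pair_stubs(rng: np.random.Generator, stubs: list[int],
                ok, edges: set, retries: int = 60) -> int:
    """Randomly pair stubs into edges accepted by ``ok``; returns the
    number of edges added.  Rejected stubs are re-shuffled a bounded
    number of times, then dropped."""
    added = 0
    pool = list(stubs)
    for _ in range(retries):
        if len(pool) < 2:
            break
        perm = rng.permutation(len(pool))
        pool = [pool[i] for i in perm]
        leftover: list[int] = []
        for i in range(0, len(pool) - 1, 2):
            u, v = pool[i], pool[i + 1]
            key = (u, v) if u < v else (v, u)
            if u == v or key in edges or not ok(u, v):
                leftover.extend((u, v))
            else:
                edges.add(key)
                added += 1
        if len(pool) % 2:
            leftover.append(pool[-1])
        if len(leftover) == len(pool):
            break  # no progress possible
        pool = leftover
    return added


def generate_planted(config: LFRConfig) -> PlantedGraph:
    """Generate a seeded planted-partition graph; reports realized mu."""
    last_err = None
    for attempt in range(config.max_retries):
        rng = np.random.default_rng(config.seed + 7919 * attempt)
        try:
            return _generate_once(rng, config)
        except GenerationError as err:
            last_err = err
    raise GenerationError(f"generation failed after retries: {last_err}")


def _generate_once(rng: np.random.Generator, cfg: LFRConfig) -> PlantedGraph:
    degrees = _degree_sequence(rng, cfg)
    sizes = _community_sizes(rng, cfg)

    k_int = np.rint((1.0 - cfg.mu) * degrees).astype(int)
    k_int = np.minimum(k_int, degrees)

    # assign nodes to communities, high internal degree first, so that a
    # node's internal degree always fits inside its community
    order = sorted(range(cfg.n), key=lambda v: -k_int[v])
    remaining = list(sizes)
    comm_of = np.empty(cfg.n, dtype=int)
    max_size = max(sizes)
    for v in order:
        if k_int[v] > max_size - 1:
            k_int[v] = max_size - 1
        eligible = [
            c for c in range(len(sizes))
            if remaining[c] > 0 and sizes[c] - 1 >= k_int[v]
        ]
        if not eligible:
            open_comms = [c for c in range(len(sizes)) if remaining[c] > 0]
            if not open_comms:
                raise GenerationError("capacity exhausted during assignment")
            c = max(open_comms, key=lambda c: sizes[c])
            k_int[v] = sizes[c] - 1
        else:
            c = int(rng.choice(eligible))
        comm_of[v] = c
        remaining[c] -= 1

    # per-community parity of internal stubs
    for c in range(len(sizes)):
        members = np.flatnonzero(comm_of == c)
        if int(k_int[members].sum()) % 2:
            v = members[int(np.argmax(k_int[members]))]
            k_int[v] -= 1
    k_ext = degrees - k_int
    if int(k_ext.sum()) % 2:
        v = int(np.argmax(k_ext))
        k_ext[v] -= 1

    edges: set[tuple[int, int]] = set()
    for c in range(len(sizes)):
        members = np.flatnonzero(comm_of == c)
        stubs = [int(v) for v in members for _ in range(int(k_int[v]))]
        _pair_stubs(rng, stubs, lambda u, v: True, edges)
    ext_stubs = [int(v) for v in range(cfg.n) for _ in range(int(k_ext[v]))]
    cross = _pair_stubs(
        rng, ext_stubs, lambda u, v: comm_of[u] != comm_of[v], edges
    )

    if not edges:
        raise GenerationError("degenerate instance with no edges")
    g = nx.Graph()
    g.add_nodes_from(range(cfg.n))
    g.add_edges_from(edges)
    planted = ReferencePartition(
        {int(v): int(comm_of[v]) for v in range(cfg.n)}, source="planted"
    )
    realized_mu = cross / len(edges)
    if cfg.mu == 0.0 and cross:
        raise GenerationError("mu=0 instance acquired cross edges")
    return PlantedGraph(graph=g, planted=planted, realized_mu=realized_mu)


def ring_of_cliques(k: int, s: int) -> PlantedGraph:
    """k cliques of size s joined in a ring by single bridge edges."""
    if k < 3 or s < 3:
        raise ValidationError("need at least 3 cliques of size 3")
    g = nx.Graph()
    for i in range(k):
        base = i * s
        members = range(base, base + s)
        g.add_edges_from(
            (u, v) for u in members for v in members if u < v
        )
    for i in range(k):
        g.add_edge(i * s + s - 1, ((i + 1) % k) * s)
    planted = ReferencePartition(
        {v: v // s for v in g.nodes}, source="ring-of-cliques"
    )
    return PlantedGraph(
        graph=g, planted=planted, realized_mu=k / g.number_of_edges()
    )


def mu_sweep(mus, base: LFRConfig, dgm: DGMConfig, n_seeds: int = 1) -> pd.DataFrame:
    """For each mu: generate instances, run the greedy baseline and the
    DGM search, and score both against the planted partition.

    Returns one row per (mu, replicate): realized_mu, greedy_q, dgm_q,
    nmi_greedy, nmi_dgm.
    """
    rows = []
    for mu in mus:
        for j in range(n_seeds):
            cfg = replace(base, mu=float(mu), seed=base.seed + 1009 * j)
            inst = generate_planted(cfg)
            greedy_p, greedy_q = run_greedy(inst.graph)
            result = run_dgm(inst.graph, replace(dgm, seed=dgm.seed + 1009 * j))
            rows.append(
                {
                    "mu": float(mu),
                    "replicate": j,
                    "realized_mu": inst.realized_mu,
                    "greedy_q": greedy_q,
                    "dgm_q": result.best_q,
                    "nmi_greedy": nmi(greedy_p, inst.planted),
                    "nmi_dgm": nmi(result.best_partition, inst.planted),
                }
            )
    return pd.DataFrame(rows)
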