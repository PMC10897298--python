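"""Partition comparison and experiment reporting.

Normalized mutual information between two partitions U, V of the same
node set, from the co-membership contingency table:

    NMI(U, V) = 2 I(U; V) / (H(U) + H(V))

with I and H in any fixed log base (the ratio is base-invariant).
NMI is 1 for identical clusterings, 0 for independent ones.  Degenerate
zero-entropy cases: two single-community partitions are identical (1);
a single-community partition against a non-trivial one shares no
information (0, which the formula yields naturally).

Also here: the 20-cell community x node strategy grid and a small
partition-vs-reference report.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .graph import Partition, ReferencePartition, sort_key
from .greedy import run_greedy
from .metrics import mean_internal_density, modularity
from .search import DGMConfig, DGMResult, run_dgm
from .strategies import CommunityStrategy, NodeStrategy

__all__ = [
    "ContingencyTable",
    "nmi",
    "strategy_grid",
    "compare_to_reference",
    "GRID_COMMUNITY_ORDER",
    "GRID_NODE_ORDER",
]

# Row/column order of the published-style strategy grid.
GRID_COMMUNITY_ORDER = [
    CommunityStrategy.RANDOM,
    CommunityStrategy.WEAK,
    CommunityStrategy.HIGH_CONDUCTANCE,
    CommunityStrategy.LOW_TPR,
    CommunityStrategy.LOW_DENSITY,
]
GRID_NODE_ORDER = [
    NodeStrategy.RANDOM,
    NodeStrategy.WEAK,
    NodeStrategy.NON_TRIAD,
    NodeStrategy.LOW_EMBEDDEDNESS,
]


@dataclass(frozen=True)
class ContingencyTable:
    """Co-membership counts between two partitions of the same n nodes."""

    counts: np.ndarray  # R x C integer matrix
    n: int

    @classmethod
    def from_partitions(cls, u: Partition, v: Partition) -> "ContingencyTable":
        if u.nodes != v.nodes:
            raise ValidationError("partitions cover different node sets")
        u_ids = sorted(u.communities, key=sort_key)
        v_ids = sorted(v.communities, key=sort_key)
        u_index = {cid: i for i, cid in enumerate(u_ids)}
        v_index = {cid: i for i, cid in enumerate(v_ids)}
        counts = np.zeros((len(u_ids), len(v_ids)), dtype=np.int64)
        for node in u.nodes:
            counts[u_index[u.community_of(node)], v_index[v.community_of(node)]] += 1
        return cls(counts=counts, n=len(u.nodes))

    @property
    def joint(self) -> np.ndarray:
        return self.counts / self.n


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(u: Partition, v: Partition) -> float:
    """Normalized mutual information between two partitions, in [0, 1]."""
    table = ContingencyTable.from_partitions(u, v)
    joint = table.joint
    pu = joint.sum(axis=1)
    pv = joint.sum(axis=0)
    hu, hv = _entropy(pu), _entropy(pv)
    if hu == 0.0 and hv == 0.0:
        return 1.0  # both trivial single-community partitions: identical
    mask = joint > 0
    mi = float(
        (joint[mask] * np.log(joint[mask] / np.outer(pu, pv)[mask])).sum()
    )
    value = 2.0 * mi / (hu + hv)
    # clamp float fuzz at the boundaries
    return min(1.0, max(0.0, value))


def strategy_grid(
    g: nx.Graph, base_config: DGMConfig, keep_results: bool = False
) -> pd.DataFrame:
    """Run the DGM search for all 20 community x node strategy pairs.

    Every cell shares the budget and seed policy of ``base_config``.
    Returns a 20-row frame (community_strategy, node_strategy, best_q)
    in the canonical grid order; with ``keep_results`` a ``result``
    column holds the full :class:`DGMResult` objects.
    """
    rows = []
    for cs in GRID_COMMUNITY_ORDER:
        for ns in GRID_NODE_ORDER:
            result: DGMResult = run_dgm(g, base_config.with_strategies(cs, ns))
            row = {
                "community_strategy": cs.value,
                "node_strategy": ns.value,
                "best_q": result.best_q,
            }
            if keep_results:
                row["result"] = result
            rows.append(row)
    return pd.DataFrame(rows)


def compare_to_reference(
    g: nx.Graph, p: Partition, ref: ReferencePartition
) -> dict:
    """Side-by-side report of a detected partition against a reference."""
    p.validate_against(g)
    ref.validate_against(g)
    return {
        "q_partition": modularity(g, p),
        "q_reference": modularity(g, ref),
        "communities_partition": len(p),
        "communities_reference": len(ref),
        "nmi": nmi(p, ref),
        "mean_density_partition": mean_internal_density(g, p),
        "mean_density_reference": mean_internal_density(g, ref),
    }


def greedy_baseline_q(g: nx.Graph) -> float:
    """Convenience: modularity reached by the plain greedy baseline."""
    _, q = run_greedy(g)
    return q
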