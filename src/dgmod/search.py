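"""The DGM driver: exploitation-exploration search over partitions.

Starting from the all-singleton partition, the search runs
``T = round(iter_multiplier * n)`` iterations.  Each iteration draws a
uniform variate u:

* ``u < p_comm``              -> community-disassembly move (if any target),
* ``u < p_comm + p_node``     -> node-disassembly move (if any target),
* otherwise                    -> exploitation: the single best
  positive-gain merge.

When exploitation is drawn but no positive merge exists (the search sits
at a local optimum), a *forced* escape move fires instead of wasting the
iteration: usually (90%) the finest perturbation — one node broken out
via the configured node strategy — and occasionally (10%) a coarse kick
that dissolves a uniformly random community.  The fine/coarse mix
matters: node-level escapes let improving single-node relocations
accumulate (each breakout is reattached optimally by the next merge),
while the occasional random community kick is what lets the search leave
basins that single-node moves cannot exit.  Forced escapes are disabled
when both exploration probabilities are zero, so that configuration
reduces exactly to the plain greedy baseline.

Modularity dips during exploration and climbs back during exploitation;
the result is the best (q, partition) snapshot seen anywhere in the run.
Restart r reseeds the stream with ``seed + r`` and the best is taken
across restarts.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import networkx as nx
import pandas as pd

from .errors import ConfigError, ValidationError
from .graph import Partition
from .greedy import AggState
from .strategies import (
    CommunityStrategy,
    NodeStrategy,
    disassemble_community,
    disassemble_node,
    select_community,
    select_node,
)

__all__ = ["DGMConfig", "DGMResult", "TrajectoryRecord", "run_dgm", "trajectory_summary"]


@dataclass(frozen=True)
class DGMConfig:
    """Search parameters.

    ``p_node``/``p_comm`` are the per-iteration exploration probabilities
    (5% each by default); ``iter_multiplier`` scales the iteration budget
    ``T = round(iter_multiplier * n)`` (default 30, so the karate network
    with n=34 runs 1020 iterations).
    """

    node_strategy: NodeStrategy = NodeStrategy.RANDOM
    community_strategy: CommunityStrategy = CommunityStrategy.WEAK
    p_node: float = 0.05
    p_comm: float = 0.05
    iter_multiplier: float = 30.0
    seed: int = 0
    n_restarts: int = 1
    exploit_to_convergence: bool = False
    # share of forced escape moves (at a local optimum) that perturb a
    # single node rather than dissolving a random community
    escape_node_share: float = 0.9

    def __post_init__(self):
        object.__setattr__(self, "node_strategy", NodeStrategy(self.node_strategy))
        object.__setattr__(
            self, "community_strategy", CommunityStrategy(self.community_strategy)
        )
        if not (0.0 <= self.p_node <= 1.0 and 0.0 <= self.p_comm <= 1.0):
            raise ConfigError("exploration probabilities must lie in [0, 1]")
        if self.p_node + self.p_comm > 1.0:
            raise ConfigError("p_node + p_comm must not exceed 1")
        if self.iter_multiplier <= 0:
            raise ConfigError("iter_multiplier must be positive")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        if not 0.0 <= self.escape_node_share <= 1.0:
            raise ConfigError("escape_node_share must lie in [0, 1]")

    def with_strategies(self, community, node) -> "DGMConfig":
        return replace(
            self,
            community_strategy=CommunityStrategy(community),
            node_strategy=NodeStrategy(node),
        )


class TrajectoryRecord(NamedTuple):
    restart: int
    iteration: int
    action: str  # merge | node_disassembly | community_disassembly |
    #              forced_disassembly | noop
    q: float


@dataclass
class DGMResult:
    """Best partition found plus the full iteration trajectory."""

    best_partition: Partition
    best_q: float
    trajectory: list[TrajectoryRecord]
    config: DGMConfig
    seed: int

    @property
    def n_communities(self) -> int:
        return len(self.best_partition)


def run_dgm(g: nx.Graph, config: DGMConfig) -> DGMResult:
    """Run the disassembly-greedy-modularity search on ``g``."""
    if g.number_of_edges() < 1:
        raise ValidationError("DGM needs a graph with at least one edge")
    n = g.number_of_nodes()
    T = max(1, round(config.iter_multiplier * n))
    p_comm, p_node = config.p_comm, config.p_node

    best_q = -math.inf
    best_assignment: Optional[dict] = None
    trajectory: list[TrajectoryRecord] = []

    for r in range(config.n_restarts):
        rng = random.Random(config.seed + r)
        state = AggState.from_singletons(g)
        if state.q > best_q:
            best_q = state.q
            best_assignment = dict(state.node_comm)

        for it in range(T):
            u = rng.random()
            action = "noop"
            if u < p_comm:
                c = select_community(state, config.community_strategy, rng)
                if c is not None:
                    disassemble_community(state, c)
                    action = "community_disassembly"
            elif u < p_comm + p_node:
                picked = select_node(state, config.node_strategy, rng)
                if picked is not None:
                    disassemble_node(state, *picked)
                    action = "node_disassembly"
            else:
                mv = state.best_merge(positive_only=True)
                if mv is not None:
                    state.apply_merge(mv[0], mv[1])
                    action = "merge"
                    if config.exploit_to_convergence:
                        while (mv := state.best_merge(positive_only=True)) is not None:
                            state.apply_merge(mv[0], mv[1])
                elif p_comm + p_node > 0.0:
                    # local optimum: forced escape (fine node perturbation,
                    # occasionally a coarse random community kick)
                    escaped = False
                    if rng.random() < config.escape_node_share:
                        picked = select_node(state, config.node_strategy, rng)
                        if picked is not None:
                            disassemble_node(state, *picked)
                            action = "forced_node_disassembly"
                            escaped = True
                    if not escaped:
                        c = select_community(state, CommunityStrategy.RANDOM, rng)
                        if c is not None:
                            disassemble_community(state, c)
                            action = "forced_community_disassembly"
            if state.q > best_q:
                best_q = state.q
                best_assignment = dict(state.node_comm)
            trajectory.append(TrajectoryRecord(r, it, action, state.q))

    assert best_assignment is not None
    return DGMResult(
        best_partition=Partition(best_assignment),
        best_q=best_q,
        trajectory=trajectory,
        config=config,
        seed=config.seed,
    )


def trajectory_summary(result: DGMResult) -> pd.DataFrame:
    """Per-iteration table (restart, iteration, action, q, running_max)
    for plotting exploration/exploitation curves; running_max is
    non-decreasing and ends at ``best_q``."""
    if not result.trajectory:
        raise ValidationError("empty trajectory")
    frame = pd.DataFrame(result.trajectory)
    frame["running_max"] = frame["q"].cummax()
    return frame
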