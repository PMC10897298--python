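"""Disassembly exploration moves.

Nine stochastic moves that undo part of the current agglomeration so the
greedy phase can rebuild it differently: four node strategies (pick one
node, break it out as a singleton, split the remainder of its community
into connected components) and five community strategies (dissolve a
whole community into singletons).

Selection criteria, in field terms:

* node ``random`` — uniform member of a uniform multi-node community;
* node ``weak`` — internal degree <= external degree (and internal
  degree >= 2, so the node is actually embedded somewhere);
* node ``low_embeddedness`` — globally minimal fraction of neighbors
  inside the own community;
* node ``non_triad`` — member of no internal triangle, in communities
  with more than 4 members;
* community ``random`` / ``weak`` / ``low_density`` / ``low_tpr`` /
  ``high_conductance``.

The ``weak`` community strategy only considers communities that fail the
weak-sense community test (summed internal degree exceeding summed
external degree, i.e. ``2*l_c > m_out``); among those failures it picks
the one with the smallest internal-minus-external edge balance.  When
every community passes the test — the typical situation once a good
partition has assembled — the strategy selects nothing, which keeps the
exploration from endlessly dismantling well-formed communities.

Score-based selections break ties uniformly from the caller's seeded
RNG; a selection with an empty candidate set returns ``None`` and the
caller treats the iteration as a no-op.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError
from .graph import Node, induced_components, sort_key
from .greedy import AggState
from .metrics import (
    community_edge_balance,
    conductance,
    internal_edge_density,
    triad_nodes,
    triad_participation_ratio,
)


class NodeStrategy(str, enum.Enum):
    RANDOM = "random"
    WEAK = "weak"
    LOW_EMBEDDEDNESS = "low_embeddedness"
    NON_TRIAD = "non_triad"


class CommunityStrategy(str, enum.Enum):
    RANDOM = "random"
    WEAK = "weak"
    LOW_DENSITY = "low_density"
    LOW_TPR = "low_tpr"
    HIGH_CONDUCTANCE = "high_conductance"


@dataclass(frozen=True)
class Move:
    """Trajectory record of one executed disassembly."""

    kind: str  # "node" | "community"
    target_community: int
    target_node: Optional[Node]
    created_communities: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if (self.kind == "node") != (self.target_node is not None):
            raise ValidationError("target_node must be set iff kind == 'node'")


def _multi_node_communities(state: AggState) -> list[int]:
    return [c for c in sorted(state.members) if len(state.members[c]) > 1]


def _argmin_choice(scored: list[tuple[float, int]], rng: random.Random,
                   largest: bool = False) -> Optional[int]:
    """Uniform pick among the communities attaining the extreme score."""
    if not scored:
        return None
    target = max(s for s, _ in scored) if largest else min(s for s, _ in scored)
    candidates = [c for s, c in scored if s == target]
    return rng.choice(candidates)


def select_node(state: AggState, strategy: NodeStrategy,
                rng: random.Random) -> Optional[tuple[int, Node]]:
    """Pick a (community, node) disassembly target, or None.

    ``weak``/``low_embeddedness``/``non_triad`` score candidates globally
    across all eligible communities; ``random`` first picks a community.
    """
    strategy = NodeStrategy(strategy)
    g = state.graph
    eligible = _multi_node_communities(state)
    if not eligible:
        return None

    if strategy is NodeStrategy.RANDOM:
        c = rng.choice(eligible)
        v = rng.choice(sorted(state.members[c], key=sort_key))
        return c, v

    if strategy is NodeStrategy.WEAK:
        candidates = []
        for c in eligible:
            mem = state.members[c]
            for v in sorted(mem, key=sort_key):
                k_int = sum(1 for w in g[v] if w in mem)
                k_ext = g.degree(v) - k_int
                if k_ext >= k_int >= 2:
                    candidates.append((c, v))
        return rng.choice(candidates) if candidates else None

    if strategy is NodeStrategy.LOW_EMBEDDEDNESS:
        best_score = None
        candidates: list[tuple[int, Node]] = []
        for c in eligible:
            mem = state.members[c]
            for v in sorted(mem, key=sort_key):
                deg = g.degree(v)
                if deg == 0:
                    continue
                score = sum(1 for w in g[v] if w in mem) / deg
                if best_score is None or score < best_score:
                    best_score = score
                    candidates = [(c, v)]
                elif score == best_score:
                    candidates.append((c, v))
        return rng.choice(candidates) if candidates else None

    # NON_TRIAD: only communities with more than 4 members are inspected
    candidates = []
    for c in eligible:
        mem = state.members[c]
        if len(mem) <= 4:
            continue
        in_triads = triad_nodes(g, mem)
        candidates.extend((c, v) for v in sorted(mem - in_triads, key=sort_key))
    return rng.choice(candidates) if candidates else None


def select_community(state: AggState, strategy: CommunityStrategy,
                     rng: random.Random) -> Optional[int]:
    """Pick a community disassembly target, or None."""
    strategy = CommunityStrategy(strategy)
    eligible = _multi_node_communities(state)
    if not eligible:
        return None

    if strategy is CommunityStrategy.RANDOM:
        return rng.choice(eligible)

    if strategy is CommunityStrategy.WEAK:
        scored = []
        for c in eligible:
            st = state.stats(c)
            if 2 * st.l_c <= st.m_out:  # fails the weak-sense community test
                scored.append((community_edge_balance(st), c))
        return _argmin_choice(scored, rng)

    if strategy is CommunityStrategy.LOW_DENSITY:
        scored = [(internal_edge_density(state.stats(c)), c) for c in eligible]
        return _argmin_choice(scored, rng)

    if strategy is CommunityStrategy.LOW_TPR:
        scored = [
            (triad_participation_ratio(state.graph, state.members[c]), c)
            for c in eligible
        ]
        return _argmin_choice(scored, rng)

    # HIGH_CONDUCTANCE
    scored = []
    for c in eligible:
        st = state.stats(c)
        if 2 * st.l_c + st.m_out > 0:
            scored.append((conductance(st), c))
    return _argmin_choice(scored, rng, largest=True)


def disassemble_node(state: AggState, community: int, v: Node) -> tuple[AggState, Move]:
    """Break ``v`` out of its community as a singleton; the remainder
    splits into its connected components.  ``q`` may decrease."""
    state._require(community)
    mem = state.members[community]
    if v not in mem:
        raise ValidationError(f"node {v!r} is not in community {community}")
    if len(mem) < 2:
        raise ValidationError("cannot disassemble a singleton community")
    rest = mem - {v}
    groups = [{v}] + induced_components(state.graph, rest)
    new_ids = state.split_community(community, groups)
    return state, Move(
        kind="node",
        target_community=community,
        target_node=v,
        created_communities=tuple(new_ids),
    )


def disassemble_community(state: AggState, community: int) -> tuple[AggState, Move]:
    """Dissolve a community: every member becomes a singleton."""
    state._require(community)
    mem = state.members[community]
    if len(mem) < 2:
        raise ValidationError("cannot disassemble a singleton community")
    groups = [{u} for u in sorted(mem, key=sort_key)]
    new_ids = state.split_community(community, groups)
    return state, Move(
        kind="community",
        target_community=community,
        target_node=None,
        created_communities=tuple(new_ids),
    )
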