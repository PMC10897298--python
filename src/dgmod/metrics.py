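"""Community-quality metrics.

All metrics are unweighted.  Notation: for a community *c* of a graph with
``L`` edges, ``l_c`` is its internal edge count, ``k_c`` the summed degree
of its members and ``m_out`` its boundary edge count, so that
``k_c = 2*l_c + m_out`` always holds.

Modularity of a partition S is

    Q(S) = sum_c [ l_c / L  -  (k_c / (2L))^2 ]

which is 0 for the all-in-one partition and lies in [-1/2, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import networkx as nx

from .errors import UndefinedMetricError, ValidationError
from .graph import Node, Partition, sort_key


@dataclass(frozen=True)
class CommunityStats:
    """Edge/degree tallies of one community.

    ``l_c`` doubles as the ``m_s`` (density) and ``m_c`` (conductance)
    internal-edge count; ``m_out`` counts edges with exactly one endpoint
    inside.
    """

    n_s: int
    l_c: int
    k_c: int
    m_out: int

    def __post_init__(self):
        if min(self.n_s, self.l_c, self.k_c, self.m_out) < 0:
            raise ValidationError("community stats must be non-negative")
        if self.k_c != 2 * self.l_c + self.m_out:
            raise ValidationError(
                f"inconsistent community stats: k_c={self.k_c} != "
                f"2*{self.l_c} + {self.m_out}"
            )
        if self.l_c > self.n_s * (self.n_s - 1) // 2:
            raise ValidationError("more internal edges than a simple graph allows")


@dataclass(frozen=True)
class NodeDegreeSplit:
    """A node's neighbor counts inside (``k_int``) and outside (``k_ext``)
    its own community; ``k_v = k_int + k_ext``."""

    k_int: int
    k_ext: int

    @property
    def k_v(self) -> int:
        return self.k_int + self.k_ext


def community_stats(g: nx.Graph, members) -> CommunityStats:
    """Tally ``CommunityStats`` for an explicit member set."""
    members = set(members)
    l_c = 0
    k_c = 0
    for u in members:
        for w in g[u]:
            if w in members:
                l_c += 1
        k_c += g.degree(u)
    l_c //= 2
    return CommunityStats(n_s=len(members), l_c=l_c, k_c=k_c, m_out=k_c - 2 * l_c)


def modularity(g: nx.Graph, p: Partition) -> float:
    """Newman modularity Q of a partition (unweighted, L = edge count)."""
    L = g.number_of_edges()
    if L == 0:
        raise UndefinedMetricError("modularity is undefined on an edgeless graph")
    p.validate_against(g)
    q = 0.0
    for members in p.communities.values():
        st = community_stats(g, members)
        q += st.l_c / L - (st.k_c / (2 * L)) ** 2
    return q


def degree_split(g: nx.Graph, p: Partition, v: Node) -> NodeDegreeSplit:
    """Exact neighbor counts of ``v`` inside/outside its community."""
    if v not in g:
        raise ValidationError(f"node {v!r} not in graph")
    mine = p.members(p.community_of(v))
    k_int = sum(1 for w in g[v] if w in mine)
    return NodeDegreeSplit(k_int=k_int, k_ext=g.degree(v) - k_int)


def is_weak_node(split: NodeDegreeSplit) -> bool:
    """A node is weak when its internal degree does not exceed its external."""
    return split.k_int <= split.k_ext


def embeddedness(g: nx.Graph, p: Partition, v: Node) -> float:
    """Fraction of ``v``'s neighbors inside its own community, in [0, 1]."""
    split = degree_split(g, p, v)
    if split.k_v == 0:
        raise UndefinedMetricError(f"embeddedness undefined for isolated node {v!r}")
    return split.k_int / split.k_v


def triad_nodes(g: nx.Graph, members) -> set:
    """Members that belong to at least one triangle of the induced subgraph.

    Both co-members and both connecting edges must lie inside the induced
    subgraph.  Adding edges inside ``members`` can only grow the set.
    """
    members = set(members)
    adj = {u: [w for w in g[u] if w in members] for u in members}
    out = set()
    for u in members:
        if u in out:
            # u already proven; its triangle partners were added with it
            continue
        nbrs = adj[u]
        found = False
        for i, v in enumerate(nbrs):
            vn = set(adj[v])
            for w in nbrs[i + 1:]:
                if w in vn:
                    out.update((u, v, w))
                    found = True
                    break
            if found:
                break
    return out


def internal_edge_density(stats: CommunityStats) -> float:
    """Internal edges over the maximum possible, ``m_s / (n_s(n_s-1)/2)``."""
    if stats.n_s < 2:
        raise UndefinedMetricError("internal edge density undefined for singletons")
    return stats.l_c / (stats.n_s * (stats.n_s - 1) / 2)


def triad_participation_ratio(g: nx.Graph, members) -> float:
    """Fraction of members that sit in at least one internal triangle."""
    members = set(members)
    if not members:
        raise ValidationError("TPR of an empty set")
    return len(triad_nodes(g, members)) / len(members)


def conductance(stats: CommunityStats) -> float:
    """Boundary edges over all edge endpoints touching the community,
    ``m_out / (2 m_c + m_out)``.  High conductance = poorly separated."""
    denom = 2 * stats.l_c + stats.m_out
    if denom == 0:
        raise UndefinedMetricError("conductance undefined for an isolated singleton")
    return stats.m_out / denom


def community_edge_balance(stats: CommunityStats) -> int:
    """Internal minus external edge count, ``l_c - m_out``.

    The community with the smallest balance is the "weak community"
    disassembly target.
    """
    return stats.l_c - stats.m_out


def mean_internal_density(g: nx.Graph, p: Partition) -> float:
    """Unweighted mean of internal edge density over communities with
    at least two members (singletons are skipped)."""
    densities = [
        internal_edge_density(community_stats(g, members))
        for members in p.communities.values()
        if len(members) >= 2
    ]
    if not densities:
        raise UndefinedMetricError("no community with 2+ members")
    return fmean(densities)


def community_table(g: nx.Graph, p: Partition):
    """Per-community metric table (list of dicts, sorted by community id).

    Used by the ``metrics`` CLI subcommand; undefined entries are None.
    """
    rows = []
    for cid in sorted(p.communities, key=sort_key):
        members = p.members(cid)
        st = community_stats(g, members)
        rows.append(
            {
                "community": cid,
                "n_s": st.n_s,
                "l_c": st.l_c,
                "m_out": st.m_out,
                "density": internal_edge_density(st) if st.n_s >= 2 else None,
                "tpr": triad_participation_ratio(g, members),
                "conductance": conductance(st) if (2 * st.l_c + st.m_out) else None,
                "balance": community_edge_balance(st),
            }
        )
    return rows
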