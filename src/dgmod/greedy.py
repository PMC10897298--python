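"""CNM-style greedy modularity agglomeration with incremental bookkeeping.

The exploitation core.  :class:`AggState` maintains, for the current
partition, per-community internal-edge and degree tallies, the symmetric
map of raw edge counts between communities, and the current modularity
``q``.  With ``a_i = k_i/(2L)`` and ``e_ij`` the *fraction* of edges
joining communities i and j, merging i and j changes modularity by
exactly

    dQ = 2 (e_ij - a_i a_j)

which is what :meth:`AggState.delta_q` returns; the identity
``q_after - q_before == dQ`` is enforced by test at 1e-12.

``run_greedy`` is the plain deterministic baseline: repeatedly apply the
best positive-gain merge (ties broken by smallest community-id pair)
until none remains.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx

from .errors import ValidationError
from .graph import Node, Partition, sort_key
from .metrics import CommunityStats

__all__ = [
    "AggState",
    "init_singletons",
    "delta_q",
    "best_merge",
    "apply_merge",
    "run_greedy",
]


class AggState:
    """Incremental agglomeration state over a fixed graph.

    Community ids are dense integers: the initial singletons get ids
    ``0..n-1`` in deterministic node order, and every community created by
    a disassembly move gets a fresh id from an internal counter.  Methods
    mutate the state in place and return it for chaining.
    """

    __slots__ = ("graph", "L", "node_comm", "members", "l", "k", "e", "q", "_next_id")

    def __init__(self, graph: nx.Graph):
        if graph.number_of_edges() < 1:
            raise ValidationError("agglomeration needs at least one edge")
        self.graph = graph
        self.L = graph.number_of_edges()
        self.node_comm: dict[Node, int] = {}
        self.members: dict[int, set] = {}
        self.l: dict[int, int] = {}
        self.k: dict[int, int] = {}
        self.e: dict[int, dict[int, int]] = {}
        self.q = 0.0
        self._next_id = 0

    # -- construction ---------------------------------------------------

    @classmethod
    def from_singletons(cls, graph: nx.Graph) -> "AggState":
        """One community per node; ``q = -sum_i a_i^2``."""
        state = cls(graph)
        order = sorted(graph.nodes, key=sort_key)
        for cid, v in enumerate(order):
            state.node_comm[v] = cid
            state.members[cid] = {v}
            state.l[cid] = 0
            state.k[cid] = graph.degree(v)
            state.e[cid] = {}
        state._next_id = len(order)
        for u, v in graph.edges:
            cu, cv = state.node_comm[u], state.node_comm[v]
            state.e[cu][cv] = state.e[cu].get(cv, 0) + 1
            state.e[cv][cu] = state.e[cv].get(cu, 0) + 1
        inv2L = 1.0 / (2 * state.L)
        state.q = -sum((kc * inv2L) ** 2 for kc in state.k.values())
        return state

    # -- inspection -----------------------------------------------------

    @property
    def n_communities(self) -> int:
        return len(self.members)

    def community_ids(self) -> list[int]:
        return sorted(self.members)

    def a(self, c: int) -> float:
        return self.k[c] / (2 * self.L)

    def stats(self, c: int) -> CommunityStats:
        lc, kc = self.l[c], self.k[c]
        return CommunityStats(n_s=len(self.members[c]), l_c=lc, k_c=kc, m_out=kc - 2 * lc)

    def partition(self) -> Partition:
        return Partition(self.node_comm)

    def recompute_q(self) -> float:
        """From-scratch Eq.-style modularity of the current partition
        (oracle for the incremental ``q``; O(n + m))."""
        inv2L = 1.0 / (2 * self.L)
        return sum(
            self.l[c] / self.L - (self.k[c] * inv2L) ** 2 for c in self.members
        )

    def _require(self, c: int) -> None:
        if c not in self.members:
            raise ValidationError(f"unknown community id {c}")

    # -- merging --------------------------------------------------------

    def delta_q(self, i: int, j: int) -> float:
        """Exact modularity change of merging communities i and j."""
        if i == j:
            raise ValidationError("cannot merge a community with itself")
        self._require(i)
        self._require(j)
        inv2L = 1.0 / (2 * self.L)
        eij = self.e[i].get(j, 0) * inv2L
        return 2.0 * (eij - (self.k[i] * inv2L) * (self.k[j] * inv2L))

    def best_merge(self, positive_only: bool = True) -> Optional[tuple[int, int, float]]:
        """Connected community pair maximizing dQ, ties broken by smallest
        (i, j); None if no connected pair exists (or none is positive)."""
        inv2L = 1.0 / (2 * self.L)
        best: Optional[tuple[int, int, float]] = None
        for i, nbrs in self.e.items():
            ai = self.k[i] * inv2L
            for j, cnt in nbrs.items():
                if j < i:
                    continue
                dq = 2.0 * (cnt * inv2L - ai * self.k[j] * inv2L)
                if best is None or dq > best[2] or (dq == best[2] and (i, j) < best[:2]):
                    best = (i, j, dq)
        if best is None or (positive_only and best[2] <= 0.0):
            return None
        return best

    def apply_merge(self, i: int, j: int) -> "AggState":
        """Merge j into i (the smaller id survives); all tallies and ``q``
        are updated incrementally."""
        dq = self.delta_q(i, j)  # validates ids
        t, o = (i, j) if i < j else (j, i)
        self.l[t] += self.l[o] + self.e[t].get(o, 0)
        self.k[t] += self.k[o]
        for u in self.members[o]:
            self.node_comm[u] = t
        self.members[t] |= self.members.pop(o)
        del self.l[o], self.k[o]
        self.e[t].pop(o, None)
        onbrs = self.e.pop(o)
        onbrs.pop(t, None)
        for nb, cnt in onbrs.items():
            new = self.e[t].get(nb, 0) + cnt
            self.e[t][nb] = new
            nbmap = self.e[nb]
            nbmap.pop(o, None)
            nbmap[t] = new
        self.q += dq
        return self

    # -- community replacement (used by disassembly moves) ---------------

    def split_community(self, c: int, groups: Iterable[Iterable[Node]]) -> list[int]:
        """Replace community ``c`` by ``groups`` (a partition of its
        members); returns the fresh community ids in group order."""
        self._require(c)
        groups = [set(gset) for gset in groups]
        old_members = self.members[c]
        union: set = set()
        for gset in groups:
            if not gset:
                raise ValidationError("empty group in split")
            union |= gset
        if union != old_members or sum(len(gs) for gs in groups) != len(old_members):
            raise ValidationError("groups must partition the community's members")

        inv2L = 1.0 / (2 * self.L)
        # retire the old community
        self.q -= self.l[c] / self.L - (self.k[c] * inv2L) ** 2
        for nb in self.e[c]:
            del self.e[nb][c]
        del self.e[c], self.l[c], self.k[c], self.members[c]

        new_ids = []
        for gset in groups:
            cid = self._next_id
            self._next_id += 1
            new_ids.append(cid)
            self.members[cid] = gset
            self.e[cid] = {}
            for u in gset:
                self.node_comm[u] = cid
        g = self.graph
        for cid in new_ids:
            lc = 0
            kc = 0
            ecounts: dict[int, int] = {}
            for u in self.members[cid]:
                kc += g.degree(u)
                for w in g[u]:
                    oc = self.node_comm[w]
                    if oc == cid:
                        lc += 1
                    else:
                        ecounts[oc] = ecounts.get(oc, 0) + 1
            lc //= 2
            self.l[cid] = lc
            self.k[cid] = kc
            for oc, cnt in ecounts.items():
                self.e[cid][oc] = cnt
                self.e[oc][cid] = cnt
            self.q += lc / self.L - (kc * inv2L) ** 2
        return new_ids


# -- functional surface ------------------------------------------------


def init_singletons(g: nx.Graph) -> AggState:
    """Start agglomeration from the all-singleton partition."""
    return AggState.from_singletons(g)


def delta_q(state: AggState, i: int, j: int) -> float:
    return state.delta_q(i, j)


def best_merge(state: AggState, positive_only: bool = True):
    return state.best_merge(positive_only=positive_only)


def apply_merge(state: AggState, i: int, j: int) -> AggState:
    return state.apply_merge(i, j)


def run_greedy(g: nx.Graph) -> tuple[Partition, float]:
    """Plain greedy modularity baseline: merge the best positive-gain pair
    until none remains.  Deterministic (smallest-id tie-break, no RNG)."""
    state = AggState.from_singletons(g)
    while (mv := state.best_merge(positive_only=True)) is not None:
        state.apply_merge(mv[0], mv[1])
    return state.partition(), state.q
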