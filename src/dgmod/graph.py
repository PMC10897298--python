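"""Graph and partition data model plus readers/writers.

Graphs are plain :class:`networkx.Graph` objects restricted to simple,
undirected, unweighted form; the readers here enforce that contract
(no self-loops, collapsed duplicates, weights dropped with a warning).
Node identifiers are opaque: integer-looking tokens are stored as
``int``, everything else as ``str``.

A :class:`Partition` is an immutable assignment of every node to exactly
one community.  :class:`ReferencePartition` additionally records where a
ground-truth labelling came from (e.g. the karate-club factions).
"""

from __future__ import annotations

import logging
from collections.abc import Hashable, Iterable, Mapping
from importlib import resources
from pathlib import Path
from types import MappingProxyType

import networkx as nx

from .errors import (
    FixtureNotFoundError,
    GraphFormatError,
    UnsupportedFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

Node = Hashable

_FIXTURES = {"karate": ("karate_edges.txt", "karate_factions.tsv")}


def sort_key(v: Node):
    """Total order over mixed int/str node identifiers (ints first)."""
    if isinstance(v, bool):  # bool is an int subclass; keep it out of the int lane
        return (1, str(v))
    if isinstance(v, int):
        return (0, v)
    return (1, str(v))


def _coerce(token: str) -> Node:
    try:
        return int(token)
    except ValueError:
        return token


class Partition:
    """Disjoint assignment of every node to exactly one community.

    Construct from a node -> community-id mapping or via
    :meth:`from_communities`.  Instances are immutable; community ids are
    arbitrary hashables kept stable for the lifetime of the object.
    """

    __slots__ = ("_assignment", "_communities")

    def __init__(self, assignment: Mapping[Node, Hashable]):
        if not assignment:
            raise ValidationError("a partition needs at least one node")
        self._assignment = dict(assignment)
        groups: dict[Hashable, set[Node]] = {}
        for node, cid in self._assignment.items():
            groups.setdefault(cid, set()).add(node)
        self._communities = {cid: frozenset(ns) for cid, ns in groups.items()}

    @classmethod
    def from_communities(cls, groups: Iterable[Iterable[Node]]) -> "Partition":
        assignment: dict[Node, Hashable] = {}
        for cid, members in enumerate(groups):
            members = list(members)
            if not members:
                raise ValidationError("empty community in partition")
            for v in members:
                if v in assignment:
                    raise ValidationError(f"node {v!r} appears in two communities")
                assignment[v] = cid
        return cls(assignment)

    @property
    def assignment(self) -> Mapping[Node, Hashable]:
        return MappingProxyType(self._assignment)

    @property
    def communities(self) -> Mapping[Hashable, frozenset]:
        return MappingProxyType(self._communities)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._assignment)

    def community_of(self, v: Node) -> Hashable:
        try:
            return self._assignment[v]
        except KeyError:
            raise ValidationError(f"node {v!r} not in partition") from None

    def members(self, cid: Hashable) -> frozenset:
        return self._communities[cid]

    def __len__(self) -> int:
        return len(self._communities)

    def __contains__(self, v: Node) -> bool:
        return v in self._assignment

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self._assignment == other._assignment

    def __hash__(self):
        return hash(frozenset(self._assignment.items()))

    def same_clustering(self, other: "Partition") -> bool:
        """Label-independent equality: identical grouping of nodes."""
        return set(self._communities.values()) == set(other._communities.values())

    def renumbered(self) -> "Partition":
        """Equivalent partition with communities relabeled 0..k-1 in order
        of their smallest member (canonical form for output files)."""
        ordered = sorted(
            self._communities.values(),
            key=lambda mem: sort_key(min(mem, key=sort_key)),
        )
        return Partition(
            {v: i for i, mem in enumerate(ordered) for v in mem}
        )

    def validate_against(self, g: nx.Graph) -> None:
        if self.nodes != frozenset(g.nodes):
            missing = frozenset(g.nodes) - self.nodes
            extra = self.nodes - frozenset(g.nodes)
            raise ValidationError(
                f"partition does not cover graph (missing={sorted(missing, key=sort_key)!r}, "
                f"extra={sorted(extra, key=sort_key)!r})"
            )

    def __repr__(self) -> str:
        return f"Partition({len(self)} communities, {len(self._assignment)} nodes)"


class ReferencePartition(Partition):
    """A :class:`Partition` carrying ground-truth provenance."""

    __slots__ = ("source",)

    def __init__(self, assignment: Mapping[Node, Hashable], source: str = "reference"):
        super().__init__(assignment)
        self.source = source

    def __repr__(self) -> str:
        return f"ReferencePartition({len(self)} communities, source={self.source!r})"


def _finish_graph(g: nx.Graph) -> nx.Graph:
    if g.number_of_nodes() == 0:
        raise GraphFormatError("graph has no nodes")
    return g


def read_edgelist(path, comment_prefix: str = "#") -> nx.Graph:
    """Read a whitespace-delimited edge list as a simple undirected graph.

    The first two tokens of each non-comment line are the endpoints;
    extra tokens (weights etc.) are ignored with a logged warning.
    Duplicate and reversed-duplicate lines collapse to one edge;
    self-loop lines are rejected.
    """
    g = nx.Graph()
    saw_extras = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected at least two tokens, got {line!r}"
                )
            if len(tokens) > 2:
                saw_extras = True
            u, v = _coerce(tokens[0]), _coerce(tokens[1])
            if u == v:
                raise ValidationError(f"{path}:{lineno}: self-loop on node {u!r}")
            g.add_edge(u, v)
    if saw_extras:
        logger.warning("%s: extra per-edge tokens (weights?) were ignored", path)
    return _finish_graph(g)


def read_gml(path) -> nx.Graph:
    """Read a Newman-collection style GML file as a simple undirected graph.

    Node ``label`` attributes, when present on every node, become the node
    identifiers; otherwise the numeric ``id`` is used.  A per-node numeric
    ``value`` attribute is retained (see :func:`value_partition`).
    Directed graphs are rejected.
    """
    try:
        parsed = nx.read_gml(path, label=None)
    except Exception as exc:  # networkx raises several parse error types
        raise GraphFormatError(f"{path}: not parseable as GML: {exc}") from exc
    if parsed.is_directed():
        raise UnsupportedFormatError(f"{path}: directed graphs are not supported")

    labels = nx.get_node_attributes(parsed, "label")
    if len(labels) == len(parsed) and len(set(labels.values())) == len(parsed):
        mapping = {n: _coerce(str(lab)) for n, lab in labels.items()}
    else:
        mapping = {n: n for n in parsed.nodes}

    g = nx.Graph()
    for n in parsed.nodes:
        attrs = {}
        if "value" in parsed.nodes[n]:
            attrs["value"] = parsed.nodes[n]["value"]
        g.add_node(mapping[n], **attrs)
    had_weights = False
    for u, v, data in parsed.edges(data=True):
        if data:
            had_weights = True
        uu, vv = mapping[u], mapping[v]
        if uu == vv:
            raise ValidationError(f"{path}: self-loop on node {uu!r}")
        g.add_edge(uu, vv)
    if had_weights:
        logger.warning("%s: edge attributes (weights?) were ignored", path)
    return _finish_graph(g)


def value_partition(g: nx.Graph, source: str = "gml-value") -> ReferencePartition | None:
    """Expose a per-node numeric ``value`` attribute as a reference partition.

    Returns ``None`` when not every node carries the attribute.
    """
    values = nx.get_node_attributes(g, "value")
    if len(values) != g.number_of_nodes() or not values:
        return None
    return ReferencePartition(values, source=source)


def load_fixture(name: str) -> tuple[nx.Graph, ReferencePartition]:
    """Load a bundled fixture by name.

    ``"karate"`` is the Zachary karate-club network (34 nodes, 78 edges)
    with its two-faction instructor/president split as the reference
    partition.  No network access is performed.
    """
    if name not in _FIXTURES:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    edges_name, labels_name = _FIXTURES[name]
    data_dir = resources.files("dgmod") / "data"
    with resources.as_file(data_dir / edges_name) as p:
        g = read_edgelist(p)
    assignment: dict[Node, Hashable] = {}
    for lineno, line in enumerate(
        (data_dir / labels_name).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        node_tok, label = line.split("\t")
        assignment[_coerce(node_tok)] = label
    ref = ReferencePartition(assignment, source=f"{name} factions")
    ref.validate_against(g)
    return g, ref


def induced_components(g: nx.Graph, nodes: Iterable[Node]) -> list[set]:
    """Connected components of the subgraph induced by ``nodes``.

    Returned as a deterministic list (ordered by smallest member) of
    disjoint sets whose union is ``nodes``.
    """
    nodes = set(nodes)
    unknown = nodes - set(g.nodes)
    if unknown:
        raise ValidationError(f"nodes not in graph: {sorted(unknown, key=sort_key)!r}")
    comps = [set(c) for c in nx.connected_components(g.subgraph(nodes))]
    return sorted(comps, key=lambda c: sort_key(min(c, key=sort_key)))


def write_membership(p: Partition, path) -> None:
    """Write a partition as a TSV of ``node<TAB>community`` lines, sorted by node."""
    lines = [
        f"{v}\t{p.community_of(v)}"
        for v in sorted(p.assignment, key=sort_key)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_membership(path) -> Partition:
    """Read a membership TSV written by :func:`write_membership`."""
    assignment: dict[Node, Hashable] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'node<TAB>community', got {line!r}"
                )
            assignment[_coerce(parts[0])] = _coerce(parts[1])
    if not assignment:
        raise GraphFormatError(f"{path}: empty membership file")
    return Partition(assignment)
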