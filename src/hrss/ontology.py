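"""OBO parsing and structural queries on the term DAG.

The graph stores typed parent links (child -> parent). All depths and
distances are edge counts with the namespace root at depth 0. Obsolete
terms are retained for bookkeeping but carry no edges and never take part
in traversals.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    CycleError,
    NamespaceMismatchError,
    OboParseError,
    UnknownTermError,
    UnreachableError,
)

#: Relations the parser understands; RSS follows is_a by default.
SUPPORTED_RELATIONS = frozenset({"is_a", "part_of"})
DEFAULT_RELATIONS = frozenset({"is_a"})


@dataclass(frozen=True)
class Term:
    """A single ontology term."""

    id: str
    name: str = ""
    namespace: str = ""
    is_obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


class OntologyGraph:
    """A parsed ontology: terms plus typed child->parent edges.

    Parameters
    ----------
    terms:
        Mapping of canonical id to :class:`Term`.
    parents:
        Mapping of child id to a set of ``(parent_id, relation)`` pairs.
        Obsolete terms must not appear on either side of an edge.
    """

    def __init__(self, terms: Mapping[str, Term], parents: Mapping[str, set[tuple[str, str]]]):
        self.terms: dict[str, Term] = dict(terms)
        self.parents: dict[str, frozenset[tuple[str, str]]] = {
            t: frozenset(parents.get(t, ())) for t in self.terms
        }
        self._alt: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                self._alt.setdefault(alt, term.id)

        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        dag = nx.DiGraph()
        dag.add_nodes_from(t for t, term in self.terms.items() if not term.is_obsolete)
        for child, links in self.parents.items():
            for parent, _rel in links:
                if parent not in self.terms:
                    raise UnknownTermError(parent)
                self._children[parent].add(child)
                dag.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise CycleError(cycle[0][0])

        # the namespace root is the parentless term that subsumes the most
        # terms; other parentless terms (e.g. orphaned by relation
        # filtering) stay queryable but have no defined depth
        candidates: dict[str, list[str]] = {}
        for tid, term in self.terms.items():
            if term.is_obsolete or self.parents[tid]:
                continue
            candidates.setdefault(term.namespace, []).append(tid)
        self._roots: dict[str, str] = {
            ns: max(roots, key=lambda t: (len(self.descendants(t)), _rev(t)))
            for ns, roots in candidates.items()
        }

        self._depth_cache: dict[str, int] = {}
        self._maxdepth_cache: dict[str, int] = {}

    # -- id plumbing -------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Canonical id for ``term_id``, following alt_id merges."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise UnknownTermError(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def root(self, namespace: str) -> str:
        return self._roots[namespace]

    @property
    def roots(self) -> dict[str, str]:
        return dict(self._roots)

    def edge_count(self) -> int:
        return sum(len(p) for p in self.parents.values())

    # -- traversals --------------------------------------------------------

    def ancestors(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure over parent links."""
        tid = self.resolve(term_id)
        seen: set[str] = set()
        stack = [tid]
        while stack:
            node = stack.pop()
            for parent, _rel in self.parents[node]:
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        if include_self:
            seen.add(tid)
        return seen

    def descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        tid = self.resolve(term_id)
        seen: set[str] = set()
        stack = [tid]
        while stack:
            node = stack.pop()
            for child in self._children[node]:
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        if include_self:
            seen.add(tid)
        return seen

    def is_leaf(self, term_id: str) -> bool:
        return not self._children[self.resolve(term_id)]

    def leaves(self, namespace: str) -> set[str]:
        return {
            t
            for t, term in self.terms.items()
            if term.namespace == namespace and not term.is_obsolete and not self._children[t]
        }

    def up_distances(self, term_id: str) -> dict[str, int]:
        """Shortest edge distance from ``term_id`` to each of its ancestors
        (including itself at 0), following parent links only."""
        tid = self.resolve(term_id)
        dist = {tid: 0}
        queue = deque([tid])
        while queue:
            node = queue.popleft()
            for parent, _rel in self.parents[node]:
                if parent not in dist:
                    dist[parent] = dist[node] + 1
                    queue.append(parent)
        return dist

    def depth(self, term_id: str) -> int:
        """Shortest edge distance from the namespace root (root depth 0)."""
        tid = self.resolve(term_id)
        if tid not in self._depth_cache:
            ups = self.up_distances(tid)
            root = self._roots.get(self.terms[tid].namespace)
            if root is None or root not in ups:
                raise UnreachableError(f"{tid!r} does not reach a namespace root")
            self._depth_cache[tid] = ups[root]
        return self._depth_cache[tid]

    def max_depth(self, namespace: str) -> int:
        """Largest root->leaf shortest-path distance in the namespace."""
        if namespace not in self._maxdepth_cache:
            depths = []
            for t in self.leaves(namespace):
                try:
                    depths.append(self.depth(t))
                except UnreachableError:  # orphaned by relation filtering
                    continue
            self._maxdepth_cache[namespace] = max(depths, default=0)
        return self._maxdepth_cache[namespace]

    # -- pairwise structural queries ---------------------------------------

    def _check_namespace(self, a: str, b: str) -> None:
        if self.namespace_of(a) != self.namespace_of(b):
            raise NamespaceMismatchError(
                f"{a!r} ({self.namespace_of(a)}) vs {b!r} ({self.namespace_of(b)})"
            )

    def common_ancestors(self, a: str, b: str) -> set[str]:
        """Shared ancestors, counting a term as an ancestor of itself."""
        self._check_namespace(a, b)
        return self.ancestors(a, include_self=True) & self.ancestors(b, include_self=True)

    def dist(self, u: str, v: str) -> int:
        """Shortest path length between two terms, routed through a common
        ancestor (never through descendants)."""
        u, v = self.resolve(u), self.resolve(v)
        if u == v:
            return 0
        common = self.common_ancestors(u, v)
        if not common:
            raise UnreachableError(f"no common ancestor for {u!r} and {v!r}")
        du, dv = self.up_distances(u), self.up_distances(v)
        return min(du[c] + dv[c] for c in common)

    def mrca(self, a: str, b: str) -> str:
        """Deepest common ancestor; depth ties break to the smallest id."""
        common = self.common_ancestors(a, b)
        if not common:
            raise UnreachableError(f"no common ancestor for {a!r} and {b!r}")
        return max(common, key=lambda c: (self.depth(c), _rev(c)))

    def leaf_generality(self, term_id: str) -> int:
        """Minimum edge distance down to a descendant leaf (0 for leaves)."""
        tid = self.resolve(term_id)
        dist = {tid: 0}
        queue = deque([tid])
        while queue:
            node = queue.popleft()
            if not self._children[node]:
                return dist[node]
            for child in self._children[node]:
                if child not in dist:
                    dist[child] = dist[node] + 1
                    queue.append(child)
        return 0  # unreachable: BFS always hits a leaf in a finite DAG


class _rev:
    """Key wrapper inverting lexicographic order, so that max() picks the
    lexicographically smallest id on primary-key ties."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_rev") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_rev") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _rev) and self.s == other.s


# -- OBO flat-file parsing -------------------------------------------------


def parse_obo(path_or_handle, relations: Iterable[str] = DEFAULT_RELATIONS) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Parameters
    ----------
    path_or_handle:
        File path or text handle.
    relations:
        Relation types to keep as edges; a subset of ``{is_a, part_of}``.

    Raises
    ------
    OboParseError
        Unsupported relation requested or structurally invalid file.
    CycleError
        The requested edge set contains a directed cycle.
    """
    relations = frozenset(relations)
    if not relations <= SUPPORTED_RELATIONS:
        raise OboParseError(f"unsupported relations: {sorted(relations - SUPPORTED_RELATIONS)}")

    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        handle: io.TextIOBase = open(path_or_handle, "rt", encoding="utf-8")
        close = True
    else:
        handle, close = path_or_handle, False

    terms: dict[str, dict] = {}
    stanza: dict | None = None
    try:
        for raw in handle:
            line = raw.split("!", 1)[0].strip() if not raw.startswith("!") else ""
            if raw.strip() == "[Term]":
                stanza = {"alt_ids": [], "parents": set(), "obsolete": False, "name": "", "namespace": ""}
                continue
            if raw.strip().startswith("[") and raw.strip().endswith("]"):
                stanza = None  # [Typedef] and friends
                continue
            if stanza is None or not line:
                continue
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key == "id":
                stanza["id"] = value
                terms[value] = stanza
            elif key == "name":
                stanza["name"] = value
            elif key == "namespace":
                stanza["namespace"] = value
            elif key == "alt_id":
                stanza["alt_ids"].append(value)
            elif key == "is_obsolete":
                stanza["obsolete"] = value.lower() == "true"
            elif key == "is_a":
                stanza["parents"].add((value.split()[0], "is_a"))
            elif key == "relationship":
                parts = value.split()
                if len(parts) >= 2:
                    stanza["parents"].add((parts[1], parts[0]))
    finally:
        if close:
            handle.close()

    term_objs: dict[str, Term] = {}
    parents: dict[str, set[tuple[str, str]]] = {}
    for tid, st in terms.items():
        term_objs[tid] = Term(
            id=tid,
            name=st["name"],
            namespace=st["namespace"],
            is_obsolete=st["obsolete"],
            alt_ids=tuple(st["alt_ids"]),
        )
    for tid, st in terms.items():
        if st["obsolete"]:
            parents[tid] = set()
            continue
        kept = set()
        for parent, rel in st["parents"]:
            if rel not in relations:
                continue
            if parent in terms and terms[parent]["obsolete"]:
                continue
            kept.add((parent, rel))
        parents[tid] = kept
    return OntologyGraph(term_objs, parents)


# Convenience wrappers mirroring the functional surface.

def ancestors(graph: OntologyGraph, term: str, include_self: bool = False) -> set[str]:
    return graph.ancestors(term, include_self=include_self)


def dist(graph: OntologyGraph, u: str, v: str) -> int:
    return graph.dist(u, v)


def mrca(graph: OntologyGraph, a: str, b: str) -> str:
    return graph.mrca(a, b)


def leaf_generality(graph: OntologyGraph, term: str) -> int:
    return graph.leaf_generality(term)
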