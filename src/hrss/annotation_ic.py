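"""GAF parsing, evidence filtering, true-path propagation and corpus IC.

Probabilities count distinct gene products (not annotation rows) per
namespace: p(c) = genes annotated to c or any descendant / genes with at
least one annotation in c's namespace. IC(c) = -log_base p(c) and is only
defined where the count is positive.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import GafParseError, MissingICError, UnknownTermError
from .ontology import OntologyGraph, _rev

log = logging.getLogger(__name__)

#: GAF column 9 aspect letter -> ontology namespace.
ASPECT_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}

GAF_COLUMNS = 17


@dataclass
class AnnotationCorpus:
    """Gene -> namespace -> term-id sets, before and after propagation."""

    direct: dict[str, dict[str, set[str]]]
    propagated: Optional[dict[str, dict[str, set[str]]]] = None
    excluded_evidence: frozenset[str] = frozenset()
    dropped_not: int = 0
    dropped_evidence: int = 0
    dropped_unknown: int = 0

    @property
    def is_propagated(self) -> bool:
        return self.propagated is not None

    def genes(self, namespace: Optional[str] = None) -> set[str]:
        if namespace is None:
            return set(self.direct)
        return {g for g, by_ns in self.direct.items() if by_ns.get(namespace)}

    def universe_size(self, namespace: str) -> int:
        """Distinct genes with >= 1 annotation in the namespace after filtering."""
        return len(self.genes(namespace))

    def direct_terms(self, gene: str, namespace: str) -> set[str]:
        return set(self.direct.get(gene, {}).get(namespace, set()))

    def propagated_terms(self, gene: str, namespace: str) -> set[str]:
        if self.propagated is None:
            raise ValueError("corpus is not propagated; call propagate() first")
        return set(self.propagated.get(gene, {}).get(namespace, set()))


def parse_gaf(
    path_or_handle,
    exclude_evidence: Iterable[str] = (),
    namespace: Optional[str] = None,
    graph: Optional[OntologyGraph] = None,
) -> AnnotationCorpus:
    """Read a GAF 2.x file into an (unpropagated) :class:`AnnotationCorpus`.

    Rows whose qualifier contains NOT are dropped, as are rows with an
    excluded evidence code. When ``graph`` is given, term ids are resolved
    through alt_id and rows hitting unknown or obsolete terms are dropped
    (counted in ``dropped_unknown``).

    ``namespace`` may be a full namespace name or a GAF aspect letter.
    """
    exclude = frozenset(exclude_evidence)
    if namespace in ASPECT_NAMESPACE:
        namespace = ASPECT_NAMESPACE[namespace]

    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        handle: io.TextIOBase = open(path_or_handle, "rt", encoding="utf-8")
        close = True
    else:
        handle, close = path_or_handle, False

    direct: dict[str, dict[str, set[str]]] = {}
    n_not = n_ev = n_unknown = 0
    try:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != GAF_COLUMNS:
                raise GafParseError(lineno, f"expected {GAF_COLUMNS} columns, got {len(fields)}")
            gene = fields[1]
            qualifier = fields[3]
            term = fields[4]
            evidence = fields[6]
            aspect = fields[8]

            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            if evidence in exclude:
                n_ev += 1
                continue
            ns = ASPECT_NAMESPACE.get(aspect, aspect)
            if namespace is not None and ns != namespace:
                continue
            if graph is not None:
                try:
                    term = graph.resolve(term)
                except UnknownTermError:
                    n_unknown += 1
                    continue
                if graph.terms[term].is_obsolete:
                    n_unknown += 1
                    continue
            direct.setdefault(gene, {}).setdefault(ns, set()).add(term)
    finally:
        if close:
            handle.close()

    if n_unknown:
        log.warning("dropped %d annotation rows with unknown/obsolete terms", n_unknown)
    return AnnotationCorpus(
        direct=direct,
        excluded_evidence=exclude,
        dropped_not=n_not,
        dropped_evidence=n_ev,
        dropped_unknown=n_unknown,
    )


def propagate(corpus: AnnotationCorpus, graph: OntologyGraph) -> AnnotationCorpus:
    """True-path-rule closure: each gene inherits every ancestor of its
    direct terms. Returns a new corpus; unknown/obsolete ids are dropped."""
    propagated: dict[str, dict[str, set[str]]] = {}
    direct: dict[str, dict[str, set[str]]] = {}
    n_unknown = corpus.dropped_unknown
    for gene, by_ns in corpus.direct.items():
        for ns, terms in by_ns.items():
            closure: set[str] = set()
            kept: set[str] = set()
            for t in terms:
                try:
                    tid = graph.resolve(t)
                except UnknownTermError:
                    n_unknown += 1
                    continue
                if graph.terms[tid].is_obsolete:
                    n_unknown += 1
                    continue
                kept.add(tid)
                closure |= graph.ancestors(tid, include_self=True)
            if kept:
                direct.setdefault(gene, {})[ns] = kept
                propagated.setdefault(gene, {})[ns] = closure
    return AnnotationCorpus(
        direct=direct,
        propagated=propagated,
        excluded_evidence=corpus.excluded_evidence,
        dropped_not=corpus.dropped_not,
        dropped_evidence=corpus.dropped_evidence,
        dropped_unknown=n_unknown,
    )


@dataclass
class ICTable:
    """Per-term annotation counts, probabilities and information content."""

    counts: dict[str, int]
    probability: dict[str, float]
    ic: dict[str, float]
    base: float
    universe: dict[str, int]
    graph: OntologyGraph = field(repr=False)

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise MissingICError(term) from None

    def require(self, *terms: str) -> None:
        for t in terms:
            if t not in self.ic:
                raise MissingICError(t)


def compute_ic(corpus: AnnotationCorpus, graph: OntologyGraph, base: float = math.e) -> ICTable:
    """Corpus-based IC over propagated annotation sets.

    Raises
    ------
    ValueError
        Corpus not propagated, or empty universe, or base invalid.
    """
    if not corpus.is_propagated:
        raise ValueError("compute_ic requires a propagated corpus")
    if base <= 0 or base == 1:
        raise ValueError(f"invalid log base {base!r}")

    counts: dict[str, int] = {}
    for gene, by_ns in corpus.propagated.items():
        for ns, terms in by_ns.items():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1

    universe = {ns: corpus.universe_size(ns) for ns in {graph.terms[t].namespace for t in counts}}
    if any(u == 0 for u in universe.values()) or not universe:
        raise ValueError("annotation universe is empty")

    log_base = math.log(base)
    probability: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t, n in counts.items():
        p = n / universe[graph.terms[t].namespace]
        probability[t] = p
        val = -math.log(p) / log_base
        ic[t] = val if val != 0.0 else 0.0  # avoid -0.0 at the root
    return ICTable(
        counts=counts, probability=probability, ic=ic, base=base, universe=universe, graph=graph
    )


def dist_ic(ic: ICTable, u: str, v: str) -> float:
    """IC gap between an ancestor ``u`` and its descendant ``v`` (0 if equal)."""
    graph = ic.graph
    u, v = graph.resolve(u), graph.resolve(v)
    if u != v and u not in graph.ancestors(v):
        raise ValueError(f"{u!r} is not an ancestor of {v!r}")
    ic.require(u, v)
    return ic[v] - ic[u]


def mica(ic: ICTable, graph: OntologyGraph, a: str, b: str) -> str:
    """Most informative common ancestor (a term subsumes itself).

    Only ancestors with defined IC compete; IC ties break to the
    lexicographically smallest id.
    """
    common = graph.common_ancestors(a, b)
    candidates = [c for c in common if c in ic]
    if not candidates:
        raise MissingICError(f"no common ancestor of {a!r}/{b!r} with defined IC")
    return max(candidates, key=lambda c: (ic[c], _rev(c)))


def mil_generality(ic: ICTable, graph: OntologyGraph, term: str) -> float:
    """IC gap from ``term`` down to its most informative annotated leaf.

    0 for leaves and for terms with no annotated descendant leaf (they
    behave as maximally specific).
    """
    tid = graph.resolve(term)
    ic.require(tid)
    if graph.is_leaf(tid):
        return 0.0
    gaps = [
        ic[leaf] - ic[tid]
        for leaf in graph.descendants(tid)
        if graph.is_leaf(leaf) and leaf in ic
    ]
    return max(gaps, default=0.0)
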