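"""Term-pair semantic similarity: HRSS, RSS, Resnik, Lin, Jiang.

The edge-based score combines three components of the DAG position of the
pair: ancestor specificity (alpha), term generality (beta) and the local
divergence from the common ancestor (gamma). The hybrid score replaces
alpha and beta with information-content analogues and gamma with the IC
gap through the most informative common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .annotation_ic import ICTable, dist_ic, mica, mil_generality
from .errors import MissingICError
from .ontology import OntologyGraph


@dataclass(frozen=True)
class TermPairScore:
    term_a: str
    term_b: str
    measure: str
    value: float
    components: dict[str, float] = field(default_factory=dict)


def rss(graph: OntologyGraph, a: str, b: str) -> TermPairScore:
    """Edge-based relative specificity similarity, in [0, 1].

    value = (maxDepth / (maxDepth + gamma)) * (alpha / (alpha + beta))
    with alpha the MRCA depth, beta the mean leaf-distance generality of
    the two terms, and gamma the summed edge distance of both terms to the
    MRCA. A zero-depth (root) MRCA scores 0.
    """
    a, b = graph.resolve(a), graph.resolve(b)
    anc = graph.mrca(a, b)
    alpha = float(graph.depth(anc))
    beta = (graph.leaf_generality(a) + graph.leaf_generality(b)) / 2.0
    ups_a, ups_b = graph.up_distances(a), graph.up_distances(b)
    gamma = float(ups_a[anc] + ups_b[anc])
    max_depth = graph.max_depth(graph.namespace_of(a))
    if alpha == 0.0:
        value = 0.0
    else:
        value = (max_depth / (max_depth + gamma)) * (alpha / (alpha + beta))
    return TermPairScore(a, b, "rss", value, {"alpha": alpha, "beta": beta, "gamma": gamma})


def hrss(ic: ICTable, graph: OntologyGraph, a: str, b: str) -> TermPairScore:
    """Hybrid relative specificity similarity, in [0, 1].

    value = (1 / (1 + gamma)) * (alpha_ic / (alpha_ic + beta_ic)); a
    zero-IC common ancestor scores 0.
    """
    a, b = graph.resolve(a), graph.resolve(b)
    ic.require(a, b)
    anc = mica(ic, graph, a, b)
    alpha_ic = ic[anc]
    beta_ic = (mil_generality(ic, graph, a) + mil_generality(ic, graph, b)) / 2.0
    gamma = dist_ic(ic, anc, a) + dist_ic(ic, anc, b)
    if alpha_ic == 0.0:
        value = 0.0
    else:
        value = (1.0 / (1.0 + gamma)) * (alpha_ic / (alpha_ic + beta_ic))
    return TermPairScore(
        a, b, "hrss", value, {"alpha_ic": alpha_ic, "beta_ic": beta_ic, "gamma": gamma}
    )


def resnik(ic: ICTable, graph: OntologyGraph, a: str, b: str) -> TermPairScore:
    """IC of the most informative common ancestor (unnormalized, >= 0)."""
    a, b = graph.resolve(a), graph.resolve(b)
    ic.require(a, b)
    anc = mica(ic, graph, a, b)
    return TermPairScore(a, b, "resnik", ic[anc], {"alpha_ic": ic[anc]})


def lin(ic: ICTable, graph: OntologyGraph, a: str, b: str) -> TermPairScore:
    """2 IC(MICA) / (IC(a) + IC(b)), with 0/0 defined as 0; in [0, 1]."""
    a, b = graph.resolve(a), graph.resolve(b)
    ic.require(a, b)
    anc = mica(ic, graph, a, b)
    denom = ic[a] + ic[b]
    value = 0.0 if denom == 0.0 else 2.0 * ic[anc] / denom
    return TermPairScore(a, b, "lin", value, {"alpha_ic": ic[anc]})


def jiang(ic: ICTable, graph: OntologyGraph, a: str, b: str) -> TermPairScore:
    """1 / (1 + d) with d = IC(a) + IC(b) - 2 IC(MICA); in (0, 1]."""
    a, b = graph.resolve(a), graph.resolve(b)
    ic.require(a, b)
    anc = mica(ic, graph, a, b)
    d = ic[a] + ic[b] - 2.0 * ic[anc]
    return TermPairScore(a, b, "jiang", 1.0 / (1.0 + d), {"alpha_ic": ic[anc], "distance": d})


#: Term-level measures keyed by CLI name. rss is purely structural.
TERM_MEASURES: dict[str, Callable[..., TermPairScore]] = {
    "hrss": hrss,
    "rss": rss,
    "resnik": resnik,
    "lin": lin,
    "jiang": jiang,
}

#: Measures whose codomain is [0, 1].
NORMALIZED_MEASURES = frozenset({"hrss", "rss", "lin", "jiang"})


def score_term_pair(
    measure: str,
    graph: OntologyGraph,
    a: str,
    b: str,
    ic: Optional[ICTable] = None,
) -> TermPairScore:
    """Dispatch a term measure by name."""
    if measure not in TERM_MEASURES:
        raise ValueError(f"unknown term measure {measure!r}")
    if measure == "rss":
        return rss(graph, a, b)
    if ic is None:
        raise ValueError(f"measure {measure!r} requires an IC table")
    return TERM_MEASURES[measure](ic, graph, a, b)
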