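"""Gene-product-level similarity.

Pairwise strategies (MAX, BMA) aggregate a term-pair score matrix built
from the two genes' annotation sets; groupwise measures (simUI, simGIC)
compare the ancestor-closed term sets directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotation_ic import AnnotationCorpus, ICTable
from .errors import UnannotatedGeneError
from .ontology import OntologyGraph
from .term_sim import NORMALIZED_MEASURES, TERM_MEASURES, score_term_pair

PAIRWISE_STRATEGIES = frozenset({"max", "bma"})
GROUPWISE_MEASURES = frozenset({"simui", "simgic"})


@dataclass(frozen=True)
class GenePairScore:
    gene_a: str
    gene_b: str
    namespace: str
    measure: str
    strategy: str  # "max" | "bma" | "groupwise"
    value: float


def max_strategy(matrix: Sequence[Sequence[float]]) -> float:
    """Largest entry of the term-pair score matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise UnannotatedGeneError("empty term-pair matrix")
    return float(m.max())


def bma_strategy(matrix: Sequence[Sequence[float]], variant: str = "pooled") -> float:
    """Best-match average of the term-pair score matrix.

    ``pooled`` (default) averages the |TP| row maxima and |TQ| column
    maxima together in one mean; ``half`` averages the two per-side means.
    """
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise UnannotatedGeneError("empty term-pair matrix")
    rows = m.max(axis=1)
    cols = m.max(axis=0)
    if variant == "pooled":
        return float((rows.sum() + cols.sum()) / (rows.size + cols.size))
    if variant == "half":
        return float((rows.mean() + cols.mean()) / 2.0)
    raise ValueError(f"unknown BMA variant {variant!r}")


def sim_ui(corpus: AnnotationCorpus, gene_a: str, gene_b: str, namespace: str) -> float:
    """Jaccard index of the two propagated term sets."""
    sa = corpus.propagated_terms(gene_a, namespace)
    sb = corpus.propagated_terms(gene_b, namespace)
    if not sa:
        raise UnannotatedGeneError(f"{gene_a!r} has no annotations in {namespace!r}")
    if not sb:
        raise UnannotatedGeneError(f"{gene_b!r} has no annotations in {namespace!r}")
    return len(sa & sb) / len(sa | sb)


def sim_gic(
    ic: ICTable, corpus: AnnotationCorpus, gene_a: str, gene_b: str, namespace: str
) -> float:
    """IC-weighted Jaccard of the propagated term sets; 0 when the union
    carries zero total IC."""
    sa = corpus.propagated_terms(gene_a, namespace)
    sb = corpus.propagated_terms(gene_b, namespace)
    if not sa:
        raise UnannotatedGeneError(f"{gene_a!r} has no annotations in {namespace!r}")
    if not sb:
        raise UnannotatedGeneError(f"{gene_b!r} has no annotations in {namespace!r}")
    union = sum(ic[t] for t in sa | sb)
    if union == 0.0:
        return 0.0
    return sum(ic[t] for t in sa & sb) / union


def _term_sets(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    gene: str,
    namespace: str,
    use_propagated: bool,
) -> set[str]:
    terms = (
        corpus.propagated_terms(gene, namespace)
        if use_propagated
        else corpus.direct_terms(gene, namespace)
    )
    root = graph.roots.get(namespace)
    terms = {t for t in terms if t != root}
    if not terms:
        raise UnannotatedGeneError(
            f"{gene!r} has no non-root annotations in {namespace!r}"
        )
    return terms


def gene_similarity(
    corpus: AnnotationCorpus,
    ic: Optional[ICTable],
    graph: OntologyGraph,
    gene_a: str,
    gene_b: str,
    namespace: str,
    measure: str,
    strategy: Optional[str] = None,
    use_propagated: bool = False,
    bma_variant: str = "pooled",
) -> GenePairScore:
    """Score one gene pair under a measure/strategy combination.

    Pairwise measures score all term pairs of the genes' direct (by
    default) annotation sets, root annotations removed, then aggregate
    with MAX or BMA. Groupwise measures take no strategy.
    """
    measure = measure.lower()
    if measure in GROUPWISE_MEASURES:
        if strategy not in (None, "groupwise"):
            raise ValueError(f"groupwise measure {measure!r} takes no strategy")
        if measure == "simui":
            value = sim_ui(corpus, gene_a, gene_b, namespace)
        else:
            if ic is None:
                raise ValueError("simgic requires an IC table")
            value = sim_gic(ic, corpus, gene_a, gene_b, namespace)
        return GenePairScore(gene_a, gene_b, namespace, measure, "groupwise", value)

    if measure not in TERM_MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if strategy is None or strategy.lower() not in PAIRWISE_STRATEGIES:
        raise ValueError(
            f"pairwise measure {measure!r} needs strategy 'max' or 'bma', got {strategy!r}"
        )
    strategy = strategy.lower()

    tp = sorted(_term_sets(corpus, graph, gene_a, namespace, use_propagated))
    tq = sorted(_term_sets(corpus, graph, gene_b, namespace, use_propagated))
    matrix = [
        [score_term_pair(measure, graph, a, b, ic=ic).value for b in tq] for a in tp
    ]
    if strategy == "max":
        value = max_strategy(matrix)
    else:
        value = bma_strategy(matrix, variant=bma_variant)
    return GenePairScore(gene_a, gene_b, namespace, measure, strategy, value)
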