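"""Shared fixtures and independent brute-force oracles.

The oracles work on plain dicts (parent maps, count tables) and never call
the package's traversal code, so they stay valid checks of it.
"""

from __future__ import annotations

import io
import math

import numpy as np
import pytest

from hrss import compute_ic, parse_gaf, parse_obo, propagate
from hrss.fixtures import random_gaf, random_ontology, toy_corpus_F, toy_ontology_T

NS = "biological_process"


# -- toy fixture T / F -----------------------------------------------------


@pytest.fixture(scope="session")
def graph_T():
    return parse_obo(io.StringIO(toy_ontology_T()))


@pytest.fixture(scope="session")
def corpus_F(graph_T):
    return propagate(parse_gaf(io.StringIO(toy_corpus_F()), graph=graph_T), graph_T)


@pytest.fixture(scope="session")
def ic_F(corpus_F, graph_T):
    return compute_ic(corpus_F, graph_T, base=2)


#: Hand-propagated annotation counts of fixture F over ontology T.
F_COUNTS = {"R": 8, "A": 4, "B": 6, "C": 2, "D": 1, "E": 3}
F_UNIVERSE = 8
#: Independent base-2 IC table derived from the counts above.
F_IC = {t: -math.log2(n / F_UNIVERSE) for t, n in F_COUNTS.items()}


# -- naive graph oracles ---------------------------------------------------


def parent_map(graph) -> dict[str, set[str]]:
    """Untyped child -> parents dict extracted from a graph (data only)."""
    return {t: {p for p, _rel in links} for t, links in graph.parents.items()}


def naive_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Recursive parent enumeration."""
    out = set()
    for p in parents.get(term, ()):
        out.add(p)
        out |= naive_ancestors(parents, p)
    return out


def naive_up_dist(parents: dict[str, set[str]], u: str, c: str) -> float:
    """Min #edges from u up to c via exhaustive recursion; inf if c is not
    reached."""
    if u == c:
        return 0
    best = math.inf
    for p in parents.get(u, ()):
        best = min(best, 1 + naive_up_dist(parents, p, c))
    return best


def naive_dist(parents: dict[str, set[str]], u: str, v: str) -> float:
    common = (naive_ancestors(parents, u) | {u}) & (naive_ancestors(parents, v) | {v})
    return min(
        (naive_up_dist(parents, u, c) + naive_up_dist(parents, v, c) for c in common),
        default=math.inf,
    )


def naive_depth(parents: dict[str, set[str]], root: str, term: str) -> float:
    return naive_up_dist(parents, term, root)


def naive_mrca_set(parents: dict[str, set[str]], root: str, a: str, b: str) -> set[str]:
    """All common ancestors of maximal depth."""
    common = (naive_ancestors(parents, a) | {a}) & (naive_ancestors(parents, b) | {b})
    best = max(naive_depth(parents, root, c) for c in common)
    return {c for c in common if naive_depth(parents, root, c) == best}


def naive_mica_set(parents: dict[str, set[str]], ic: dict[str, float], a: str, b: str) -> set[str]:
    """All common ancestors (with defined IC) of maximal IC."""
    common = (naive_ancestors(parents, a) | {a}) & (naive_ancestors(parents, b) | {b})
    common = {c for c in common if c in ic}
    best = max(ic[c] for c in common)
    return {c for c in common if ic[c] == best}


# -- statistics oracles ----------------------------------------------------


def mann_whitney_auc(pos, neg) -> float:
    """Wins / (P*N) with ties counted one half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson_closed_form(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


# -- random fixture factory ------------------------------------------------


def make_random_fixture(seed: int, n_terms: int = 20, n_genes: int = 12):
    """Parse a random ontology + corpus + IC table from one seed."""
    rng = np.random.default_rng(seed)
    graph = parse_obo(io.StringIO(random_ontology(rng, n_terms=n_terms)))
    term_ids = sorted(graph.terms)
    gaf = random_gaf(rng, term_ids, n_genes=n_genes, annotations_per_gene=2)
    corpus = propagate(parse_gaf(io.StringIO(gaf), graph=graph), graph)
    ic = compute_ic(corpus, graph, base=2)
    return graph, corpus, ic
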