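"""Deterministic miniature OBO/GAF generators and a seeded benchmark.

Everything here is a pure function of its arguments (seed included), so
tests and demos never need a network or binary fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GenerationError

NS = "biological_process"
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


def _obo_header() -> str:
    return "format-version: 1.2\nontology: toy\n"


def _term_stanza(tid: str, name: str, namespace: str, parents=(), obsolete: bool = False) -> str:
    lines = [f"[Term]", f"id: {tid}", f"name: {name}", f"namespace: {namespace}"]
    for parent, rel in parents:
        if rel == "is_a":
            lines.append(f"is_a: {parent} ! parent")
        else:
            lines.append(f"relationship: {rel} {parent} ! parent")
    if obsolete:
        lines.append("is_obsolete: true")
    return "\n".join(lines) + "\n"


def _gaf_row(gene: str, term: str, evidence: str, aspect: str, qualifier: str = "involved_in") -> str:
    fields = [
        "TOY",            # 1 DB
        gene,             # 2 DB object id
        gene,             # 3 symbol
        qualifier,        # 4 qualifier
        term,             # 5 ontology term id
        "TOY:0001",       # 6 reference
        evidence,         # 7 evidence code
        "",               # 8 with/from
        aspect,           # 9 aspect
        gene,             # 10 name
        "",               # 11 synonyms
        "protein",        # 12 type
        "taxon:4932",     # 13 taxon
        "20120401",       # 14 date
        "TOY",            # 15 assigned by
        "",               # 16 annotation extension
        "",               # 17 gene product form id
    ]
    return "\t".join(fields) + "\n"


def toy_ontology_T() -> str:
    """The canonical 6-term DAG: R; A,B under R; C under both A and B;
    D under C; E under B. maxDepth 3, leaves {D, E}."""
    parts = [_obo_header()]
    edges = {
        "R": (),
        "A": (("R", "is_a"),),
        "B": (("R", "is_a"),),
        "C": (("A", "is_a"), ("B", "is_a")),
        "D": (("C", "is_a"),),
        "E": (("B", "is_a"),),
    }
    for tid in "RABCDE":
        parts.append("\n" + _term_stanza(tid, f"term {tid}", NS, edges[tid]))
    return "".join(parts)


#: Direct annotations of the toy corpus; propagated counts over ontology T
#: are R:8 A:4 B:6 C:2 D:1 E:3 of a universe of 8 genes.
TOY_F_DIRECT = {
    "g1": "D",
    "g2": "C",
    "g3": "A",
    "g4": "A",
    "g5": "E",
    "g6": "E",
    "g7": "E",
    "g8": "B",
}
#: Genes whose only annotation carries the electronically-inferred code.
TOY_F_IEA_GENES = ("g4", "g8")


def toy_corpus_F() -> str:
    """GAF for 8 genes over ontology T; two genes are IEA-only."""
    rows = ["!gaf-version: 2.2\n"]
    for gene, term in TOY_F_DIRECT.items():
        evidence = "IEA" if gene in TOY_F_IEA_GENES else "EXP"
        rows.append(_gaf_row(gene, term, evidence, "P"))
    return "".join(rows)


# -- random generators -----------------------------------------------------


def random_ontology(
    rng: np.random.Generator,
    n_terms: int = 30,
    max_parents: int = 2,
    namespace: str = NS,
    prefix: str = "RT",
) -> str:
    """A random rooted DAG in OBO text: term i draws 1..max_parents
    parents among terms 0..i-1 (term 0 is the root), so acyclicity holds
    by construction."""
    if n_terms < 1:
        raise GenerationError("need at least one term")
    ids = [f"{prefix}:{i:04d}" for i in range(n_terms)]
    parts = [_obo_header(), "\n" + _term_stanza(ids[0], "root", namespace)]
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        k = min(k, i)
        parent_idx = rng.choice(i, size=k, replace=False)
        parents = tuple((ids[int(j)], "is_a") for j in sorted(parent_idx))
        parts.append("\n" + _term_stanza(ids[i], f"term {i}", namespace, parents))
    return "".join(parts)


def random_gaf(
    rng: np.random.Generator,
    term_ids: list[str],
    n_genes: int = 40,
    annotations_per_gene: int = 2,
    iea_fraction: float = 0.0,
    namespace: str = NS,
) -> str:
    """Random annotations: every gene gets >= 1 term drawn uniformly."""
    rows = ["!gaf-version: 2.2\n"]
    aspect = _ASPECT[namespace]
    for g in range(n_genes):
        gene = f"gene{g:04d}"
        k = max(1, annotations_per_gene)
        chosen = rng.choice(len(term_ids), size=min(k, len(term_ids)), replace=False)
        for j in sorted(int(c) for c in chosen):
            evidence = "IEA" if rng.random() < iea_fraction else "EXP"
            rows.append(_gaf_row(gene, term_ids[j], evidence, aspect))
    return "".join(rows)


# -- seeded PPI-style benchmark --------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_terms: int = 30
    max_parents: int = 2
    n_genes: int = 40
    annotations_per_gene: int = 2
    iea_fraction: float = 0.1
    namespace: str = NS
    n_pairs: int = 50


@dataclass(frozen=True)
class Benchmark:
    obo: str
    gaf: str
    positives: str  # TSV gene_a <tab> gene_b
    negatives: str


def random_benchmark(spec: FixtureSpec) -> Benchmark:
    """A benchmark where positives are gene pairs sharing a deep (hence
    high-IC) term and negatives share at most a shallow term.

    Layout: one root, a layer of shallow terms, and several chains of
    depth 4 ending in deep leaves ("modules"). Genes are split round-robin
    across modules and annotated to their module's deep leaf plus one
    random shallow term; positives are within-module pairs, negatives are
    sampled cross-module pairs of equal number.
    """
    rng = np.random.default_rng(spec.seed)
    chain_len = 4
    n_shallow = max(3, spec.n_terms // 6)
    n_modules = (spec.n_terms - 1 - n_shallow) // chain_len
    if n_modules < 2:
        raise GenerationError(
            f"{spec.n_terms} terms cannot host >= 2 depth-{chain_len} modules"
        )

    ids = [f"BM:{i:04d}" for i in range(1 + n_shallow + n_modules * chain_len)]
    root = ids[0]
    shallow = ids[1 : 1 + n_shallow]
    parts = [_obo_header(), "\n" + _term_stanza(root, "root", spec.namespace)]
    for s in shallow:
        parts.append("\n" + _term_stanza(s, "shallow", spec.namespace, ((root, "is_a"),)))
    deep_leaves = []
    next_id = 1 + n_shallow
    for m in range(n_modules):
        anchor = shallow[int(rng.integers(len(shallow)))]
        parent = anchor
        for d in range(chain_len):
            tid = ids[next_id]
            next_id += 1
            parts.append(
                "\n" + _term_stanza(tid, f"module {m} depth {d + 2}", spec.namespace, ((parent, "is_a"),))
            )
            parent = tid
        deep_leaves.append(parent)
    obo = "".join(parts)

    # genes: module members plus ~10% background noise genes on shallow terms
    n_noise = max(1, spec.n_genes // 10)
    n_members = spec.n_genes - n_noise
    genes = [f"gene{g:04d}" for g in range(spec.n_genes)]
    module_of: dict[str, int] = {}
    aspect = _ASPECT[spec.namespace]
    rows = ["!gaf-version: 2.2\n"]
    for g in range(spec.n_genes):
        gene = genes[g]
        extra = shallow[int(rng.integers(len(shallow)))]
        if g < n_members:
            module_of[gene] = g % n_modules
            terms = [deep_leaves[g % n_modules], extra]
        else:
            terms = [extra]
        for t in terms:
            evidence = "IEA" if rng.random() < spec.iea_fraction else "EXP"
            rows.append(_gaf_row(gene, t, evidence, aspect))
    gaf = "".join(rows)

    members = genes[:n_members]
    pos_pool = [
        (a, b)
        for a, b in itertools.combinations(members, 2)
        if module_of[a] == module_of[b]
    ]
    neg_pool = [
        (a, b)
        for a, b in itertools.combinations(genes, 2)
        if module_of.get(a) is None or module_of.get(b) is None or module_of[a] != module_of[b]
    ]
    if len(pos_pool) < spec.n_pairs or len(neg_pool) < spec.n_pairs:
        raise GenerationError(
            f"cannot draw {spec.n_pairs} pairs (pools: {len(pos_pool)} pos, {len(neg_pool)} neg)"
        )
    pos_idx = rng.choice(len(pos_pool), size=spec.n_pairs, replace=False)
    neg_idx = rng.choice(len(neg_pool), size=spec.n_pairs, replace=False)
    positives = "".join(f"{a}\t{b}\n" for a, b in (pos_pool[int(i)] for i in sorted(pos_idx)))
    negatives = "".join(f"{a}\t{b}\n" for a, b in (neg_pool[int(i)] for i in sorted(neg_idx)))
    return Benchmark(obo=obo, gaf=gaf, positives=positives, negatives=negatives)


def write_benchmark(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Materialize a benchmark into four text files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bench = random_benchmark(spec)
    paths = {}
    for name, text in (
        ("ontology.obo", bench.obo),
        ("annotations.gaf", bench.gaf),
        ("positives.tsv", bench.positives),
        ("negatives.tsv", bench.negatives),
    ):
        p = outdir / name
        p.write_text(text)
        paths[name] = p
    return paths
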