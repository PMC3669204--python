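# hrss

Semantic similarity of ontology terms and gene products, built around a
hybrid edge- and information-content-based measure (HRSS) together with
the comparison measures RSS, Resnik, Lin, Jiang, simUI and simGIC, the
MAX/BMA pairwise aggregation strategies, and the evaluation statistics
needed to benchmark them: ROC/AUC (trapezoidal rule), Youden/F1 threshold
selection, PPV/NPV, four-level confidence binning, and seeded
randomization Z-scores for ortholog pair sets.

The package reads OBO 1.2/1.4 ontology flat files and GAF 2.x annotation
files, applies evidence-code filtering (e.g. dropping IEA) and true-path
propagation, and computes corpus-based IC tables. A fixtures module
generates miniature deterministic OBO/GAF files and a seeded synthetic
PPI-style benchmark, so everything is testable offline.

## Library quick start

```python
import io
from hrss import parse_obo, parse_gaf, propagate, compute_ic, hrss, gene_similarity
from hrss.fixtures import toy_ontology_T, toy_corpus_F

graph = parse_obo(io.StringIO(toy_ontology_T()))            # or a real .obo path
corpus = propagate(parse_gaf(io.StringIO(toy_corpus_F()), graph=graph), graph)
ic = compute_ic(corpus, graph, base=2)                      # natural log by default

hrss(ic, graph, "D", "E").value                             # term-level, ~0.218
gene_similarity(corpus, ic, graph, "g1", "g5",
                "biological_process", "hrss", "max").value  # gene-level
```

## CLI

The console script `hrss` exposes five subcommands; every command accepts
`--obo`, `--gaf`, `--namespace`, repeated `--exclude-evidence` codes,
`--log-base` and `--relations`, with defaults overridable from a YAML
file via `--config` (flags > config file > defaults).

```sh
# write toy fixture files, then score a term pair
hrss fixtures --outdir demo
printf 'D\tE\n' > pairs.tsv
hrss termsim --obo demo/toy.obo --gaf demo/toy.gaf --log-base 2 pairs.tsv scored.tsv

# gene pairs with a measure/strategy
hrss genesim --obo demo/toy.obo --gaf demo/toy.gaf --measure hrss --strategy bma pairs.tsv out.tsv

# seeded synthetic benchmark + ROC/threshold report with confidence bins
hrss fixtures --outdir bench --benchmark --seed 1
awk '{print $0"\t1"}' bench/positives.tsv >  labeled.tsv
awk '{print $0"\t0"}' bench/negatives.tsv >> labeled.tsv
hrss evaluate --obo bench/ontology.obo --gaf bench/annotations.gaf \
    --scheme yeast-bp labeled.tsv report.json roc.tsv

# randomization Z-score for an ortholog pair list
hrss zscore --obo bench/ontology.obo --gaf bench/annotations.gaf \
    --strategy bma --reps 1000 --seed 42 bench/positives.tsv zscore.json
```

## Conventions

- Depths and distances are edge counts with the namespace root at depth 0;
  paths between terms are routed through common ancestors only.
- Only `is_a` links are traversed by default; `part_of` can be enabled via
  `--relations`/`relations=`.
- IC counts distinct genes per namespace; terms with zero annotation count
  have no IC and scoring them raises a `MissingICError`.
- Pairwise gene measures use direct (unpropagated) annotation sets with
  root annotations removed; groupwise measures use propagated sets.
- A pair is predicted positive when its score is >= the threshold; ROC
  sweeps descending unique scores plus a sentinel above the maximum.
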