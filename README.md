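# phylodag

Compact storage, combinatorial extension and likelihood-based ranking of
maximum-parsimony (MP) phylogenetic histories with inferred ancestral
sequences, built around a *history DAG*: a directed acyclic graph whose
vertices are (sequence label, child-clade set) pairs. The graph union of a
collection of histories sharing a leaf set stores shared substructure once
and, by recombining substructures, typically expresses many more MP
histories than were used to build it. Any history score that decomposes as
a sum over edges can be optimized, counted, marginalized and trimmed on the
DAG by linear-time dynamic programming.

The package includes:

- **`phylodag.sdag`** — the history DAG: graph union, ambiguity expansion,
  completion (adding all clade-compatible edges), collapsing of
  zero-mutation internal edges, history extraction/enumeration.
- **`phylodag.weights`** — generic DP engine over edge-decomposable weights:
  `optimal_weight`, `trim`, `count_histories`, `marginalize` (log-domain
  sum-product), `lexicographic_trim`, `linear_combination`.
- **`phylodag.parsimony`** — Hamming edge weight, per-site MP ancestral
  state sets (IUPAC-coded), and an exhaustive MP-tree generator for tiny
  leaf sets (a desk-scale stand-in for an external parsimony search).
- **`phylodag.context`** — 5-mer mutability models (S5F-style CSV:
  `fivemer,rate,A,C,G,T`) and the Poisson context branch log-likelihood
  `sum log(lambda_j) + n log(t_hat) - n` with the branch length at its MLE
  `t_hat = n / sum_j gamma_j`; N-padded end contexts resolve to arithmetic
  means over compatible 5-mers.
- **`phylodag.branching`** — abundance-aware branching-process likelihood
  `f(c, m | p, q)` per genotype (binary branching probability `p`, per-child
  mutation probability `q`), edge-decomposable on collapsed genotype trees,
  with `(p, q)` fitted by maximizing the marginal likelihood over every
  history in the DAG.
- **`phylodag.simulator`** — germinal-centre B-cell evolution: carrying
  capacity competition, 5-mer context mutation, paratope/structural site
  partition, weighted amino-acid target distance selection, affinity-ranked
  sampling, true-genealogy output.
- **`phylodag.metrics`** — the MRCA sequence distance (per-taxon-pair
  normalized Hamming distance between true and inferred MRCA sequences) and
  Robinson–Foulds.
- **`phylodag.io` / `phylodag.cli`** — FASTA + abundance TSV readers, newick
  + FASTA history round-tripping, a PHYLIP `dnapars` outfile parser, DAG
  JSON serialization, and a `click` CLI.

## CLI

```sh
# simulate a germinal centre and write sampled sequences + true history
phylodag simulate --seed 1 --generations 20 --outdir sim/

# build a DAG from histories (newick + FASTA pairs, or a dnapars outfile)
phylodag build --tree sim/true.nwk sim/true.fasta --out dag.json

# full pipeline: union -> expand ambiguities -> complete -> trim to MP ->
# collapse -> fit (p, q) -> rank (default: branching-process likelihood,
# then Poisson context likelihood)
phylodag rank --tree tree1.nwk tree1.fasta --tree tree2.nwk tree2.fasta \
    --fasta obs.fasta --abundances obs.tsv \
    --mutability-model model.csv --fit --outdir out/

# rank by a linear combination instead of lexicographically
phylodag rank ... --ranking bp_likelihood,context_likelihood \
    --coefficients 1.0,0.5 --outdir out/

# compare an inferred history against the truth (MRCA distance + RF)
phylodag compare true.nwk true.fasta best.nwk best.fasta

# convert a dnapars outfile into newick + FASTA histories
phylodag convert outfile --outdir trees/
```

`rank` writes `best.nwk`/`best.fasta` (the top-ranked history),
`dag.json` (the trimmed DAG) and `report.json` (history counts per pipeline
stage, fitted parameters, optimal criterion values).

## File formats

- **Abundances**: two-column TSV `sequence_id<TAB>count`; ids must appear in
  the accompanying FASTA; duplicate sequences are merged with summed counts.
- **Histories**: newick with named internal nodes + FASTA mapping node
  names to sequences. Branch lengths are ignored by ranking.
- **Mutability model**: CSV with header `fivemer,rate,A,C,G,T`, one row per
  each of the 1024 unambiguous 5-mers; the central-base column is 0.
- **DAG JSON** (schema version 1): label table, node table (`label` index +
  clades as sorted label-index lists), edge list, UA children; `.gz` paths
  are transparently compressed.

Sequence sites are 1-based in documentation and error messages.
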