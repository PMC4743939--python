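# plastidarch

Comparative analysis of chloroplast genome architecture for people who work
on organelle genome evolution: detecting the quadripartite structure
(inverted repeat, large and small single-copy regions), extracting signed
gene orders, decomposing two genomes into syntenic blocks, computing the
minimum reversal distance, and tracing signed gene-pair (adjacency)
characters on a phylogeny under Dollo parsimony. A ground-truthed synthetic
genome evolver makes every stage testable without downloading any data.

## The science in brief

A typical chloroplast genome is a circle partitioned as
IR<sub>A</sub> + LSC + IR<sub>B</sub> + SSC, where the two IR copies are
exact reverse complements carrying the rRNA operon
(*rrs*–*trnI(gau)*–*trnA(ugc)*–*rrl*–*rrf*). Lineages differ by IR
expansion/contraction (genes crossing the repeat boundary), gene losses, and
inversions that shuffle gene order. `plastidarch` quantifies these
differences at gene-level resolution:

- **Signed gene order** π: the genes around the circle, each signed by
  coding strand, with one IR copy removed so every gene appears once.
- **Reversal distance** between two genomes, via the Hannenhalli–Pevzner
  breakpoint-graph formula *d* = (*n* + 1) − *c* + *h* + *f*
  (cycles, hurdles, fortress) — the exact minimum number of inversions, not
  a lower bound. Circular genomes are handled by the standard anchor
  reduction; a breadth-first-search oracle validates the implementation
  exhaustively for small *n*.
- **Syntenic blocks**: maximal runs of conserved signed adjacencies; on the
  circular adjacency graph, so blocks spanning the linearization origin are
  not fragmented.
- **Signed gene pairs** as phylogenetic characters: an adjacency is named
  by the gene ends that abut (e.g. `3'psaM-5'trnQ(uug)`) and is invariant
  under reverse complement. Pairs present in ≥ 3 taxa are coded
  present / absent / inapplicable (gray: a pair whose gene was itself lost)
  and traced on a rooted tree under Dollo parsimony (one gain, minimal
  losses), classifying each character as synapomorphic, autapomorphic or
  homoplasic.
- **Ancestral gene partitioning**: each gene of a query genome is labeled
  LSC-origin / SSC-origin / rDNA-operon by its position relative to the
  rRNA operon in a reference genome with an ancestral layout, exposing
  genes the IR acquired from the single-copy regions.

## Worked example

Simulate four genomes along a tree, then run the full pipeline:

```sh
printf '((A,B),(C,D));\n' > tree.nwk
plastidarch simulate --tree tree.nwk --seed 3 --out sim/
plastidarch run sim/A.gb sim/B.gb sim/C.gb sim/D.gb --tree tree.nwk --out run/
```

The run prints (seed 3):

```json
{
  "largest_block_size": 92,
  "n_blocks": 2,
  "n_pair_characters": 88,
  "reversal_distance": 2,
  "shared_genes": 96,
  "unique_to_a": 1,
  "unique_to_b": 1
}
```

Reading: genomes A and B share 96 genes (each lost one gene on its own
branch); their orders differ by 2 inversions (one per branch, matching the
simulation settings), which cut the circle into 2 syntenic blocks, the
larger covering 92 genes across the LSC and IR. `run/` also contains the
per-genome quadripartite maps and partition tables, the blocks table, the
NEXUS pair matrix, the Dollo per-character and per-branch tables, and a
markdown report (`run/report.md`) with an IR/LSC/SSC length table per
genome.

To compare two real annotated genomes, pass their GenBank flat files
(sequence included) to `plastidarch run`; e.g. with the two
chlorodendrophycean chloroplast genomes (GenBank KU167097 and KU167098)
the same command reports their shared gene count, block decomposition,
reversal distance and IR/SSC lengths.

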