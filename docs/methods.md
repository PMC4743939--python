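# Methods

This note documents the models, conventions and numerical choices behind
`plastidarch`, in the order the pipeline applies them.

## Genome model and gene-name normalization

Genomes are read from GenBank flat files. Coordinates are 1-based
inclusive, as in the format itself; a feature crossing the origin of a
circular molecule is stored with `start > end` and a `wraps_origin` flag
(written back as a `join(...)` location). Every gene-bearing feature (CDS,
tRNA, rRNA, other RNAs, plus plain `gene` features not doubled by one of
those) is captured once; `repeat_region` features are kept separately for
annotation-based IR detection. Linear records are accepted with a warning.

Gene symbols are folded to the plastid convention (`PsbA -> psbA`); tRNAs
become `trnX(nnn)` with a lowercase anticodon taken from the name, the
`anticodon`/`product` qualifiers, or an explicit argument. A built-in
synonym table maps common alternates (`rrn16 -> rrs`, `rrn23 -> rrl`,
elongator/initiator methionine tRNAs, ...) and is user-extensible; a tRNA
whose anticodon cannot be resolved is kept verbatim and flagged with a
warning rather than guessed.

The signed gene order keeps one IR copy: genes whose majority length lies
in IR-B are dropped, so the retained copy is IR-A, the one starting at the
smaller coordinate. This choice is arbitrary but deterministic; adjacency
characters are invariant under it because a pair equals its reverse
complement. Residual duplicate gene names abort with the offending names
listed — silent deduplication could hide an annotation error.
Freestanding ORFs (`orf###`) are excluded from gene orders by default;
whether intron-borne ORFs belong in adjacency catalogues is genuinely
debatable, so the exclusion is a flag, not a hard rule.

## Inverted-repeat detection

Sequence-based detection finds the longest pair of disjoint
reverse-complementary segments by seed-and-extend: exact k-mer seeds
(k = min(min_len, 21)) against the reverse complement, grouped by
anti-diagonal (i + j is constant along one inverted alignment) and extended
maximally. The sequence is doubled so repeats and single-copy regions may
span the origin; a wrapped repeat can place two distinct alignment runs on
the same anti-diagonal, so consumed i-ranges are tracked per diagonal
rather than a single flag. Candidates whose two copies overlap on the
circle raise an error rather than returning a half-valid map; no candidate
at all yields an explicit "no IR" map (the whole circle as LSC).

Defaults: `min_len = 1000` bp (well above chance matches at plastome
scale, well below real plastid IRs) and `max_mismatch_frac = 0` — chlorophyte
IR copies are typically kept identical by concerted evolution; a nonzero
fraction enables greedy mismatch-tolerant extension for divergent repeats.
The two single-copy gaps are named by size: the smaller is the SSC, which
may contain zero genes (its length is still nonzero).

Genes are assigned to regions by the majority of their length
(`junction_policy="majority"`); the alternative policy labels
boundary-straddling genes `junction` instead of forcing a call.

Ancestral-origin classification labels each query gene by where its
ortholog sits in a reference genome with an ancestral quadripartite layout,
relative to the rDNA operon: reference-LSC genes are LSC-origin,
reference-SSC genes SSC-origin, the five operon genes rDNA-operon, and
non-operon genes inside the reference IR are assigned to the nearer
single-copy side along the circle. "Within or near" a region is thus
operationalized as strict majority containment plus nearest-side for
IR-resident reference genes; genes at reference junctions could be called
differently under a fuzzier notion of "near".

## Adjacency pairs and the character matrix

An adjacency between neighboring genes is canonicalized over the
reverse-complement symmetry ((a, b) ≡ (−b, −a); the lexicographically
smaller representation wins) and named by the abutting gene ends
(`3'` end of a forward gene faces right, `5'` faces left). Orders are
treated as circular by default, so an order of n genes yields exactly n
pairs including the wrap-around adjacency; a flag disables this for
genuinely linear molecules. Intervening non-coding DNA never breaks an
adjacency: the characters live on the gene order, not the sequence.

States are three-valued. A pair is *inapplicable* in a taxon — not absent —
when at least one of its genes is missing from that taxon's repertoire;
treating gene loss as adjacency loss would double-count a single loss
event. Characters present in fewer than `min_taxa` (default 3) taxa are
dropped. The matrix is written as a standard NEXUS CHARACTERS block
(symbols 0/1, inapplicable as `?`, labels as character-state labels), and
the gene-repertoire presence/absence table is emitted alongside.

## Syntenic blocks

Blocks are maximal runs of conserved adjacencies between two orders reduced
to their shared gene set: the signed gene sequence of a block in genome B
equals that in A or its reversed negation. Block finding runs on the
circular adjacency graph, so a conserved run spanning the linearization
origin is one block, not three. Every shared gene lands in exactly one
block (≥ 2 genes) or in the singleton list; with no singletons the block
count equals the breakpoint count, an identity cross-checked against the
pair module. Gene-level blocks deliberately replace nucleotide-level
colinear-block alignment, whose minimum-weight thresholds can fail to
resolve two-gene clusters.

## Reversal distance

The distance is the full Hannenhalli–Pevzner formula
d = (n + 1) − c + h + f on the breakpoint graph of the framed permutation:
c alternating cycles; hurdles h counted as unoriented components whose
positions are consecutive on the circle of unoriented-component positions
(joining the two frame ends makes the "greatest hurdle" case uniform); the
fortress f when an odd number (≥ 3) of hurdles are all superhurdles. A
cycle-only lower bound would undercount precisely on the hurdle-rich
permutations rearrangement studies care about.

Circular gene orders are reduced by anchoring: rotate (and reflect if
needed) so a chosen gene reads +1 first, then solve the linear problem on
the remaining n − 1 relabeled elements. The reduction is validated against
a breadth-first search that explores genuinely circular states
(canonicalized over rotation and reflection), and the linear formula is
validated against exhaustive BFS for every signed permutation with n ≤ 6
and 1000 random permutations at n = 7. Fortress-bearing permutations do
not occur at these sizes; that branch follows the standard theory and is
exercised only structurally. The distance is deterministic; no
tie-breaking is involved.

## Dollo tracing

Characters are traced under Dollo parsimony: at most one gain, then only
losses. The gain sits on the edge above the MRCA of the present leaves
("root" when that is the root — a character present on both sides of the
root is ancestral, and the data cannot distinguish a root-state from a
gain just above it). Losses are the topmost edges inside the gain clade
whose subtrees contain no present leaf, counted only when the subtree
contains a definitely-absent leaf: inapplicable leaves are wildcards
optimized to whichever state avoids a loss. Minimality of this
construction is verified against an exhaustive search over all gain
placements and loss-edge subsets on random 8-leaf trees. Polytomies are
allowed; a loss on each child edge of a polytomy counts separately.

Classification: invariant (present everywhere applicable, no losses),
autapomorphic (pendant gain, or a single pendant loss), synapomorphic_gain
(internal gain, no losses), synapomorphic_loss (exactly one internal
clade-level loss), homoplasic_loss (≥ 2 independent losses). Any character
with an inapplicable cell anywhere is flagged ambiguous: a taxon that lost
one of the pair's genes could have carried the adjacency, so its support
for a clade cannot be asserted. The tree is always an input; the package
never infers topologies.

## The synthetic evolver

The generator emulates the architecture this pipeline is built for: a
circular ancestor with the rDNA operon mid-IR, a gene-rich LSC, a small
SSC (possibly gene-empty), random gene/spacer sequences, and IR copies
that are exact reverse complements including internal spacers. Defaults —
75 LSC genes, 4 SSC genes, 15 IR genes besides the 5 operon genes (99
genes total), gene lengths 90–1200 bp, spacers 30–200 bp — give a ~90 kb
plastome-like genome with a realistic ~100-gene complement. One junction
base on each side of each IR copy is set so the planted repeat cannot be
extended by chance, making detected coordinates exactly comparable to the
planted truth.

Evolution along a rooted tree applies, per branch, a configured number of
whole-gene events: inversions confined to one region (re-mirrored into
IR-B when they hit the IR, as concerted evolution would), gene losses
(both IR copies at once; the operon is immune), and IR boundary shifts
moving whole genes between the repeat and an adjacent single-copy region.
Infeasible draws are resampled up to a cap. All randomness flows from one
stream seeded by the configuration, branches are visited in preorder, and
spacer synthesis is seeded per genome id, so runs are bit-reproducible and
replaying the event log over the ancestor reproduces every tip exactly.

What the generator does *not* emulate — nucleotide substitutions,
intron gain/loss, intra-gene breakpoints, duplications outside the IR,
annotation noise — bounds what passing tests show: the pipeline's
combinatorics are exact on clean gene-level data; robustness to divergent
IR copies or mis-annotated real records is limited to the mismatch
tolerance and synonym table described above.

## Problem sizes used in verification

The shipped verification (test suite and `scripts/acceptance.py`) uses
exhaustive reversal checks to n = 6 plus 1000 random permutations at
n = 7, 200 random 8-leaf trees for Dollo minimality, 100 seeded genomes
(25 LSC / 2 SSC / 5 + operon IR genes) for planted-IR recovery, and
40–99-gene orders for the conservation laws — sizes at which the
brute-force oracles are themselves exact and fast, and which match or
exceed the gene counts of real plastomes for the gene-order statistics.
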