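"""Gene-level syntenic blocks between two signed gene orders.

A syntenic block is a maximal run of two or more genes whose signed order
in genome B equals that in genome A or its reversed negation — i.e. a
maximal run of conserved adjacencies.  Working at gene level (rather than
on nucleotide alignments) keeps very small conserved clusters resolvable
and, because block finding runs on the circular adjacency graph, a block
may span the linearization origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .gene_pairs import adjacency_pairs, canonicalize
from .genome_model import SignedGene, SignedGeneOrder
from .quadripartite import PartitionReport


@dataclass
class SyntenicBlock:
    """A maximal conserved run, reported in genome A's orientation."""

    genes: tuple[SignedGene, ...]
    location_a: tuple[int, int]  # inclusive index range in order A (may wrap)
    location_b: tuple[int, int]  # inclusive index range in order B (may wrap)
    orientation: str  # 'same' | 'inverted'
    regions_a: set[str] = field(default_factory=set)
    regions_b: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.genes)

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]


def shared_blocks(
    a: SignedGeneOrder, b: SignedGeneOrder
) -> tuple[list[SyntenicBlock], list[str]]:
    """Decompose two same-gene-set orders into maximal blocks and singletons.

    Every shared gene lands in exactly one block (>= 2 genes) or in the
    singleton list.  Orders must already be reduced to their shared gene
    set (see :func:`plastidarch.genome_model.reduce_to_shared`).
    """
    if a.name_set() != b.name_set():
        raise ValueError(
            "gene sets differ; reduce both orders to the shared set first"
        )
    n = len(a)
    if n == 0:
        return [], []
    pos_b = {g.name: i for i, g in enumerate(b.genes)}
    sign_b = {g.name: g.sign for g in b.genes}
    bpairs = adjacency_pairs(b) if len(b) > 1 else set()

    def conserved(i: int) -> bool:
        j = (i + 1) % n
        if not a.circular and j == 0:
            return False
        return canonicalize(a.genes[i], a.genes[j]) in bpairs

    if n == 1:
        return [], [a.genes[0].name]

    adj_count = n if a.circular else n - 1
    flags = [conserved(i) for i in range(adj_count)]

    if all(flags) and a.circular:
        block = _make_block(tuple(a.genes), (0, n - 1), pos_b, sign_b, len(b))
        return [block], []

    # start just after a breakpoint so no run is split at the wrap point
    if a.circular:
        start = (next(i for i, f in enumerate(flags) if not f) + 1) % n
    else:
        start = 0
    blocks: list[SyntenicBlock] = []
    singletons: list[str] = []
    run: list[int] = [start]
    for step in range(n - 1):
        i = (start + step) % n  # adjacency between gene i and gene i+1 (mod n)
        if flags[i]:
            run.append((i + 1) % n)
        else:
            _flush(run, a, blocks, singletons, pos_b, sign_b, len(b))
            run = [(i + 1) % n]
    _flush(run, a, blocks, singletons, pos_b, sign_b, len(b))
    return blocks, singletons


def _flush(run, a, blocks, singletons, pos_b, sign_b, nb) -> None:
    if len(run) >= 2:
        genes = tuple(a.genes[i] for i in run)
        blocks.append(_make_block(genes, (run[0], run[-1]), pos_b, sign_b, nb))
    else:
        singletons.append(a.genes[run[0]].name)


def _make_block(genes, location_a, pos_b, sign_b, nb) -> SyntenicBlock:
    first, last = genes[0], genes[-1]
    if len(genes) >= 2:
        second = genes[1]
        forward = pos_b[second.name] == (pos_b[first.name] + 1) % nb and (
            sign_b[first.name] == first.sign
        )
    else:
        forward = sign_b[first.name] == first.sign
    if forward:
        orientation = "same"
        location_b = (pos_b[first.name], pos_b[last.name])
    else:
        orientation = "inverted"
        location_b = (pos_b[last.name], pos_b[first.name])
    return SyntenicBlock(
        genes=genes,
        location_a=location_a,
        location_b=location_b,
        orientation=orientation,
    )


def annotate_block_regions(
    blocks: Sequence[SyntenicBlock],
    partition_a: Optional[PartitionReport],
    partition_b: Optional[PartitionReport],
) -> None:
    """Fill each block's set of spanned region labels in both genomes."""
    reg_a = partition_a.region_of() if partition_a else {}
    reg_b = partition_b.region_of() if partition_b else {}
    for blk in blocks:
        blk.regions_a = {reg_a[g] for g in blk.gene_names() if g in reg_a}
        blk.regions_b = {reg_b[g] for g in blk.gene_names() if g in reg_b}


def block_stats(
    blocks: Sequence[SyntenicBlock],
    singletons: Sequence[str],
    partitions: Optional[tuple[PartitionReport, PartitionReport]] = None,
) -> dict:
    """Summary of a block decomposition (counts, coverage, largest blocks)."""
    if partitions is not None:
        annotate_block_regions(blocks, partitions[0], partitions[1])
    ordered = sorted(blocks, key=lambda b: (-len(b), b.gene_names()))
    rows = []
    for i, blk in enumerate(ordered, start=1):
        rows.append(
            {
                "block": i,
                "size": len(blk),
                "orientation": blk.orientation,
                "start_a": blk.location_a[0],
                "end_a": blk.location_a[1],
                "start_b": blk.location_b[0],
                "end_b": blk.location_b[1],
                "regions_a": ",".join(sorted(blk.regions_a)),
                "regions_b": ",".join(sorted(blk.regions_b)),
                "genes": " ".join(str(g) for g in blk.genes),
            }
        )
    genes_in_blocks = sum(len(b) for b in blocks)
    shared = genes_in_blocks + len(singletons)
    return {
        "n_blocks": len(blocks),
        "genes_in_blocks": genes_in_blocks,
        "n_singletons": len(singletons),
        "shared_genes": shared,
        "coverage": genes_in_blocks / shared if shared else 0.0,
        "largest_block_size": len(ordered[0]) if ordered else 0,
        "largest_block_regions": sorted(ordered[0].regions_a) if ordered else [],
        "table": pd.DataFrame(rows),
        "singletons": sorted(singletons),
    }


def blocks_to_gff3(
    blocks: Sequence[SyntenicBlock],
    genome_id: str,
    which: str = "a",
) -> str:
    """GFF3 track of block index ranges (gene-index coordinates, 1-based)."""
    lines = ["##gff-version 3"]
    ordered = sorted(blocks, key=lambda b: (-len(b), b.gene_names()))
    for i, blk in enumerate(ordered, start=1):
        loc = blk.location_a if which == "a" else blk.location_b
        strand = "+" if (which == "a" or blk.orientation == "same") else "-"
        lines.append(
            f"{genome_id}\tplastidarch\tsyntenic_block\t{loc[0] + 1}\t{loc[1] + 1}"
            f"\t.\t{strand}\t.\tID=block{i};size={len(blk)}"
        )
    return "\n".join(lines) + "\n"
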