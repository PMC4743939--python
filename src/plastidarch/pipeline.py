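"""End-to-end comparative analysis: parse -> quadripartite -> orders ->
pairs -> blocks -> distance -> Dollo -> report.

The pipeline is deterministic given its configuration: all tabular outputs
are sorted on stable keys and the only randomness in the package lives in
the synthetic evolver.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import dollo as dollo_mod
from . import gene_pairs, genome_model, quadripartite, reversal, synteny

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class RunConfig:
    genome_paths: list[str]
    out_dir: str
    reference_path: Optional[str] = None
    tree_path: Optional[str] = None
    min_taxa: int = 3
    ir_min_len: int = 1000
    junction_policy: str = "majority"
    drop_orfs: bool = True
    topology: str = "circular"  # for the reversal stage
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in list(self.genome_paths) + [
            p for p in (self.reference_path, self.tree_path) if p
        ]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _quad_for(genome, min_len):
    if genome.sequence is not None:
        return quadripartite.detect_inverted_repeat(genome, min_len=min_len)
    if len(genome.repeat_regions) == 2:
        return quadripartite.detect_ir_from_annotation(genome)
    return quadripartite.no_ir_map(genome.length)


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage; write machine-readable outputs.

    Pairwise stages (blocks, reversal distance) use the first two genomes;
    the pair-matrix and Dollo stages need at least three genomes and a
    tree.  Returns the in-memory report bundle.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"summary": {}, "genomes": {}}

    genomes = []
    for path in config.genome_paths:
        try:
            genomes.append(genome_model.read_genbank(path))
        except Exception as exc:
            raise PipelineError("parse", f"{path}: {exc}") from exc

    reference = None
    if config.reference_path:
        reference = genome_model.read_genbank(config.reference_path)
        ref_quad = _quad_for(reference, config.ir_min_len)

    orders = {}
    partitions = {}
    for genome in genomes:
        try:
            quad = _quad_for(genome, config.ir_min_len)
            part = quadripartite.assign_regions(
                genome, quad, junction_policy=config.junction_policy
            )
            if reference is not None:
                part = quadripartite.classify_ancestral_origin(
                    part, reference, ref_quad
                )
            order = genome_model.extract_signed_gene_order(
                genome, quad=quad, drop_orfs=config.drop_orfs
            )
        except Exception as exc:
            raise PipelineError("quadripartite/order", f"{genome.id}: {exc}") from exc
        orders[genome.id] = order
        partitions[genome.id] = part
        (out / f"{genome.id}.quad.json").write_text(quad.to_json())
        (out / f"{genome.id}.partition.tsv").write_text(part.to_tsv())
        genome_model.write_order_tsv(
            order, out / f"{genome.id}.order.tsv", genome, part.region_of()
        )
        bundle["genomes"][genome.id] = {
            "length": genome.length,
            "n_genes": len(order),
            "ir_length": quad.ir_length,
            "lsc_length": quad.lsc_length,
            "ssc_length": quad.ssc_length,
            "quad": quad,
            "partition": part,
            "order": order,
        }

    summary = bundle["summary"]
    if len(genomes) >= 2:
        ga, gb = genomes[0].id, genomes[1].id
        try:
            ra, rb, ua, ub = genome_model.reduce_to_shared(orders[ga], orders[gb])
            blocks, singletons = synteny.shared_blocks(ra, rb)
            stats = synteny.block_stats(
                blocks, singletons, (partitions[ga], partitions[gb])
            )
            perm = reversal.to_permutation(ra, rb)
            dist = reversal.reversal_distance(perm)
        except Exception as exc:
            raise PipelineError("synteny/distance", f"{ga} vs {gb}: {exc}") from exc
        stats["table"].to_csv(out / "blocks.tsv", sep="\t", index=False)
        (out / "distance.json").write_text(
            json.dumps({"a": ga, "b": gb, "topology": perm.topology,
                        **dist.as_dict()}, indent=2)
        )
        bundle["blocks"] = blocks
        bundle["block_stats"] = stats
        bundle["distance"] = dist
        summary.update(
            {
                "pairwise_a": ga,
                "pairwise_b": gb,
                "shared_genes": len(ra),
                "unique_to_a": len(ua),
                "unique_to_b": len(ub),
                "n_blocks": stats["n_blocks"],
                "genes_in_blocks": stats["genes_in_blocks"],
                "largest_block_size": stats["largest_block_size"],
                "largest_block_regions": stats["largest_block_regions"],
                "reversal_distance": dist.d,
            }
        )

    if len(genomes) >= 3:
        try:
            matrix = gene_pairs.build_pair_matrix(
                [orders[g.id] for g in genomes],
                repertoires={g.id: g.gene_names() for g in genomes},
                min_taxa=config.min_taxa,
            )
        except Exception as exc:
            raise PipelineError("pair_matrix", str(exc)) from exc
        gene_pairs.write_nexus(matrix, out / "pairs.nex")
        (out / "pairs.long.tsv").write_text(matrix.to_long_tsv())
        matrix.repertoire_table().to_csv(out / "gene_repertoire.tsv", sep="\t")
        bundle["pair_matrix"] = matrix
        summary["n_pair_characters"] = len(matrix.characters)

        if config.tree_path:
            try:
                tree = dollo_mod.read_newick(config.tree_path)
                dollo_mod.check_taxa(tree, matrix.taxa)
                results = dollo_mod.trace_matrix(tree, matrix)
            except Exception as exc:
                raise PipelineError("dollo", str(exc)) from exc
            rows = sorted((r.as_row() for r in results), key=lambda r: r["character"])
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "dollo.characters.tsv", sep="\t",
                                      index=False)
            dollo_mod.per_branch_summary(results, tree).to_csv(
                out / "dollo.branches.tsv", sep="\t", index=False
            )
            (out / "dollo.annotated.nwk").write_text(
                dollo_mod.annotated_newick(tree, results) + "\n"
            )
            bundle["dollo"] = results
            summary["n_synapomorphic_pairs"] = sum(
                1 for r in results if r.classification == "synapomorphic_gain"
            )
            summary["n_homoplasic_pairs"] = sum(
                1 for r in results if r.classification == "homoplasic_loss"
            )

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(config, out)
    return bundle


def _write_manifest(config: RunConfig, out: Path) -> None:
    def digest(path: str) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()[:16]

    manifest = {
        "inputs": {p: digest(p) for p in config.genome_paths},
        "reference": (
            {config.reference_path: digest(config.reference_path)}
            if config.reference_path
            else None
        ),
        "tree": config.tree_path,
        "parameters": {
            "min_taxa": config.min_taxa,
            "ir_min_len": config.ir_min_len,
            "junction_policy": config.junction_policy,
            "drop_orfs": config.drop_orfs,
            "topology": config.topology,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def make_report(bundle: dict) -> str:
    """Human-readable markdown summary of a pipeline run."""
    lines = ["# Chloroplast genome architecture report", ""]
    if bundle.get("genomes"):
        lines += [
            "## Genomes",
            "",
            "| genome | size (bp) | genes | IR (bp) | LSC (bp) | SSC (bp) |",
            "|---|---|---|---|---|---|",
        ]
        for gid in sorted(bundle["genomes"]):
            g = bundle["genomes"][gid]
            lines.append(
                f"| {gid} | {g['length']} | {g['n_genes']} | {g['ir_length']} "
                f"| {g['lsc_length']} | {g['ssc_length']} |"
            )
        lines.append("")
    s = bundle.get("summary", {})
    if "shared_genes" in s:
        lines += [
            "## Pairwise comparison",
            "",
            f"- genomes: {s['pairwise_a']} vs {s['pairwise_b']}",
            f"- shared genes: {s['shared_genes']}",
            f"- syntenic blocks: {s['n_blocks']} covering {s['genes_in_blocks']} genes",
            f"- largest block: {s['largest_block_size']} genes"
            + (
                f" (regions: {', '.join(s['largest_block_regions'])})"
                if s.get("largest_block_regions")
                else ""
            ),
            f"- minimum reversal distance: {s['reversal_distance']}",
            "",
        ]
    if "n_pair_characters" in s:
        lines += [
            "## Gene-pair characters",
            "",
            f"- characters coded: {s['n_pair_characters']}",
        ]
        if "n_synapomorphic_pairs" in s:
            lines += [
                f"- synapomorphic gains: {s['n_synapomorphic_pairs']}",
                f"- homoplasic losses: {s['n_homoplasic_pairs']}",
            ]
        lines.append("")
    return "\n".join(lines)
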