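"""Ground-truthed synthetic evolution of quadripartite chloroplast genomes.

Generates an ancestral circular genome with the canonical architecture —
an inverted repeat carrying the rDNA operon, a gene-rich LSC and a small
SSC — and evolves it along a rooted tree by whole-gene events: segment
inversions inside one region, gene losses (both IR copies at once), and
IR boundary shifts that move whole genes between the repeat and the
flanking single-copy regions.  Every event is logged, so each stage of the
comparative pipeline can be tested against a known truth without any
external data.

Events operate at gene granularity; nucleotide-level breakpoints inside
genes, substitutions and intron dynamics are deliberately out of scope.
Inversions never partially overlap an IR copy, mirroring the concerted
evolution that keeps real IR copies identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genome_model import AnnotatedGenome, GeneFeature, SignedGene, SignedGeneOrder
from .quadripartite import QuadripartiteMap, _build_map, revcomp
from .dollo import RootedTree

#: rDNA operon, always kept inside the IR in transcription order
RDNA_OPERON = ("rrs", "trnI(gau)", "trnA(ugc)", "rrl", "rrf")

#: plastid-like gene vocabulary for naming synthetic genes
PLASTID_VOCABULARY = [
    "atpA", "atpB", "atpE", "atpF", "atpH", "atpI", "accD", "ccsA", "cemA",
    "chlB", "chlI", "chlL", "chlN", "clpP", "cysA", "cysT", "ftsH", "infA",
    "minD", "petA", "petB", "petD", "petG", "petL", "psaA", "psaB", "psaC",
    "psaI", "psaJ", "psaM", "psbA", "psbB", "psbC", "psbD", "psbE", "psbF",
    "psbH", "psbI", "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ",
    "rbcL", "rpl2", "rpl5", "rpl12", "rpl14", "rpl16", "rpl19", "rpl20",
    "rpl23", "rpl32", "rpl36", "rpoA", "rpoB", "rpoC1", "rpoC2", "rps2",
    "rps3", "rps4", "rps7", "rps8", "rps9", "rps11", "rps12", "rps14",
    "rps18", "rps19", "rnpB", "tufA", "ycf1", "ycf3", "ycf4", "ycf12",
    "ycf20", "ycf47", "ycf62",
    "trnC(gca)", "trnD(guc)", "trnE(uuc)", "trnF(gaa)", "trnG(gcc)",
    "trnG(ucc)", "trnH(gug)", "trnI(cau)", "trnK(uuu)", "trnL(caa)",
    "trnL(uaa)", "trnL(uag)", "trnMe(cau)", "trnMf(cau)", "trnN(guu)",
    "trnP(ugg)", "trnQ(uug)", "trnR(acg)", "trnR(ccg)", "trnR(ucu)",
    "trnS(gcu)", "trnS(gga)", "trnS(uga)", "trnT(ugu)", "trnV(uac)",
    "trnW(cca)", "trnY(gua)",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the generator; the defaults emulate a ~100-gene plastome."""

    n_lsc_genes: int = 75
    n_ssc_genes: int = 4
    n_ir_genes: int = 15  # besides the five rDNA operon genes
    gene_length_range: tuple[int, int] = (90, 1200)
    spacer_length_range: tuple[int, int] = (30, 200)
    inversions_per_branch: int = 1
    losses_per_branch: int = 1
    ir_shifts_per_branch: int = 0
    inversion_span_range: tuple[int, int] = (2, 6)
    ir_shift_span_range: tuple[int, int] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lsc_genes", "n_ssc_genes", "n_ir_genes",
                     "inversions_per_branch", "losses_per_branch",
                     "ir_shifts_per_branch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_lsc_genes < 2:
            raise ValueError("need at least 2 LSC genes to anchor the architecture")


@dataclass
class Event:
    """One recorded evolutionary event on a branch."""

    kind: str  # inversion | gene_loss | ir_shift
    params: dict


@dataclass
class GenomeArchitecture:
    """Gene-level state of one genome: three region gene lists + sequences.

    The circle reads LSC, IR-A, SSC, IR-B where IR-B is the reverse
    complement of IR-A (including intergenic spacers), so only one IR copy
    is stored.
    """

    lsc: list[SignedGene]
    ir: list[SignedGene]
    ssc: list[SignedGene]
    gene_seqs: dict[str, str]

    def copy(self) -> "GenomeArchitecture":
        return GenomeArchitecture(
            list(self.lsc), list(self.ir), list(self.ssc), self.gene_seqs
        )

    def all_genes(self) -> list[SignedGene]:
        return self.lsc + self.ir + self.ssc

    def reduced_order(self, genome_id: str = "") -> SignedGeneOrder:
        """The IR-deduplicated circular signed gene order."""
        return SignedGeneOrder(genome_id, tuple(self.all_genes()), circular=True)

    def region_of(self) -> dict[str, str]:
        out = {}
        for g in self.lsc:
            out[g.name] = "LSC"
        for g in self.ir:
            out[g.name] = "IR"
        for g in self.ssc:
            out[g.name] = "SSC"
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows: ancestor, per-branch events, tips."""

    config: EvolutionConfig
    ancestor: AnnotatedGenome
    ancestor_arch: GenomeArchitecture
    events: dict[str, list[Event]]  # keyed by child-node edge id
    tip_archs: dict[str, GenomeArchitecture]
    tip_genomes: dict[str, AnnotatedGenome]
    tip_quads: dict[str, QuadripartiteMap]


def _category(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name in ("rrs", "rrl", "rrf"):
        return "rRNA"
    if name == "rnpB":
        return "other_RNA"
    return "protein"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "T"), size=length))


# ---------------------------------------------------------------------------
# ancestor construction


def make_architecture(config: EvolutionConfig) -> GenomeArchitecture:
    """Build the ancestral gene-level architecture (seeded, reproducible)."""
    rng = np.random.default_rng(config.seed)
    needed = config.n_lsc_genes + config.n_ssc_genes + config.n_ir_genes
    vocab = [n for n in PLASTID_VOCABULARY if n not in RDNA_OPERON]
    if needed > len(vocab):
        extra = [f"ycf{100 + i}" for i in range(needed - len(vocab))]
        vocab = vocab + extra
    picked = [str(x) for x in rng.choice(vocab, size=needed, replace=False)]
    lsc_names = picked[: config.n_lsc_genes]
    ir_extra = picked[config.n_lsc_genes : config.n_lsc_genes + config.n_ir_genes]
    ssc_names = picked[config.n_lsc_genes + config.n_ir_genes :]

    def signed(names: Sequence[str]) -> list[SignedGene]:
        return [SignedGene(n, int(rng.choice((-1, 1)))) for n in names]

    # the operon sits mid-IR in transcription order on one strand
    half = len(ir_extra) // 2
    ir = (
        signed(ir_extra[:half])
        + [SignedGene(n, +1) for n in RDNA_OPERON]
        + signed(ir_extra[half:])
    )
    lsc, ssc = signed(lsc_names), signed(ssc_names)
    lo, hi = config.gene_length_range
    gene_seqs = {
        g.name: _random_seq(rng, int(rng.integers(lo, hi + 1)))
        for g in lsc + ir + ssc
    }
    return GenomeArchitecture(lsc=lsc, ir=ir, ssc=ssc, gene_seqs=gene_seqs)


def make_ancestor(config: EvolutionConfig) -> AnnotatedGenome:
    """Materialize the ancestral genome (annotation + sequence)."""
    return materialize(make_architecture(config), "ancestor", config)[0]


# ---------------------------------------------------------------------------
# materialization to an annotated, sequenced genome


def materialize(
    arch: GenomeArchitecture, genome_id: str, config: EvolutionConfig
) -> tuple[AnnotatedGenome, QuadripartiteMap]:
    """Render an architecture into sequence + features, IR copies identical.

    Spacer sequences are drawn from a stream seeded by (config seed,
    genome id), so the same architecture always renders to the same bytes.
    """
    rng = np.random.default_rng([config.seed, zlib.crc32(genome_id.encode())])
    lo, hi = config.spacer_length_range
    lo = max(2, lo)

    def spacer() -> str:
        return _random_seq(rng, int(rng.integers(lo, hi + 1)))

    def oriented(g: SignedGene) -> str:
        s = arch.gene_seqs[g.name]
        return s if g.sign > 0 else revcomp(s)

    chunks: list[str] = []
    feats: list[tuple[SignedGene, int, int]] = []  # gene, start0, end0 (half-open)
    pos = 0

    def emit_gene(g: SignedGene) -> None:
        nonlocal pos
        sp = spacer()
        chunks.append(sp)
        pos += len(sp)
        gs = oriented(g)
        chunks.append(gs)
        feats.append((g, pos, pos + len(gs)))
        pos += len(gs)

    for g in arch.lsc:
        emit_gene(g)
    ira_start = pos + 0
    ira_chunks: list[str] = []
    ira_feats: list[tuple[SignedGene, int, int]] = []
    for g in arch.ir:
        sp = spacer()
        ira_chunks.append(sp)
        gs = oriented(g)
        off = sum(len(c) for c in ira_chunks)
        ira_chunks.append(gs)
        ira_feats.append((g, off, off + len(gs)))
    ira_block = "".join(ira_chunks)
    chunks.append(ira_block)
    for g, s, e in ira_feats:
        feats.append((g, ira_start + s, ira_start + e))
    pos += len(ira_block)
    ira_end = pos
    for g in arch.ssc:
        emit_gene(g)
    chunks.append(spacer())  # guarantees a nonzero SSC gap even with 0 genes
    pos = sum(len(c) for c in chunks)
    irb_start = pos
    irb_block = revcomp(ira_block)
    chunks.append(irb_block)
    for g, s, e in ira_feats:  # mirrored copies, flipped strand
        feats.append(
            (-g, irb_start + (len(ira_block) - e), irb_start + (len(ira_block) - s))
        )
    pos += len(irb_block)
    chunks.append(spacer())  # trailing spacer before wrapping to LSC
    seq = list("".join(chunks))
    n = len(seq)
    irb_end = irb_start + len(irb_block)

    # block IR extension at all four junctions (bases just outside the copies)
    seq[(ira_start - 1) % n] = "A"
    seq[irb_end % n] = "A"
    seq[ira_end % n] = "A"
    seq[(irb_start - 1) % n] = "A"
    sequence = "".join(seq)

    features = [
        GeneFeature(
            raw_name=g.name,
            normalized_name=g.name,
            category=_category(g.name),
            strand="+" if g.sign > 0 else "-",
            start=s + 1,
            end=e,
        )
        for g, s, e in feats
    ]
    genome = AnnotatedGenome(
        id=genome_id,
        length=n,
        circular=True,
        features=features,
        sequence=sequence,
        repeat_regions=[(ira_start + 1, ira_end), (irb_start + 1, irb_end)],
    )
    quad = _build_map(n, (ira_start, len(ira_block)), (irb_start, len(irb_block)))
    return genome, quad


# ---------------------------------------------------------------------------
# evolutionary events


class InfeasibleEventError(RuntimeError):
    pass


def apply_event(arch: GenomeArchitecture, event: Event) -> GenomeArchitecture:
    """Apply one recorded event; pure (returns a new architecture)."""
    out = arch.copy()
    p = event.params
    if event.kind == "inversion":
        seg = getattr(out, p["region"])
        i, span = p["start"], p["span"]
        seg[i : i + span] = [-g for g in reversed(seg[i : i + span])]
    elif event.kind == "gene_loss":
        seg = getattr(out, p["region"])
        idx = next(i for i, g in enumerate(seg) if g.name == p["gene"])
        del seg[idx]
    elif event.kind == "ir_shift":
        k, side, direction = p["k"], p["side"], p["direction"]
        if side == "lsc" and direction == "expand":
            out.ir[:0] = out.lsc[-k:]
            del out.lsc[-k:]
        elif side == "lsc" and direction == "contract":
            out.lsc.extend(out.ir[:k])
            del out.ir[:k]
        elif side == "ssc" and direction == "expand":
            out.ir.extend(out.ssc[:k])
            del out.ssc[:k]
        elif side == "ssc" and direction == "contract":
            out.ssc[:0] = out.ir[-k:]
            del out.ir[-k:]
        else:
            raise ValueError(f"bad ir_shift parameters: {p}")
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return out


def _sample_event(
    arch: GenomeArchitecture, kind: str, rng: np.random.Generator,
    config: EvolutionConfig, max_tries: int = 50,
) -> Optional[Event]:
    operon = set(RDNA_OPERON)
    for _ in range(max_tries):
        if kind == "inversion":
            eligible = [r for r in ("lsc", "ir", "ssc") if len(getattr(arch, r)) >= 2]
            if not eligible:
                break
            region = eligible[int(rng.integers(len(eligible)))]
            seg = getattr(arch, region)
            lo, hi = config.inversion_span_range
            span = int(rng.integers(max(2, lo), max(2, min(hi, len(seg))) + 1))
            if span > len(seg):
                continue
            start = int(rng.integers(0, len(seg) - span + 1))
            genes = [g.name for g in seg[start : start + span]]
            return Event("inversion", {"region": region, "start": start,
                                       "span": span, "genes": genes})
        if kind == "gene_loss":
            pool = [
                (r, g)
                for r in ("lsc", "ir", "ssc")
                for g in getattr(arch, r)
                if g.name not in operon
            ]
            if not pool:
                break
            region, gene = pool[int(rng.integers(len(pool)))]
            return Event("gene_loss", {"region": region, "gene": gene.name})
        if kind == "ir_shift":
            side = ("lsc", "ssc")[int(rng.integers(2))]
            direction = ("expand", "contract")[int(rng.integers(2))]
            lo, hi = config.ir_shift_span_range
            k = int(rng.integers(lo, hi + 1))
            if direction == "expand":
                source = arch.lsc if side == "lsc" else arch.ssc
                moved = source[-k:] if side == "lsc" else source[:k]
                if len(source) < k + (1 if side == "lsc" else 0):
                    continue
            else:
                moved = arch.ir[:k] if side == "lsc" else arch.ir[-k:]
                if len(arch.ir) < k or any(g.name in operon for g in moved):
                    continue
            return Event("ir_shift", {"side": side, "direction": direction,
                                      "k": k, "genes": [g.name for g in moved]})
        break
    raise InfeasibleEventError(
        f"could not sample a feasible {kind!r} event after {max_tries} tries"
    )


def evolve(
    tree: RootedTree,
    ancestor: GenomeArchitecture | AnnotatedGenome,
    config: EvolutionConfig,
) -> tuple[dict[str, AnnotatedGenome], GroundTruth]:
    """Evolve the ancestor along every branch of a rooted tree.

    Branches are visited in preorder and all randomness flows from one
    stream seeded by ``config.seed``, so a run is bit-reproducible.
    Returns the tip genomes and the full ground truth (event log per edge,
    tip architectures, true quadripartite maps).
    """
    if isinstance(ancestor, AnnotatedGenome):
        arch0 = architecture_from_genome(ancestor)
    else:
        arch0 = ancestor
    rng = np.random.default_rng([config.seed, 1])
    states: dict[int, GenomeArchitecture] = {id(tree.root): arch0}
    events: dict[str, list[Event]] = {}
    tip_archs: dict[str, GenomeArchitecture] = {}
    for node in tree.nodes_preorder():
        if node.parent is None:
            continue
        arch = states[id(node.parent)].copy()
        branch_events: list[Event] = []
        plan = (
            ["inversion"] * config.inversions_per_branch
            + ["gene_loss"] * config.losses_per_branch
            + ["ir_shift"] * config.ir_shifts_per_branch
        )
        for kind in plan:
            ev = _sample_event(arch, kind, rng, config)
            arch = apply_event(arch, ev)
            branch_events.append(ev)
        events[node.id] = branch_events
        states[id(node)] = arch
        if node.is_leaf:
            tip_archs[node.name] = arch

    tip_genomes: dict[str, AnnotatedGenome] = {}
    tip_quads: dict[str, QuadripartiteMap] = {}
    for name in sorted(tip_archs):
        genome, quad = materialize(tip_archs[name], name, config)
        tip_genomes[name] = genome
        tip_quads[name] = quad
    anc_genome, _ = materialize(arch0, "ancestor", config)
    return tip_genomes, GroundTruth(
        config=config,
        ancestor=anc_genome,
        ancestor_arch=arch0,
        events=events,
        tip_archs=tip_archs,
        tip_genomes=tip_genomes,
        tip_quads=tip_quads,
    )


def replay(truth: GroundTruth, tree: RootedTree) -> dict[str, GenomeArchitecture]:
    """Re-apply the logged events to the ancestor; must reproduce every tip."""
    states: dict[int, GenomeArchitecture] = {id(tree.root): truth.ancestor_arch}
    tips: dict[str, GenomeArchitecture] = {}
    for node in tree.nodes_preorder():
        if node.parent is None:
            continue
        arch = states[id(node.parent)].copy()
        for ev in truth.events[node.id]:
            arch = apply_event(arch, ev)
        states[id(node)] = arch
        if node.is_leaf:
            tips[node.name] = arch
    return tips


def architecture_from_genome(
    genome: AnnotatedGenome, quad: Optional[QuadripartiteMap] = None
) -> GenomeArchitecture:
    """Recover the gene-level architecture of an annotated, sequenced genome."""
    from .quadripartite import assign_regions, detect_inverted_repeat, interval_overlap

    if quad is None:
        if genome.repeat_regions and len(genome.repeat_regions) == 2:
            from .quadripartite import detect_ir_from_annotation

            quad = detect_ir_from_annotation(genome)
        else:
            quad = detect_inverted_repeat(genome, min_len=200)
    part = assign_regions(genome, quad)
    lsc, ir, ssc = [], [], []
    for row in part.rows:  # rows are aligned with the sorted features
        g = SignedGene(row.gene, +1 if row.strand == "+" else -1)
        if row.region == "LSC":
            lsc.append(g)
        elif row.region == "SSC":
            ssc.append(g)
        elif row.region == "IR" and row.copy == "IR-A":
            ir.append(g)
    gene_seqs = {}
    if genome.sequence:
        for f in genome.features:
            if f.wraps_origin:
                sub = genome.sequence[f.start - 1 :] + genome.sequence[: f.end]
            else:
                sub = genome.sequence[f.start - 1 : f.end]
            gene_seqs[f.normalized_name] = sub if f.strand == "+" else revcomp(sub)
    return GenomeArchitecture(lsc=lsc, ir=ir, ssc=ssc, gene_seqs=gene_seqs)


# ---------------------------------------------------------------------------
# GenBank output


_FEATURE_TYPE = {
    "protein": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "other_RNA": "ncRNA",
    "orf": "CDS",
}


def emit_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write a genome as a GenBank flat file that round-trips through
    :func:`plastidarch.genome_model.read_genbank`."""
    record = SeqRecord(
        Seq(genome.sequence or ("N" * genome.length)),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="synthetic chloroplast genome (plastidarch evolver)",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    n = genome.length
    for f in genome.features:
        strand = 1 if f.strand == "+" else -1
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, n, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers = {"gene": [f.raw_name]}
        record.features.append(
            SeqFeature(loc, type=_FEATURE_TYPE.get(f.category, "misc_feature"),
                       qualifiers=qualifiers)
        )
    for s, e in genome.repeat_regions:
        record.features.append(
            SeqFeature(
                SimpleLocation(s - 1, e, 1),
                type="repeat_region",
                qualifiers={"rpt_type": ["inverted"]},
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")
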