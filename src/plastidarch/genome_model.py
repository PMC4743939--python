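"""Annotated chloroplast genomes and signed gene orders.

This module reads annotated organelle genomes from GenBank flat files,
normalizes gene names to the plastid convention (``psbA``, ``trnQ(uug)``,
...), and reduces a genome's annotation to the *signed gene order* on which
all downstream comparative stages (adjacency pairs, syntenic blocks,
reversal distance) operate.  A signed gene order lists the genes once
around the circle, signed by coding strand, with one copy of the inverted
repeat removed so each IR-resident gene appears a single time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

logger = logging.getLogger(__name__)

#: feature keys that carry genes, mapped to gene categories
_CATEGORY_BY_KEY = {
    "CDS": "protein",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ncRNA": "other_RNA",
    "misc_RNA": "other_RNA",
    "tmRNA": "other_RNA",
}

_ORF_RE = re.compile(r"^orf\d*", re.IGNORECASE)


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be parsed into a genome."""


class DuplicateGeneError(ValueError):
    """Raised when unsigned gene names remain duplicated after IR removal."""

    def __init__(self, duplicates: Sequence[str]):
        self.duplicates = sorted(duplicates)
        super().__init__(
            "duplicate unsigned gene names after IR deduplication: "
            + ", ".join(self.duplicates)
            + " (disambiguate via the synonym table or check the IR map)"
        )


class SignedGene(NamedTuple):
    """A gene name with an orientation sign (+1 forward, -1 reverse)."""

    name: str
    sign: int

    def __neg__(self) -> "SignedGene":
        return SignedGene(self.name, -self.sign)

    def __str__(self) -> str:
        return ("+" if self.sign > 0 else "-") + self.name


def parse_signed(token: str) -> SignedGene:
    """Parse ``"+psbA"`` / ``"-psbA"`` / ``"psbA"`` into a :class:`SignedGene`."""
    token = token.strip()
    if token.startswith("-"):
        return SignedGene(token[1:], -1)
    if token.startswith("+"):
        return SignedGene(token[1:], +1)
    return SignedGene(token, +1)


@dataclass(frozen=True)
class GeneFeature:
    """One gene-bearing feature of an annotated genome.

    Coordinates are 1-based inclusive, as in GenBank flat files.  A feature
    spanning the origin of a circular genome has ``start > end`` and
    ``wraps_origin`` set.
    """

    raw_name: str
    normalized_name: str
    category: str  # protein | tRNA | rRNA | other_RNA | orf
    strand: str  # '+' | '-'
    start: int
    end: int
    wraps_origin: bool = False

    def length(self, genome_length: int) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end


@dataclass
class AnnotatedGenome:
    """A circular (or linear) annotated genome."""

    id: str
    length: int
    circular: bool
    features: list[GeneFeature]
    sequence: Optional[str] = None
    #: (start, end) 1-based inclusive coordinates of any repeat_region features
    repeat_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        self.features.sort(key=lambda f: (f.start, f.end))

    def gene_names(self) -> set[str]:
        return {f.normalized_name for f in self.features}


@dataclass(frozen=True)
class SignedGeneOrder:
    """Ordered signed gene names for one genome (one IR copy retained)."""

    genome_id: str
    genes: tuple[SignedGene, ...]
    circular: bool = True

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def name_set(self) -> set[str]:
        return {g.name for g in self.genes}

    def reverse_complement(self) -> "SignedGeneOrder":
        return SignedGeneOrder(
            self.genome_id, tuple(-g for g in reversed(self.genes)), self.circular
        )

    def rotate(self, k: int) -> "SignedGeneOrder":
        if not self.circular:
            raise ValueError("cannot rotate a linear gene order")
        k %= len(self.genes)
        return SignedGeneOrder(
            self.genome_id, self.genes[k:] + self.genes[:k], self.circular
        )


# ---------------------------------------------------------------------------
# gene name normalization


#: default synonym table; user tables extend/override it
DEFAULT_SYNONYMS = {
    "rrn16": "rrs",
    "rrn16s": "rrs",
    "16s rrna": "rrs",
    "rrn23": "rrl",
    "rrn23s": "rrl",
    "23s rrna": "rrl",
    "rrn5": "rrf",
    "rrn5s": "rrf",
    "5s rrna": "rrf",
    "trnfm": "trnMf(cau)",
    "trnfm-cau": "trnMf(cau)",
    "trnm-cau": "trnMe(cau)",
    "infa": "infA",
}

_TRNA_RE = re.compile(
    r"^trn(?P<aa>[A-Za-z]{1,3}[ef]?)[\s\-_]*(?:\((?P<ac1>[A-Za-z]{3})\)|(?P<ac2>[A-Za-z]{3}))?$"
)


def normalize_gene_name(
    raw: str,
    anticodon: Optional[str] = None,
    synonyms: Optional[dict[str, str]] = None,
) -> str:
    """Normalize a gene symbol to the plastid convention.

    tRNA genes become ``trnX(nnn)`` with a lowercase anticodon; other
    symbols get their leading (lowercase-by-convention) prefix folded, e.g.
    ``PsbA -> psbA``.  Synonyms are applied first (case-insensitively), so
    e.g. ``rrn23 -> rrl``.  A tRNA whose anticodon cannot be resolved is
    flagged with a warning and kept verbatim.
    """
    table = dict(DEFAULT_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    name = raw.strip()
    if name.lower() in table:
        return table[name.lower()]
    m = _TRNA_RE.match(name) if name.lower().startswith("trn") else None
    if m:
        aa = m.group("aa")
        aa = aa[0].upper() + aa[1:] if len(aa) > 1 else aa.upper()
        ac = anticodon or m.group("ac1") or m.group("ac2")
        if ac is None:
            logger.warning("tRNA %r has no resolvable anticodon; kept verbatim", raw)
            return name
        return f"trn{aa}({ac.lower()})"
    if _ORF_RE.match(name):
        return name.lower()
    # fold the leading lowercase-by-convention prefix: PsbA -> psbA, RBCL -> rbcL
    if len(name) >= 3 and name[:3].isalpha() and not name[:3].islower():
        if name.isupper() and len(name) > 3:
            return name[:-1].lower() + name[-1]
        return name[:3].lower() + name[3:]
    return name


# ---------------------------------------------------------------------------
# GenBank input


def _feature_name(feat) -> Optional[str]:
    for key in ("gene", "locus_tag", "product", "label", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _feature_anticodon(feat) -> Optional[str]:
    q = feat.qualifiers
    if "anticodon" in q:
        m = re.search(r"seq\s*:\s*([acgut]{3})", q["anticodon"][0], re.IGNORECASE)
        if m:
            return m.group(1)
    for key in ("product", "note"):
        if key in q:
            m = re.search(r"\(([ACGUTacgut]{3})\)", q[key][0])
            if m:
                return m.group(1)
    return None


def _location_coords(feat, length: int) -> tuple[int, int, bool]:
    """Return (start, end, wraps_origin) in 1-based inclusive coordinates."""
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        parts = list(loc.parts)
        # a join whose successive parts jump backwards crosses the origin
        for a, b in zip(parts, parts[1:]):
            if int(b.start) < int(a.start):
                return int(parts[0].start) + 1, int(parts[-1].end), True
    return int(loc.start) + 1, int(loc.end), False


def read_genbank(
    path: str | Path,
    synonyms: Optional[dict[str, str]] = None,
) -> AnnotatedGenome:
    """Read one GenBank flat file into an :class:`AnnotatedGenome`.

    Every gene-bearing feature (CDS, tRNA, rRNA, other RNAs, plus plain
    ``gene`` features not covered by one of those) is captured once, with
    its category inferred from the feature key.  ``repeat_region`` features
    are collected separately for annotation-based IR detection.  A linear
    record is accepted with ``circular=False`` and a warning.
    """
    path = Path(path)
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise GenBankParseError(f"{path}: no GenBank record found")
    except ValueError as exc:
        raise GenBankParseError(f"{path}: malformed GenBank record: {exc}") from exc

    topology = (record.annotations.get("topology") or "").lower()
    circular = topology == "circular"
    if not circular:
        logger.warning("%s: record is not marked circular; treating as linear", path)
    try:
        sequence = str(record.seq) if len(record.seq) else None
    except Exception:  # undefined sequence (feature-table-only record)
        sequence = None
    length = len(record) if len(record) else None

    features: list[GeneFeature] = []
    repeat_regions: list[tuple[int, int]] = []
    covered: set[tuple[str, int]] = set()  # (normalized name, start)

    def add(feat, category: str) -> None:
        raw = _feature_name(feat)
        if raw is None:
            return
        norm = normalize_gene_name(raw, _feature_anticodon(feat), synonyms)
        if category != "orf" and _ORF_RE.match(norm):
            category = "orf"
        start, end, wraps = _location_coords(feat, length or 0)
        key = (norm, start)
        if key in covered:
            return
        covered.add(key)
        features.append(
            GeneFeature(
                raw_name=raw,
                normalized_name=norm,
                category=category,
                strand="-" if feat.location.strand == -1 else "+",
                start=start,
                end=end,
                wraps_origin=wraps,
            )
        )

    for feat in record.features:
        if feat.type in _CATEGORY_BY_KEY:
            add(feat, _CATEGORY_BY_KEY[feat.type])
        elif feat.type == "repeat_region":
            s, e, _ = _location_coords(feat, length or 0)
            repeat_regions.append((s, e))
    # plain gene features not already captured at the same locus
    captured_names = {(f.normalized_name,) for f in features}
    captured_starts = {(f.normalized_name, f.start) for f in features}
    for feat in record.features:
        if feat.type != "gene":
            continue
        raw = _feature_name(feat)
        if raw is None:
            continue
        norm = normalize_gene_name(raw, _feature_anticodon(feat), synonyms)
        start, end, _ = _location_coords(feat, length or 0)
        near = any(
            f.normalized_name == norm and abs(f.start - start) <= (end - start + 1)
            for f in features
        )
        if not near and (norm, start) not in captured_starts:
            add(feat, "orf" if _ORF_RE.match(norm) else "protein")

    if length is None:
        length = max((f.end for f in features), default=0)
    return AnnotatedGenome(
        id=record.id or path.stem,
        length=length,
        circular=circular,
        features=features,
        sequence=sequence,
        repeat_regions=repeat_regions,
    )


# ---------------------------------------------------------------------------
# signed gene order extraction


def extract_signed_gene_order(
    genome: AnnotatedGenome,
    quad=None,
    include: Optional[set[str]] = None,
    drop_orfs: bool = True,
) -> SignedGeneOrder:
    """Extract the signed gene order of a genome, keeping one IR copy.

    Genes are ordered by start coordinate around the circle; the sign is the
    coding strand.  When a quadripartite map is given, every gene whose
    majority length lies inside IR-B is removed so each IR gene appears
    once (the retained copy, IR-A, is the one starting at the smaller
    coordinate).  Freestanding ORFs and, optionally, whole categories can
    be excluded.  Residual duplicate unsigned names raise
    :class:`DuplicateGeneError`.
    """
    feats = list(genome.features)
    if drop_orfs:
        feats = [
            f for f in feats
            if f.category != "orf" and not _ORF_RE.match(f.normalized_name)
        ]
    if include is not None:
        feats = [f for f in feats if f.category in include]
    if quad is not None and quad.ir_length > 0:
        from .quadripartite import interval_overlap  # local import, no cycle at runtime

        def in_ir_b(f: GeneFeature) -> bool:
            glen = f.length(genome.length)
            ov = interval_overlap(
                (f.start, f.end), quad.ir_b, genome.length, genome.circular
            )
            return ov * 2 > glen

        feats = [f for f in feats if not in_ir_b(f)]
    feats.sort(key=lambda f: (f.start, f.end))
    genes = tuple(
        SignedGene(f.normalized_name, +1 if f.strand == "+" else -1) for f in feats
    )
    names = [g.name for g in genes]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DuplicateGeneError(sorted(dupes))
    return SignedGeneOrder(genome.id, genes, genome.circular)


def reduce_to_shared(
    a: SignedGeneOrder, b: SignedGeneOrder
) -> tuple[SignedGeneOrder, SignedGeneOrder, list[str], list[str]]:
    """Restrict two gene orders to their shared unsigned gene set.

    Relative order and signs are preserved.  Returns the two reduced orders
    plus the genes unique to each input.  An empty intersection is an
    error.
    """
    shared = a.name_set() & b.name_set()
    if not shared:
        raise ValueError(
            f"no genes shared between {a.genome_id!r} and {b.genome_id!r}"
        )
    unique_a = sorted(a.name_set() - shared)
    unique_b = sorted(b.name_set() - shared)
    ra = SignedGeneOrder(
        a.genome_id, tuple(g for g in a.genes if g.name in shared), a.circular
    )
    rb = SignedGeneOrder(
        b.genome_id, tuple(g for g in b.genes if g.name in shared), b.circular
    )
    return ra, rb, unique_a, unique_b


# ---------------------------------------------------------------------------
# plain-text output


def write_order_tsv(
    order: SignedGeneOrder,
    path: str | Path,
    genome: Optional[AnnotatedGenome] = None,
    regions: Optional[dict[str, str]] = None,
) -> None:
    """Write a gene order as one-line-per-gene TSV (name, sign, start, end, region)."""
    coords = {}
    if genome is not None:
        coords = {f.normalized_name: (f.start, f.end) for f in genome.features}
    with open(path, "w") as fh:
        fh.write("gene\tsign\tstart\tend\tregion\n")
        for g in order.genes:
            s, e = coords.get(g.name, ("", ""))
            region = (regions or {}).get(g.name, "")
            fh.write(f"{g.name}\t{'+' if g.sign > 0 else '-'}\t{s}\t{e}\t{region}\n")


def read_order_tsv(path: str | Path, genome_id: str = "", circular: bool = True) -> SignedGeneOrder:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene\t"):
            raise ValueError(f"{path}: not a gene-order TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0]:
                genes.append(SignedGene(parts[0], +1 if parts[1] != "-" else -1))
    return SignedGeneOrder(genome_id or str(path), tuple(genes), circular)


def to_grimm_line(order: SignedGeneOrder) -> str:
    """Single-line signed list, ``>id`` header plus signed names, ``$`` terminator."""
    terminator = "@" if order.circular else "$"
    return f">{order.genome_id}\n" + " ".join(str(g) for g in order.genes) + f" {terminator}\n"


def from_grimm_line(text: str) -> SignedGeneOrder:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("expected a '>' header line")
    genome_id = lines[0][1:].strip()
    tokens = " ".join(lines[1:]).split()
    circular = tokens and tokens[-1] == "@"
    genes = tuple(parse_signed(t) for t in tokens if t not in ("$", "@"))
    return SignedGeneOrder(genome_id, genes, circular)
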