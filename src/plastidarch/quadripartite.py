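"""Quadripartite structure: inverted-repeat detection and gene partitioning.

The canonical plastid architecture is IR-A + LSC + IR-B + SSC: two identical
reverse-complementary repeat copies separated by a large and a small
single-copy region.  This module finds the IR from sequence (maximal exact
or near-exact inverted repeat, seed-and-extend) or from ``repeat_region``
annotation, partitions the circle into the four regions, labels every gene
by region, and classifies each gene's ancestral origin (LSC-side vs
SSC-side of the rDNA operon) against a reference genome with an ancestral
layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_model import AnnotatedGenome, GeneFeature

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

#: the five rDNA operon genes used as the ancestral positional anchor
RDNA_OPERON = ("rrs", "trnI(gau)", "trnA(ugc)", "rrl", "rrf")


class OverlappingRepeatError(ValueError):
    """The best inverted-repeat candidate overlaps its own second copy."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# circular interval arithmetic (1-based inclusive; start > end means a wrap)


def _segments(interval: tuple[int, int], n: int) -> list[tuple[int, int]]:
    """Split a possibly origin-wrapping interval into 0-based half-open runs."""
    s, e = interval
    if s <= e:
        return [(s - 1, e)]
    return [(s - 1, n), (0, e)]


def interval_length(interval: Optional[tuple[int, int]], n: int) -> int:
    if interval is None:
        return 0
    return sum(b - a for a, b in _segments(interval, n))


def interval_overlap(
    x: Optional[tuple[int, int]],
    y: Optional[tuple[int, int]],
    n: int,
    circular: bool = True,
) -> int:
    """Overlap in bp between two circular 1-based inclusive intervals."""
    if x is None or y is None:
        return 0
    total = 0
    for a1, b1 in _segments(x, n):
        for a2, b2 in _segments(y, n):
            total += max(0, min(b1, b2) - max(a1, a2))
    return total


@dataclass(frozen=True)
class QuadripartiteMap:
    """Coordinates of IR-A, IR-B, LSC and SSC on one circular genome.

    All coordinates are 1-based inclusive; an interval with start > end
    wraps the origin.  ``ir_length`` is the length of one IR copy; an
    IR-less genome has ``ir_length == 0`` and the whole circle as LSC.
    """

    genome_length: int
    ir_a: Optional[tuple[int, int]]
    ir_b: Optional[tuple[int, int]]
    lsc: Optional[tuple[int, int]]
    ssc: Optional[tuple[int, int]]

    @property
    def ir_length(self) -> int:
        return interval_length(self.ir_a, self.genome_length)

    @property
    def lsc_length(self) -> int:
        return interval_length(self.lsc, self.genome_length)

    @property
    def ssc_length(self) -> int:
        return interval_length(self.ssc, self.genome_length)

    def __post_init__(self) -> None:
        n = self.genome_length
        la, lb = interval_length(self.ir_a, n), interval_length(self.ir_b, n)
        if la != lb:
            raise ValueError(f"IR copies have unequal lengths ({la} vs {lb})")
        total = la + lb + self.lsc_length + self.ssc_length
        if total != n:
            raise ValueError(f"regions sum to {total}, expected genome length {n}")
        if self.lsc_length < self.ssc_length:
            raise ValueError("LSC must be at least as long as SSC")

    def regions(self) -> dict[str, Optional[tuple[int, int]]]:
        return {"IR-A": self.ir_a, "IR-B": self.ir_b, "LSC": self.lsc, "SSC": self.ssc}

    def to_json(self) -> str:
        payload = {
            "genome_length": self.genome_length,
            "ir_a": self.ir_a,
            "ir_b": self.ir_b,
            "lsc": self.lsc,
            "ssc": self.ssc,
            "ir_length": self.ir_length,
            "lsc_length": self.lsc_length,
            "ssc_length": self.ssc_length,
        }
        return json.dumps(payload, indent=2)

    def to_bed(self, genome_id: str) -> str:
        """Four-region BED track (wrapping intervals split into two lines)."""
        lines = []
        for name, iv in self.regions().items():
            if iv is None:
                continue
            for a, b in _segments(iv, self.genome_length):
                lines.append(f"{genome_id}\t{a}\t{b}\t{name}")
        return "\n".join(lines) + "\n"


def no_ir_map(genome_length: int) -> QuadripartiteMap:
    return QuadripartiteMap(genome_length, None, None, (1, genome_length), None)


def _build_map(n: int, arc_a: tuple[int, int], arc_b: tuple[int, int]) -> QuadripartiteMap:
    """Build the map from two 0-based half-open IR arcs on the circle."""
    (a0, la), (b0, lb) = arc_a, arc_b
    assert la == lb
    if b0 < a0:
        a0, b0 = b0, a0
    a_end, b_end = (a0 + la) % n, (b0 + lb) % n

    def arc(start0: int, length: int) -> Optional[tuple[int, int]]:
        if length <= 0:
            return None
        return (start0 % n + 1, (start0 + length - 1) % n + 1)

    gap1 = (b0 - a_end) % n  # from end of first copy to start of second
    gap2 = (a0 - b_end) % n
    sc1, sc2 = arc(a_end, gap1), arc(b_end, gap2)
    if gap1 >= gap2:
        lsc, ssc = sc1, sc2
    else:
        lsc, ssc = sc2, sc1
    ir_a, ir_b = arc(a0, la), arc(b0, lb)
    return QuadripartiteMap(n, ir_a, ir_b, lsc, ssc)


# ---------------------------------------------------------------------------
# sequence-based IR detection


def detect_inverted_repeat(
    genome: AnnotatedGenome,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.0,
) -> QuadripartiteMap:
    """Find the longest pair of disjoint reverse-complementary segments.

    Seed-and-extend over the (doubled, for circularity) sequence: exact
    k-mer seeds against the reverse complement are grouped by anti-diagonal
    (i + j is constant along one inverted-repeat pair) and extended
    maximally, tolerating a mismatch fraction up to ``max_mismatch_frac``
    (default 0: exact, the typical plastid condition).  Returns a map with
    ``ir_length == 0`` when nothing reaches ``min_len``; raises
    :class:`OverlappingRepeatError` when only self-overlapping candidates
    exist.
    """
    if genome.sequence is None:
        raise ValueError(
            "genome has no sequence; use detect_ir_from_annotation instead"
        )
    seq = genome.sequence.upper()
    n = len(seq)
    d = seq + seq if genome.circular else seq
    k = max(4, min(min_len, 21))
    if n < 2 * min_len:
        return no_ir_map(n)

    index: dict[str, list[int]] = {}
    for j in range(len(d) - k + 1):
        index.setdefault(d[j : j + k], []).append(j)

    # one extension per maximal run: seeds of one inverted pair share the
    # anti-diagonal i + j, but a wrapped repeat can put two distinct runs on
    # the same anti-diagonal, so consumed i-ranges are tracked per diagonal
    seen_diag: dict[int, list[tuple[int, int]]] = {}
    candidates: dict[frozenset, tuple[int, int, int]] = {}
    for i in range(len(d) - k + 1):
        rc_kmer = revcomp(d[i : i + k])
        for j in index.get(rc_kmer, ()):
            if j <= i:
                continue
            diag = i + j
            ranges = seen_diag.setdefault(diag, [])
            if any(lo <= i < hi for lo, hi in ranges):
                continue
            a, b, length = _extend(d, i, j, k, max_mismatch_frac)
            ranges.append((a, a + length))
            if length < min_len:
                continue
            key = frozenset({a % n, b % n})
            prev = candidates.get(key)
            if prev is None or length > prev[2]:
                candidates[key] = (a, b, length)

    best = None
    overlapping_seen = False
    for a, b, length in sorted(candidates.values(), key=lambda t: -t[2]):
        if _disjoint_on_circle(a % n, b % n, length, n):
            best = (a % n, b % n, length)
            break
        overlapping_seen = True
    if best is None:
        if overlapping_seen:
            raise OverlappingRepeatError(
                f"inverted-repeat candidates >= {min_len} bp overlap their own copy"
            )
        return no_ir_map(n)
    a, b, length = best
    return _build_map(n, (a, length), (b, length))


def _extend(d: str, i: int, j: int, k: int, frac: float) -> tuple[int, int, int]:
    """Maximally extend an inverted seed (i, j, k) within the doubled string.

    Segment A grows leftwards as B grows rightwards and vice versa;
    extension is greedy with the cumulative mismatch fraction capped.
    """
    lo_a, hi_a = i, i + k  # A = d[lo_a:hi_a]
    lo_b, hi_b = j, j + k  # B = d[lo_b:hi_b], B == revcomp(A) up to mismatches
    mismatches = 0

    def budget_ok(extra: int, new_len: int) -> bool:
        return (mismatches + extra) <= frac * new_len

    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    # grow A left / B right
    while lo_a > 0 and hi_b < len(d):
        match = comp.get(d[lo_a - 1]) == d[hi_b]
        if not match and not budget_ok(1, hi_a - lo_a + 1):
            break
        mismatches += 0 if match else 1
        lo_a -= 1
        hi_b += 1
    # grow A right / B left (stop before the copies meet)
    while hi_a < lo_b:
        match = comp.get(d[hi_a]) == d[lo_b - 1]
        if not match and not budget_ok(1, hi_a - lo_a + 1):
            break
        mismatches += 0 if match else 1
        hi_a += 1
        lo_b -= 1
    return lo_a, lo_b, hi_a - lo_a


def _disjoint_on_circle(a: int, b: int, length: int, n: int) -> bool:
    if 2 * length > n:
        return False
    x = interval_overlap(
        ((a % n) + 1, (a + length - 1) % n + 1),
        ((b % n) + 1, (b + length - 1) % n + 1),
        n,
    )
    return x == 0


def detect_ir_from_annotation(genome: AnnotatedGenome) -> QuadripartiteMap:
    """Build the quadripartite map from two annotated ``repeat_region`` features."""
    rr = genome.repeat_regions
    if len(rr) != 2:
        raise ValueError(
            f"expected exactly 2 repeat_region features, found {len(rr)}; "
            "use sequence-based detection (detect_inverted_repeat)"
        )
    n = genome.length
    lens = [interval_length(iv, n) for iv in rr]
    if lens[0] != lens[1]:
        raise ValueError(
            f"repeat_region features have unequal lengths ({lens[0]} vs {lens[1]})"
        )
    arcs = [( _segments(iv, n)[0][0] if iv[0] <= iv[1] else iv[0] - 1, L)
            for iv, L in zip(rr, lens)]
    return _build_map(n, arcs[0], arcs[1])


# ---------------------------------------------------------------------------
# gene partitioning


@dataclass
class PartitionRow:
    gene: str
    category: str
    strand: str
    start: int
    end: int
    region: str  # IR | LSC | SSC | junction
    copy: str = ""  # IR-A / IR-B for IR genes
    ancestral_origin: str = "unknown"


@dataclass
class PartitionReport:
    """Per-gene region labels (and ancestral origins) for one genome."""

    genome_id: str
    rows: list[PartitionRow] = field(default_factory=list)

    def region_of(self) -> dict[str, str]:
        return {r.gene: r.region for r in self.rows}

    def origin_of(self) -> dict[str, str]:
        return {r.gene: r.ancestral_origin for r in self.rows}

    def genes_in_region(self, region: str, category: Optional[str] = None,
                        dedupe: bool = True) -> list[str]:
        names = []
        for r in self.rows:
            if r.region == region and (category is None or r.category == category):
                if not dedupe or r.gene not in names:
                    names.append(r.gene)
        return names

    def to_tsv(self) -> str:
        lines = ["gene\tcategory\tstrand\tstart\tend\tregion\tcopy\tancestral_origin"]
        for r in self.rows:
            lines.append(
                f"{r.gene}\t{r.category}\t{r.strand}\t{r.start}\t{r.end}"
                f"\t{r.region}\t{r.copy}\t{r.ancestral_origin}"
            )
        return "\n".join(lines) + "\n"


def assign_regions(
    genome: AnnotatedGenome,
    quad: QuadripartiteMap,
    junction_policy: str = "majority",
) -> PartitionReport:
    """Label every gene with the region containing it.

    ``junction_policy='majority'`` assigns a boundary-straddling gene to the
    region holding the majority of its length; ``'junction'`` labels such
    genes ``junction`` instead.
    """
    if junction_policy not in ("majority", "junction"):
        raise ValueError(f"unknown junction_policy {junction_policy!r}")
    n = genome.length
    report = PartitionReport(genome.id)
    for f in genome.features:
        iv = (f.start, f.end)
        overlaps = {
            name: interval_overlap(iv, arc, n) for name, arc in quad.regions().items()
        }
        merged = {
            "IR": overlaps["IR-A"] + overlaps["IR-B"],
            "LSC": overlaps["LSC"],
            "SSC": overlaps["SSC"],
        }
        touched = [k for k, v in overlaps.items() if v > 0]
        if junction_policy == "junction" and len(touched) > 1:
            region = "junction"
        else:
            region = max(merged, key=lambda k: (merged[k], k))
        copy = ""
        if region == "IR":
            copy = "IR-A" if overlaps["IR-A"] >= overlaps["IR-B"] else "IR-B"
        report.rows.append(
            PartitionRow(
                gene=f.normalized_name,
                category=f.category,
                strand=f.strand,
                start=f.start,
                end=f.end,
                region=region,
                copy=copy,
            )
        )
    return report


def _midpoint(f: GeneFeature, n: int) -> float:
    if not f.wraps_origin:
        return (f.start + f.end) / 2 % n
    return ((f.start + f.end + n) / 2) % n


def _circular_distance_to_arc(pos: float, arc: Optional[tuple[int, int]], n: int) -> float:
    if arc is None:
        return float("inf")
    best = float("inf")
    for a, b in _segments(arc, n):
        if a <= pos < b:
            return 0.0
        for edge in (a, b - 1):
            d = abs(pos - edge)
            best = min(best, d, n - d)
    return best


def classify_ancestral_origin(
    query: PartitionReport,
    reference: AnnotatedGenome,
    reference_quad: QuadripartiteMap,
    operon: Sequence[str] = RDNA_OPERON,
) -> PartitionReport:
    """Label query genes by their position in an ancestral reference layout.

    Genes of the rDNA operon are labeled ``rDNA-operon``; other genes are
    ``SSC-origin`` if they sit in (or, inside the reference IR, nearer to)
    the reference SSC — i.e. downstream of the rDNA operon — and
    ``LSC-origin`` if on the LSC side.  Genes absent from the reference are
    ``unknown``.  The reference must carry the rDNA operon.
    """
    ref_names = reference.gene_names()
    if not ({"rrs", "rrl"} <= ref_names):
        raise ValueError("reference genome lacks the rDNA operon (rrs/rrl not found)")
    ref_part = assign_regions(reference, reference_quad)
    ref_region = ref_part.region_of()
    ref_feat = {f.normalized_name: f for f in reference.features}
    n = reference.length
    operon_set = set(operon)

    def origin(name: str) -> str:
        if name in operon_set:
            return "rDNA-operon"
        if name not in ref_region:
            return "unknown"
        region = ref_region[name]
        if region == "LSC":
            return "LSC-origin"
        if region == "SSC":
            return "SSC-origin"
        # IR-resident non-operon reference gene: side relative to the operon,
        # operationalized as the nearer single-copy region along the circle
        mid = _midpoint(ref_feat[name], n)
        d_ssc = _circular_distance_to_arc(mid, reference_quad.ssc, n)
        d_lsc = _circular_distance_to_arc(mid, reference_quad.lsc, n)
        return "SSC-origin" if d_ssc <= d_lsc else "LSC-origin"

    out = PartitionReport(query.genome_id)
    for r in query.rows:
        out.rows.append(
            PartitionRow(
                gene=r.gene,
                category=r.category,
                strand=r.strand,
                start=r.start,
                end=r.end,
                region=r.region,
                copy=r.copy,
                ancestral_origin=origin(r.gene),
            )
        )
    return out


def lsc_origin_ir_genes(report: PartitionReport) -> list[str]:
    """IR-resident genes of LSC origin — the atypical IR acquisitions."""
    out = []
    for r in report.rows:
        if r.region == "IR" and r.ancestral_origin == "LSC-origin" and r.gene not in out:
            out.append(r.gene)
    return sorted(out)
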