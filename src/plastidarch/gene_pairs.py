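"""Signed gene adjacencies and the multi-taxon character matrix.

An adjacency joins the abutting ends of two neighboring genes; because a
genome and its reverse complement describe the same molecule, the pair
``(+a, +b)`` is the same character as ``(-b, -a)``.  Each canonical pair is
named by the gene ends that meet at the junction, e.g. ``3'psaM-5'trnQ(uug)``.
Pairs observed across a set of genomes are coded as three-state characters
(present / absent / inapplicable-because-a-gene-was-lost), filtered to those
present in a minimum number of taxa, and written to NEXUS for parsimony
programs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome_model import SignedGene, SignedGeneOrder

PRESENT, ABSENT, INAPPLICABLE = "present", "absent", "inapplicable"
_STATE_SYMBOL = {PRESENT: "1", ABSENT: "0", INAPPLICABLE: "?"}
_SYMBOL_STATE = {v: k for k, v in _STATE_SYMBOL.items()}


@dataclass(frozen=True, order=True)
class SignedGenePair:
    """A canonical signed adjacency between two genes."""

    left: SignedGene
    right: SignedGene

    @property
    def label(self) -> str:
        """Junction label: which end of each gene abuts the other.

        A forward gene presents its 3' end to the junction on its right and
        its 5' end on its left; a reverse gene presents the opposite ends.
        """
        out_end = "3'" if self.left.sign > 0 else "5'"
        in_end = "5'" if self.right.sign > 0 else "3'"
        return f"{out_end}{self.left.name}-{in_end}{self.right.name}"

    def genes(self) -> tuple[str, str]:
        return (self.left.name, self.right.name)

    def __str__(self) -> str:
        return self.label


def canonicalize(left: SignedGene, right: SignedGene) -> SignedGenePair:
    """Canonical form of an adjacency: the smaller of (l, r) and (-r, -l)."""
    a = (left.name, left.sign, right.name, right.sign)
    b = (right.name, -right.sign, left.name, -left.sign)
    if b < a:
        left, right = -right, -left
    return SignedGenePair(left, right)


def adjacency_pairs(order: SignedGeneOrder) -> set[SignedGenePair]:
    """Canonical pairs of all adjacent genes (with the wrap-around pair
    when the order is circular): n pairs for a circular order of n genes,
    n - 1 for a linear one."""
    genes = order.genes
    if not genes:
        raise ValueError(f"empty gene order for {order.genome_id!r}")
    pairs = {
        canonicalize(genes[i], genes[i + 1]) for i in range(len(genes) - 1)
    }
    if order.circular and len(genes) > 1:
        pairs.add(canonicalize(genes[-1], genes[0]))
    return pairs


def breakpoint_count(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (over shared genes)."""
    return len(adjacency_pairs(a) - adjacency_pairs(b))


@dataclass
class PairMatrix:
    """Taxa x canonical-pair character matrix with three states."""

    states: pd.DataFrame  # index: taxa; columns: pair labels; values: state strings
    characters: list[SignedGenePair]
    repertoires: dict[str, set[str]]

    @property
    def taxa(self) -> list[str]:
        return list(self.states.index)

    def character_by_label(self, label: str) -> SignedGenePair:
        for c in self.characters:
            if c.label == label:
                return c
        raise KeyError(label)

    def to_long_tsv(self) -> str:
        lines = ["taxon\tpair_label\tstate"]
        for taxon in self.states.index:
            for label in self.states.columns:
                lines.append(f"{taxon}\t{label}\t{self.states.at[taxon, label]}")
        return "\n".join(lines) + "\n"

    def repertoire_table(self) -> pd.DataFrame:
        """Gene presence/absence per taxon (the gene-repertoire side table)."""
        genes = sorted(set().union(*self.repertoires.values()))
        data = {
            g: [g in self.repertoires[t] for t in self.states.index] for g in genes
        }
        return pd.DataFrame(data, index=self.states.index)


def build_pair_matrix(
    orders: Sequence[SignedGeneOrder],
    repertoires: Optional[dict[str, set[str]]] = None,
    min_taxa: int = 3,
) -> PairMatrix:
    """Code signed gene pairs present in >= ``min_taxa`` genomes as characters.

    A pair is ``inapplicable`` in a taxon when at least one of its genes is
    missing from that taxon's gene repertoire (the repertoire defaults to
    the genes of the taxon's order), ``present`` when the adjacency occurs,
    and ``absent`` otherwise.
    """
    if len(orders) < 3:
        raise ValueError("need at least 3 taxa to code pair characters")
    for o in orders:
        if len(o) == 0:
            raise ValueError(f"empty gene order for taxon {o.genome_id!r}")
    ids = [o.genome_id for o in orders]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids among orders")
    if repertoires is None:
        repertoires = {o.genome_id: o.name_set() for o in orders}
    pair_sets = {o.genome_id: adjacency_pairs(o) for o in orders}
    counts: dict[SignedGenePair, int] = {}
    for ps in pair_sets.values():
        for p in ps:
            counts[p] = counts.get(p, 0) + 1
    characters = sorted(
        (p for p, c in counts.items() if c >= min_taxa), key=lambda p: p.label
    )
    rows = {}
    for o in orders:
        rep = repertoires[o.genome_id]
        ps = pair_sets[o.genome_id]
        row = []
        for ch in characters:
            if ch in ps:
                row.append(PRESENT)
            elif all(g in rep for g in ch.genes()):
                row.append(ABSENT)
            else:
                row.append(INAPPLICABLE)
        rows[o.genome_id] = row
    states = pd.DataFrame.from_dict(
        rows, orient="index", columns=[c.label for c in characters]
    )
    return PairMatrix(states=states, characters=characters, repertoires=repertoires)


# ---------------------------------------------------------------------------
# NEXUS interchange


def write_nexus(matrix: PairMatrix, path: str | Path) -> None:
    """Write a standard NEXUS CHARACTERS block (0/1, inapplicable as '?')."""
    taxa = matrix.taxa
    labels = list(matrix.states.columns)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(taxa)};\n")
        fh.write("    TAXLABELS " + " ".join(f"'{t}'" for t in taxa) + ";\n")
        fh.write("END;\n\n")
        fh.write("BEGIN CHARACTERS;\n")
        fh.write(f"    DIMENSIONS NCHAR={len(labels)};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        if labels:
            fh.write("    CHARSTATELABELS\n")
            fh.write(
                ",\n".join(
                    f"        {i + 1} '{lab}'" for i, lab in enumerate(labels)
                )
            )
            fh.write(";\n")
        fh.write("    MATRIX\n")
        for t in taxa:
            symbols = "".join(
                _STATE_SYMBOL[matrix.states.at[t, lab]] for lab in labels
            )
            fh.write(f"        '{t}' {symbols}\n")
        fh.write("    ;\nEND;\n")


def read_nexus_states(path: str | Path) -> pd.DataFrame:
    """Read back a matrix written by :func:`write_nexus` (round-trip reader)."""
    labels: list[str] = []
    taxa: list[str] = []
    rows: list[list[str]] = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.upper().startswith("CHARSTATELABELS"):
                section = "labels"
                line = line[len("CHARSTATELABELS"):].strip()
            if section == "labels" and line:
                for part in line.split(","):
                    part = part.strip().rstrip(";")
                    if not part:
                        continue
                    q1 = part.find("'")
                    if q1 >= 0:
                        labels.append(part[q1 + 1 : part.rfind("'")])
                if ";" in raw:
                    section = None
                continue
            if line.upper() == "MATRIX":
                section = "matrix"
                continue
            if section == "matrix":
                if line.startswith(";"):
                    section = None
                    continue
                if not line:
                    continue
                if line.startswith("'"):
                    q2 = line.find("'", 1)
                    name, symbols = line[1:q2], line[q2 + 1 :].strip()
                else:
                    name, _, symbols = line.partition(" ")
                taxa.append(name)
                rows.append([_SYMBOL_STATE[s] for s in symbols.strip()])
    ncols = len(labels) if labels else (len(rows[0]) if rows else 0)
    return pd.DataFrame(rows, index=taxa, columns=labels or range(ncols))
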