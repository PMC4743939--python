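import random
import textwrap

import numpy as np
import pytest

from plastidarch.evolver import EvolutionConfig, make_architecture, materialize
from plastidarch.genome_model import AnnotatedGenome, GeneFeature, SignedGene, SignedGeneOrder


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


@pytest.fixture
def tiny_genbank(tmp_path):
    """A hand-written circular 1 kb record: three plain genes plus one
    origin-wrapping CDS."""
    rng = random.Random(5)
    seq = "".join(rng.choice("acgt") for _ in range(1000))
    text = textwrap.dedent(
        """\
        LOCUS       synthfix                1000 bp    DNA     circular PLN 01-JAN-2020
        DEFINITION  synthetic three-gene fixture.
        ACCESSION   synthfix
        VERSION     synthfix.1
        KEYWORDS    .
        SOURCE      synthetic construct
          ORGANISM  synthetic construct
        FEATURES             Location/Qualifiers
             source          1..1000
                             /organism="synthetic construct"
             CDS             1..300
                             /gene="psbA"
             tRNA            complement(400..600)
                             /gene="trnQ-UUG"
             CDS             700..900
                             /gene="rbcL"
             CDS             join(950..1000,1..20)
                             /gene="ycf1"
        ORIGIN
        """
    ) + _origin_block(seq) + "\n//\n"
    path = tmp_path / "fixture.gb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def default_config():
    return EvolutionConfig(seed=11)


@pytest.fixture(scope="session")
def ancestor_arch(default_config):
    return make_architecture(default_config)


@pytest.fixture(scope="session")
def ancestor_genome(ancestor_arch, default_config):
    genome, quad = materialize(ancestor_arch, "ancestor", default_config)
    return genome, quad


def simple_genome(genes, length=1000, circular=True, genome_id="g"):
    """Build a minimal AnnotatedGenome from (name, strand, start, end) tuples."""
    feats = [
        GeneFeature(
            raw_name=n, normalized_name=n, category="protein", strand=s,
            start=a, end=b, wraps_origin=a > b,
        )
        for (n, s, a, b) in genes
    ]
    return AnnotatedGenome(
        id=genome_id, length=length, circular=circular, features=feats
    )


def order_of(tokens, genome_id="g", circular=True):
    """Gene order from '+a -b +c' style strings."""
    genes = tuple(
        SignedGene(t[1:], -1 if t[0] == "-" else 1) for t in tokens.split()
    )
    return SignedGeneOrder(genome_id, genes, circular)


def random_signed_order(names, rng, genome_id="r", circular=True):
    names = list(names)
    rng.shuffle(names)
    genes = tuple(SignedGene(n, rng.choice((-1, 1))) for n in names)
    return SignedGeneOrder(genome_id, genes, circular)
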