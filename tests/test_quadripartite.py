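"""IR detection, quadripartite partitioning and ancestral-origin labels."""

import random

import pytest

from plastidarch.evolver import (
    Event,
    EvolutionConfig,
    apply_event,
    make_architecture,
    materialize,
)
from plastidarch.genome_model import AnnotatedGenome
from plastidarch.quadripartite import (
    QuadripartiteMap,
    assign_regions,
    classify_ancestral_origin,
    detect_inverted_repeat,
    detect_ir_from_annotation,
    interval_overlap,
    lsc_origin_ir_genes,
    no_ir_map,
    revcomp,
)

from conftest import simple_genome
from oracles import has_inverted_repeat_kmers


def _bare_genome(seq, genome_id="s", circular=True, repeat_regions=()):
    return AnnotatedGenome(
        id=genome_id, length=len(seq), circular=circular, features=[],
        sequence=seq, repeat_regions=list(repeat_regions),
    )


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestDetectInvertedRepeat:
    def test_planted_exact_repeat_recovered(self):
        rng = random.Random(3)
        left = _random_seq(rng, 3000)
        ir = _random_seq(rng, 2000)
        mid = _random_seq(rng, 2500)
        right = _random_seq(rng, 2500)
        seq = left + ir + mid + revcomp(ir) + right
        quad = detect_inverted_repeat(_bare_genome(seq), min_len=1000)
        assert quad.ir_length == 2000
        assert quad.ir_a == (3001, 5000)
        assert quad.ir_b == (7501, 9500)
        assert quad.lsc_length == 5500 and quad.ssc_length == 2500

    def test_random_sequence_has_no_ir(self):
        rng = random.Random(9)
        seq = _random_seq(rng, 10000)
        # independent oracle: no 1000-mer occurs reverse-complemented at all
        assert not has_inverted_repeat_kmers(seq, 1000)
        quad = detect_inverted_repeat(_bare_genome(seq), min_len=1000)
        assert quad.ir_length == 0 and quad.lsc_length == 10000

    def test_repeat_spanning_origin_found(self):
        rng = random.Random(4)
        ir = _random_seq(rng, 1500)
        a = _random_seq(rng, 2000)
        b = _random_seq(rng, 3000)
        # circle: [tail of IR-A][gap][IR-B][gap][head of IR-A]; the 'A'
        # bases at each junction block any chance 1-bp extension
        seq = ir[700:] + "A" + a + "A" + revcomp(ir) + "A" + b + "A" + ir[:700]
        quad = detect_inverted_repeat(_bare_genome(seq), min_len=1000)
        assert quad.ir_length == 1500
        irb_start0 = len(ir[700:]) + 1 + len(a) + 1
        assert quad.ir_b == (len(seq) - 700 + 1, 800)
        assert quad.ir_a == (irb_start0 + 1, irb_start0 + 1500)

    def test_requires_sequence(self):
        g = simple_genome([("a", "+", 1, 100)], length=5000)
        with pytest.raises(ValueError, match="no sequence"):
            detect_inverted_repeat(g)

    def test_planted_recovery_on_evolver_genomes(self):
        for seed in (1, 2, 3):
            config = EvolutionConfig(seed=seed, n_lsc_genes=20, n_ssc_genes=2,
                                     n_ir_genes=4)
            genome, truth = materialize(
                make_architecture(config), f"g{seed}", config
            )
            quad = detect_inverted_repeat(genome, min_len=1000)
            assert (quad.ir_a, quad.ir_b) == (truth.ir_a, truth.ir_b)

    def test_rotation_invariance(self):
        rng = random.Random(12)
        ir = _random_seq(rng, 1200)
        seq = _random_seq(rng, 2000) + ir + _random_seq(rng, 1500) + revcomp(ir)
        base = detect_inverted_repeat(_bare_genome(seq), min_len=1000)
        for shift in (137, 2500, 4100):
            rot = seq[shift:] + seq[:shift]
            quad = detect_inverted_repeat(_bare_genome(rot), min_len=1000)
            assert quad.ir_length == base.ir_length
            assert quad.lsc_length == base.lsc_length
            assert quad.ssc_length == base.ssc_length

    def test_reverse_complement_invariance(self):
        rng = random.Random(13)
        ir = _random_seq(rng, 1200)
        seq = _random_seq(rng, 2000) + ir + _random_seq(rng, 1500) + revcomp(ir)
        base = detect_inverted_repeat(_bare_genome(seq), min_len=1000)
        quad = detect_inverted_repeat(_bare_genome(revcomp(seq)), min_len=1000)
        assert (quad.ir_length, quad.lsc_length, quad.ssc_length) == (
            base.ir_length, base.lsc_length, base.ssc_length,
        )


class TestAnnotationBasedDetection:
    def test_two_equal_repeat_regions(self):
        g = simple_genome([("a", "+", 1, 50)], length=1000)
        g.repeat_regions = [(101, 200), (901, 1000)]
        quad = detect_ir_from_annotation(g)
        assert quad.ir_length == 100
        assert quad.lsc_length == 700 and quad.ssc_length == 100

    def test_wrong_count_errors(self):
        g = simple_genome([("a", "+", 1, 50)], length=1000)
        g.repeat_regions = [(101, 200)]
        with pytest.raises(ValueError, match="exactly 2"):
            detect_ir_from_annotation(g)

    def test_unequal_lengths_error(self):
        g = simple_genome([("a", "+", 1, 50)], length=1000)
        g.repeat_regions = [(101, 200), (901, 950)]
        with pytest.raises(ValueError, match="unequal"):
            detect_ir_from_annotation(g)


class TestAssignRegions:
    QUAD = QuadripartiteMap(1000, (101, 300), (601, 800), (801, 100), (301, 600))

    def test_containment(self):
        g = simple_genome([("x", "+", 150, 250)])
        part = assign_regions(g, self.QUAD)
        assert part.region_of()["x"] == "IR"
        assert part.rows[0].copy == "IR-A"

    def test_majority_rule(self):
        # 60 bp in LSC (41..100), 40 bp in IR-A (101..140)
        g = simple_genome([("y", "+", 41, 140)])
        part = assign_regions(g, self.QUAD)
        assert part.region_of()["y"] == "LSC"

    def test_junction_policy(self):
        g = simple_genome([("y", "+", 41, 140)])
        part = assign_regions(g, self.QUAD, junction_policy="junction")
        assert part.region_of()["y"] == "junction"

    def test_every_gene_labeled_once(self, ancestor_genome):
        genome, quad = ancestor_genome
        part = assign_regions(genome, quad)
        assert len(part.rows) == len(genome.features)

    def test_region_lengths_sum_to_genome(self, ancestor_genome):
        _, quad = ancestor_genome
        assert (
            quad.lsc_length + quad.ssc_length + 2 * quad.ir_length
            == quad.genome_length
        )

    def test_no_ir_map_is_all_lsc(self):
        quad = no_ir_map(5000)
        assert quad.ir_length == 0 and quad.lsc_length == 5000


@pytest.fixture(scope="module")
def reference():
    config = EvolutionConfig(seed=21, n_lsc_genes=20, n_ssc_genes=4, n_ir_genes=2)
    return materialize(make_architecture(config), "ref", config), config


class TestAncestralOrigin:

    def test_operon_and_region_labels(self, reference):
        (ref_genome, ref_quad), config = reference
        part = assign_regions(ref_genome, ref_quad)
        out = classify_ancestral_origin(part, ref_genome, ref_quad)
        origins = out.origin_of()
        assert origins["rrl"] == "rDNA-operon"
        assert origins["rrs"] == "rDNA-operon"
        arch = make_architecture(config)
        for g in arch.lsc:
            assert origins[g.name] == "LSC-origin"
        for g in arch.ssc:
            assert origins[g.name] == "SSC-origin"

    def test_gene_absent_from_reference_is_unknown(self, reference):
        (ref_genome, ref_quad), _ = reference
        g = simple_genome([("zzz9", "+", 1, 100)])
        part = assign_regions(g, no_ir_map(1000))
        out = classify_ancestral_origin(part, ref_genome, ref_quad)
        assert out.origin_of()["zzz9"] == "unknown"

    def test_reference_without_operon_errors(self):
        g = simple_genome([("a", "+", 1, 100)])
        part = assign_regions(g, no_ir_map(1000))
        with pytest.raises(ValueError, match="rDNA operon"):
            classify_ancestral_origin(part, g, no_ir_map(1000))

    def test_ir_expansion_creates_lsc_origin_ir_genes(self, reference):
        """Genes pulled into the IR by a boundary shift keep their LSC
        ancestry — the atypical-IR-gene signature."""
        (ref_genome, ref_quad), config = reference
        arch = make_architecture(config)
        moved = [g.name for g in arch.lsc[-2:]]
        shifted = apply_event(
            arch,
            Event("ir_shift", {"side": "lsc", "direction": "expand", "k": 2,
                               "genes": moved}),
        )
        genome, quad = materialize(shifted, "shifted", config)
        part = assign_regions(genome, quad)
        out = classify_ancestral_origin(part, ref_genome, ref_quad)
        acquired = lsc_origin_ir_genes(out)
        assert set(moved) <= set(acquired)


def test_interval_overlap_wrapping():
    assert interval_overlap((901, 100), (951, 50), 1000) == 100
    assert interval_overlap((901, 100), (200, 300), 1000) == 0
    assert interval_overlap((1, 1000), (500, 600), 1000) == 101
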