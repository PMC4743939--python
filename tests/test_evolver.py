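"""The synthetic genome evolver: determinism, IR integrity, event semantics."""

import pytest

from plastidarch.dollo import read_newick
from plastidarch.evolver import (
    Event,
    EvolutionConfig,
    GenomeArchitecture,
    InfeasibleEventError,
    _sample_event,
    apply_event,
    architecture_from_genome,
    emit_genbank,
    evolve,
    make_ancestor,
    make_architecture,
    materialize,
    replay,
)
from plastidarch.genome_model import SignedGene, read_genbank
from plastidarch.quadripartite import detect_inverted_repeat, revcomp
from plastidarch.reversal import reversal_distance, to_permutation
from plastidarch.synteny import shared_blocks

import numpy as np


SMALL = EvolutionConfig(seed=5, n_lsc_genes=12, n_ssc_genes=2, n_ir_genes=3)


class TestMakeAncestor:
    def test_same_seed_identical_bytes(self, tmp_path):
        g1 = make_ancestor(SMALL)
        g2 = make_ancestor(SMALL)
        p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
        emit_genbank(g1, p1)
        emit_genbank(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        g1 = make_ancestor(SMALL)
        g2 = make_ancestor(EvolutionConfig(seed=6, n_lsc_genes=12,
                                           n_ssc_genes=2, n_ir_genes=3))
        assert g1.sequence != g2.sequence

    def test_detection_matches_planted_ir(self):
        arch = make_architecture(SMALL)
        genome, truth = materialize(arch, "anc", SMALL)
        quad = detect_inverted_repeat(genome, min_len=500)
        assert (quad.ir_a, quad.ir_b) == (truth.ir_a, truth.ir_b)

    def test_ir_copies_exact_reverse_complement(self):
        genome, truth = materialize(make_architecture(SMALL), "anc", SMALL)
        a1, a2 = truth.ir_a
        b1, b2 = truth.ir_b
        assert genome.sequence[a1 - 1 : a2] == revcomp(genome.sequence[b1 - 1 : b2])

    def test_operon_inside_ir(self):
        arch = make_architecture(SMALL)
        ir_names = {g.name for g in arch.ir}
        assert {"rrs", "rrl", "rrf", "trnI(gau)", "trnA(ugc)"} <= ir_names

    def test_gene_empty_ssc_valid(self):
        config = EvolutionConfig(seed=5, n_lsc_genes=12, n_ssc_genes=0,
                                 n_ir_genes=3)
        genome, truth = materialize(make_architecture(config), "anc", config)
        assert truth.ssc_length > 0
        from plastidarch.quadripartite import assign_regions

        part = assign_regions(genome, truth)
        assert part.genes_in_region("SSC") == []


class TestEvents:
    def test_inversion_reverses_and_negates(self):
        arch = make_architecture(SMALL)
        before = list(arch.lsc)
        after = apply_event(
            arch, Event("inversion", {"region": "lsc", "start": 2, "span": 3})
        )
        assert after.lsc[2:5] == [-g for g in reversed(before[2:5])]
        assert after.lsc[:2] == before[:2] and after.lsc[5:] == before[5:]

    def test_gene_loss_removes_both_ir_copies(self):
        arch = make_architecture(SMALL)
        victim = next(g for g in arch.ir if g.name not in
                      ("rrs", "rrl", "rrf", "trnI(gau)", "trnA(ugc)"))
        after = apply_event(
            arch, Event("gene_loss", {"region": "ir", "gene": victim.name})
        )
        genome, _ = materialize(after, "t", SMALL)
        assert victim.name not in genome.gene_names()

    def test_ir_shift_relabels_exactly_the_moved_genes(self):
        arch = make_architecture(SMALL)
        moved = [g.name for g in arch.lsc[-2:]]
        after = apply_event(
            arch,
            Event("ir_shift", {"side": "lsc", "direction": "expand", "k": 2,
                               "genes": moved}),
        )
        before_regions = arch.region_of()
        after_regions = after.region_of()
        changed = {
            n for n in before_regions if before_regions[n] != after_regions[n]
        }
        assert changed == set(moved)
        assert all(after_regions[n] == "IR" for n in moved)

    def test_infeasible_ir_shift_raises(self):
        arch = GenomeArchitecture(
            lsc=[SignedGene("a", 1), SignedGene("b", 1)],
            ir=[SignedGene(n, 1) for n in
                ("rrs", "trnI(gau)", "trnA(ugc)", "rrl", "rrf")],
            ssc=[],
            gene_seqs={},
        )
        config = EvolutionConfig(n_lsc_genes=2, n_ssc_genes=0, n_ir_genes=0,
                                 ir_shift_span_range=(5, 5))
        rng = np.random.default_rng(0)
        with pytest.raises(InfeasibleEventError):
            _sample_event(arch, "ir_shift", rng, config)


class TestEvolve:
    def test_zero_events_tips_equal_ancestor(self):
        config = EvolutionConfig(seed=5, n_lsc_genes=12, n_ssc_genes=2,
                                 n_ir_genes=3, inversions_per_branch=0,
                                 losses_per_branch=0)
        arch = make_architecture(config)
        tree = read_newick("((A,B),C);")
        tips, truth = evolve(tree, arch, config)
        for name in tips:
            assert truth.tip_archs[name].all_genes() == arch.all_genes()
            assert truth.events[name] == []

    def test_replay_reproduces_tips(self):
        tree = read_newick("((A,B),(C,D));")
        arch = make_architecture(SMALL)
        tips, truth = evolve(tree, arch, SMALL)
        replayed = replay(truth, tree)
        for name in tips:
            assert replayed[name].all_genes() == truth.tip_archs[name].all_genes()
            genome, _ = materialize(replayed[name], name, SMALL)
            assert genome.sequence == tips[name].sequence

    def test_ir_copies_identical_after_all_events(self):
        tree = read_newick("((A,B),(C,D));")
        config = EvolutionConfig(seed=3, inversions_per_branch=2,
                                 losses_per_branch=1, ir_shifts_per_branch=1)
        tips, truth = evolve(tree, make_architecture(config), config)
        for name, genome in tips.items():
            quad = truth.tip_quads[name]
            a1, a2 = quad.ir_a
            b1, b2 = quad.ir_b
            assert genome.sequence[a1 - 1 : a2] == revcomp(
                genome.sequence[b1 - 1 : b2]
            )

    def test_single_inversion_distance_and_blocks(self):
        config = EvolutionConfig(seed=13, inversions_per_branch=1,
                                 losses_per_branch=0)
        arch = make_architecture(config)
        tree = read_newick("(A,B);")
        tips, truth = evolve(tree, arch, config)
        anc_order = arch.reduced_order("anc")
        for name in tips:
            tip_order = truth.tip_archs[name].reduced_order(name)
            d = reversal_distance(to_permutation(anc_order, tip_order)).d
            assert d <= 1
            blocks, singles = shared_blocks(anc_order, tip_order)
            assert len(blocks) <= 2

    def test_k_inversions_distance_bound_and_usual_equality(self):
        tree = read_newick("(A,B);")
        hits = total = 0
        for k in (1, 2, 3):
            for seed in range(10):
                config = EvolutionConfig(seed=seed, inversions_per_branch=k,
                                         losses_per_branch=0)
                arch = make_architecture(config)
                tips, truth = evolve(tree, arch, config)
                anc = arch.reduced_order("anc")
                for name in tips:
                    tip = truth.tip_archs[name].reduced_order(name)
                    d = reversal_distance(to_permutation(anc, tip)).d
                    assert d <= k
                    total += 1
                    hits += d == k
        assert hits / total >= 0.95

    def test_event_log_counts_match_config(self):
        tree = read_newick("((A,B),C);")
        config = EvolutionConfig(seed=5, n_lsc_genes=12, n_ssc_genes=2,
                                 n_ir_genes=3, inversions_per_branch=2,
                                 losses_per_branch=1)
        _, truth = evolve(tree, make_architecture(config), config)
        for edge, events in truth.events.items():
            kinds = [e.kind for e in events]
            assert kinds == ["inversion", "inversion", "gene_loss"]


class TestGenBankRoundTrip:
    def test_round_trip_equality(self, tmp_path):
        genome, _ = materialize(make_architecture(SMALL), "rt", SMALL)
        path = tmp_path / "rt.gb"
        emit_genbank(genome, path)
        back = read_genbank(path)
        assert back.length == genome.length
        assert back.circular
        assert back.sequence == genome.sequence
        assert [
            (f.normalized_name, f.category, f.strand, f.start, f.end)
            for f in back.features
        ] == [
            (f.normalized_name, f.category, f.strand, f.start, f.end)
            for f in genome.features
        ]
        assert back.repeat_regions == genome.repeat_regions

    def test_wrapping_feature_round_trip(self, tmp_path):
        from plastidarch.genome_model import AnnotatedGenome, GeneFeature

        genome = AnnotatedGenome(
            id="wrap",
            length=1000,
            circular=True,
            features=[
                GeneFeature("psbA", "psbA", "protein", "+", 950, 20, True)
            ],
            sequence="A" * 1000,
        )
        path = tmp_path / "wrap.gb"
        emit_genbank(genome, path)
        back = read_genbank(path)
        f = back.features[0]
        assert f.wraps_origin and f.start == 950 and f.end == 20

    def test_architecture_recovered_from_genome(self):
        arch = make_architecture(SMALL)
        genome, quad = materialize(arch, "rec", SMALL)
        rec = architecture_from_genome(genome, quad)
        assert rec.lsc == arch.lsc
        assert rec.ir == arch.ir
        assert rec.ssc == arch.ssc
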