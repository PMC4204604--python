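"""Simulator: genome/methylome generation, conversion, amplification."""

import numpy as np
import pytest
from scipy import stats as sps

import methylbias as mb
from methylbias import sequtils as sq
from helpers import make_truth


class TestGenerateGenome:
    def test_lengths_and_contigs_forced_by_parameters(self):
        g = mb.generate_genome(2, 1000, (0.3, 0.5), 500, seed=7)
        assert g.total_length == 2500
        assert len(g.contigs) == 2
        assert g.control_contig in g.contigs

    def test_same_seed_gives_byte_identical_genome(self):
        a = mb.generate_genome(2, 1000, (0.3, 0.5), 500, seed=7)
        b = mb.generate_genome(2, 1000, (0.3, 0.5), 500, seed=7)
        assert a.contigs == b.contigs

    def test_flat_gradient_realizes_target_gc(self):
        g = mb.generate_genome(10, 10000, (0.30, 0.30), 500, seed=11)
        main = next(c for c in g.contigs if c != g.control_contig)
        assert abs(sq.gc_fraction(g.contigs[main]) - 0.30) < 0.02

    @pytest.mark.parametrize("kwargs", [
        dict(n_regions=1), dict(region_length=50),
        dict(gc_gradient=(0.0, 0.5)), dict(control_length=0)])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_regions=2, region_length=1000, gc_gradient=(0.3, 0.5),
                    control_length=500, seed=1)
        base.update(kwargs)
        with pytest.raises(mb.ParameterError):
            mb.generate_genome(**base)


class TestGenerateMethylome:
    def _genome(self, seq):
        return mb.GenomeSequence({"m": seq, "c": "ATAT"}, "c",
                                 regions=[("m", 0, len(seq))])

    def test_cg_context_from_sequence(self):
        truth = mb.generate_methylome(self._genome("ACGT"), [(1.0, 1.0, 1.0)])
        frame = truth.to_frame()
        plus = frame[(frame.strand == "+") & (frame.contig == "m")]
        assert plus.pos.tolist() == [1]
        assert plus.context.tolist() == ["CG"]

    def test_chg_context_with_h_equal_a(self):
        truth = mb.generate_methylome(self._genome("ACAGT"), [(0.5, 0.5, 0.5)])
        frame = truth.to_frame()
        rec = frame[(frame.contig == "m") & (frame.pos == 1)
                    & (frame.strand == "+")]
        assert rec.context.tolist() == ["CHG"]

    def test_all_zero_triples_give_all_zero_probabilities(self, gradient_genome):
        truth = mb.generate_methylome(gradient_genome, [(0, 0, 0)] * 4)
        assert (truth.to_frame().probability == 0).all()

    def test_control_contig_is_fully_unmethylated(self, gradient_truth,
                                                  gradient_genome):
        frame = gradient_truth.to_frame()
        ctrl = frame[frame.contig == gradient_genome.control_contig]
        assert len(ctrl) > 0
        assert (ctrl.probability == 0).all()

    def test_triple_count_mismatch_rejected(self, gradient_genome):
        with pytest.raises(mb.ParameterError):
            mb.generate_methylome(gradient_genome, [(0.5, 0.5, 0.5)] * 3)


class TestSimulateFragments:
    def test_zero_fragments_gives_empty_pool(self, gradient_genome):
        assert mb.simulate_fragments(gradient_genome, 0, 50, seed=1) == []

    def test_starts_within_valid_range(self):
        g = mb.GenomeSequence({"c": "ACGT" * 25}, "c")
        frags = mb.simulate_fragments(g, 200, 50, seed=2)
        assert all(0 <= f.start <= 50 for f in frags)

    def test_contig_share_proportional_to_length(self):
        g = mb.GenomeSequence(
            {"big": "ACGT" * 22500, "small": "ACGT" * 2500}, "small")
        frags = mb.simulate_fragments(g, 10000, 50, seed=3)
        share = sum(f.contig == "small" for f in frags) / 10000
        assert abs(share - 0.10) < 0.01

    def test_fragment_too_long_rejected(self, gradient_genome):
        with pytest.raises(mb.ParameterError):
            mb.simulate_fragments(gradient_genome, 10, 601, seed=1)

    def test_minus_strand_sequence_is_reverse_complement(self, gradient_genome):
        frags = mb.simulate_fragments(gradient_genome, 50, 40, seed=4)
        f = next(f for f in frags if f.strand == "-")
        ref = gradient_genome.contigs[f.contig][f.start:f.start + 40]
        assert f.sequence == sq.revcomp(ref)


class TestBisulfiteConversion:
    def test_forced_outcomes(self):
        g = mb.GenomeSequence({"m": "ACGCT", "c": "ATAT"}, "c")
        truth = make_truth(g, {("m", "+"): {1: 1.0, 3: 0.0}})
        frag = mb.Fragment("m", 0, "+", "ACGCT")
        assert mb.bisulfite_convert_fragment(frag, truth, 0.0, seed=1) == "ACGTT"

    def test_c_free_fragment_unchanged(self):
        g = mb.GenomeSequence({"m": "AGGT", "c": "ATAT"}, "c")
        truth = make_truth(g)
        frag = mb.Fragment("m", 0, "+", "AGGT")
        assert mb.bisulfite_convert_fragment(frag, truth, 0.3, seed=1) == "AGGT"

    def test_nonconversion_rate_sets_retained_c_count(self):
        g = mb.GenomeSequence({"m": "C" * 10000, "c": "ATAT"}, "c")
        truth = make_truth(g)
        frag = mb.Fragment("m", 0, "+", "C" * 10000)
        conv = mb.bisulfite_convert_fragment(frag, truth, 0.005, seed=13)
        assert 35 <= conv.count("C") <= 65  # mean 50, +-2 binomial SD

    def test_converted_gc_never_exceeds_original(self, gradient_genome,
                                                 gradient_truth):
        pool = mb.simulate_fragments(gradient_genome, 300, 80, seed=6)
        conv = mb.bisulfite_convert_pool(pool, gradient_truth, 0.01, seed=7)
        for raw, c in zip(pool, conv):
            assert sq.gc_fraction(c.sequence) <= sq.gc_fraction(raw.sequence)

    def test_pool_conversion_deterministic(self, gradient_genome,
                                           gradient_truth):
        pool = mb.simulate_fragments(gradient_genome, 100, 60, seed=8)
        a = mb.bisulfite_convert_pool(pool, gradient_truth, 0.01, seed=9)
        b = mb.bisulfite_convert_pool(pool, gradient_truth, 0.01, seed=9)
        assert [f.sequence for f in a] == [f.sequence for f in b]


class TestAmplifyAndSample:
    def _two_fragment_pool(self):
        # GC 0.75 and 0.25 at length 8
        g = mb.GenomeSequence({"m": "GGGCGGATGCATTATA", "c": "ATAT"}, "c")
        return [mb.Fragment("m", 0, "+", "GGGCGGAT"),
                mb.Fragment("m", 8, "+", "GCATTATA")]

    def test_zero_cycles_samples_uniformly(self):
        pool = self._two_fragment_pool()
        lib = mb.amplify_and_sample(pool, mb.ENZYME_PRESETS["pfu-like"], 0,
                                    20000, seed=1)
        share = sum(r.start == 0 for r in lib.reads) / 20000
        assert abs(share - 0.5) < 0.02

    def test_constant_efficiency_is_cycle_invariant(self):
        pool = self._two_fragment_pool()
        enzyme = mb.EnzymeProfile("flat", base_efficiency=1.0, gc_coefficient=0.0)
        lib = mb.amplify_and_sample(pool, enzyme, 15, 20000, seed=2)
        share = sum(r.start == 0 for r in lib.reads) / 20000
        assert abs(share - 0.5) < 0.02

    def test_high_gc_read_share_matches_copy_weight_model(self):
        # e(0.75)=0.9, e(0.25)=0.5 under e0=0.7, gamma=0.8;
        # expected share 1.9^15 / (1.9^15 + 1.5^15)
        pool = self._two_fragment_pool()
        enzyme = mb.EnzymeProfile("steep", base_efficiency=0.7,
                                  gc_coefficient=0.8)
        lib = mb.amplify_and_sample(pool, enzyme, 15, 100000, seed=3)
        share = sum(r.start == 0 for r in lib.reads) / 100000
        expected = 1.9**15 / (1.9**15 + 1.5**15)
        assert abs(share - expected) < 0.002

    def test_empty_pool_rejected(self):
        with pytest.raises(mb.ParameterError):
            mb.amplify_and_sample([], mb.ENZYME_PRESETS["pfu-like"], 4, 10,
                                  seed=1)

    def test_library_deterministic_given_seed(self, gradient_genome,
                                              gradient_truth):
        pool = mb.simulate_fragments(gradient_genome, 200, 60, seed=4)
        conv = mb.bisulfite_convert_pool(pool, gradient_truth, 0.005, seed=5)
        a = mb.amplify_and_sample(conv, mb.ENZYME_PRESETS["epimark-like"], 8,
                                  500, seed=6)
        b = mb.amplify_and_sample(conv, mb.ENZYME_PRESETS["epimark-like"], 8,
                                  500, seed=6)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        assert [(r.contig, r.start, r.strand) for r in a.reads] == \
               [(r.contig, r.start, r.strand) for r in b.reads]


def test_saturating_profile_flattens_above_threshold():
    enzyme = mb.ENZYME_PRESETS["epimark-like"]
    assert enzyme.efficiency(0.7) == enzyme.efficiency(0.6)
    assert enzyme.efficiency(0.5) < enzyme.efficiency(0.6)


def test_unbiased_enzyme_read_counts_exchangeable_across_gc():
    """With gamma=0 the per-GC-decile read counts pass a chi-square test of
    uniform-over-fragments sampling in >=95% of 100 seeded draws."""
    genome = mb.generate_genome(10, 1000, (0.3, 0.5), 500, seed=21)
    triples = [(m, 0.7 * m, 0.3 * m) for m in np.linspace(0.9, 0.1, 10)]
    truth = mb.generate_methylome(genome, triples)
    pool = mb.simulate_fragments(genome, 2000, 100, seed=22)
    conv = mb.bisulfite_convert_pool(pool, truth, 0.005, seed=23)
    gc = np.array([sq.gc_fraction(f.sequence) for f in conv])
    edges = np.quantile(gc, np.linspace(0, 1, 11))[1:-1]
    pool_bins = np.searchsorted(edges, gc)
    expected = np.bincount(pool_bins, minlength=10) / len(conv)
    enzyme = mb.ENZYME_PRESETS["kapa-like"]
    non_significant = 0
    for seed in range(100):
        lib = mb.amplify_and_sample(conv, enzyme, 8, 5000, seed=1000 + seed)
        read_gc = np.array([sq.gc_fraction(r.sequence) for r in lib.reads])
        observed = np.bincount(np.searchsorted(edges, read_gc), minlength=10)
        p = sps.chisquare(observed, expected * 5000).pvalue
        non_significant += p > 0.01
    assert non_significant >= 95
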