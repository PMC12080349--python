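"""Dereplication, length filtering, and mutation counting/summary."""

import random

import pytest

from ecrmech.repeat_mutations import (count_mutations, dereplicate_arrays,
                                      filter_length_outliers, mutation_summary)
from ecrmech.seqcore import NucleotideSequence
from ecrmech.synth import SynthConfig, generate_cohort
from ecrmech.pipeline import run_pipeline, RunConfig

NS = NucleotideSequence


def qc_cohort(cfg, seed):
    """Generate and QC a cohort without the slower stages."""
    cfg_run = RunConfig(synth=cfg, seed=seed,
                        skip_stages=("helix", "rit", "energy", "mechanisms"))
    return run_pipeline(cfg_run)


class TestDereplicate:
    def test_identical_repeat_lists_collapse(self):
        cfg = SynthConfig(n_loci=4, p_mutation=0.0, p_nonextra_mutated=0.0,
                          p_reverse=0.0)
        loci = generate_cohort(cfg, seed=3).loci
        # force two loci to share their repeat strings
        loci[1].contig = loci[0].contig
        loci[1].repeats = loci[0].repeats
        loci[1].spacers = loci[0].spacers
        assert len(dereplicate_arrays(loci)) == 3

    def test_single_base_difference_keeps_both(self, rng):
        cfg = SynthConfig(n_loci=2, p_mutation=1.0,
                          mutation_count_probs=((1, 1.0),))
        loci = generate_cohort(cfg, seed=4).loci
        assert len(dereplicate_arrays(loci)) == 2

    def test_empty(self):
        assert dereplicate_arrays([]) == []


class TestLengthFilter:
    def _locus_with_repeat_lengths(self, rng, lengths):
        from test_locus_qc import build_locus
        locus, _, consensus = build_locus(rng, n_spacers=len(lengths) - 1)
        locus.consensus = NS("c", consensus)
        # shrink selected repeats by rebuilding intervals
        from ecrmech.seqcore import GenomicInterval
        new = []
        for iv, L in zip(locus.repeats, lengths):
            new.append(GenomicInterval(iv.contig, iv.start, iv.start + L))
        locus.repeats = new
        locus.spacers = [GenomicInterval(iv.contig, a.end, b.start)
                         for iv, (a, b) in zip(locus.spacers, zip(new, new[1:]))]
        return locus

    def test_one_nt_discrepancy_retained(self, rng):
        locus = self._locus_with_repeat_lengths(rng, [35, 36, 36, 36])
        assert 0 in filter_length_outliers(locus)

    def test_two_nt_discrepancy_excluded(self, rng):
        locus = self._locus_with_repeat_lengths(rng, [34, 36, 36, 36])
        keep = filter_length_outliers(locus)
        assert 0 not in keep and keep == [1, 2, 3]

    def test_all_equal_all_retained(self, rng):
        locus = self._locus_with_repeat_lengths(rng, [36] * 4)
        assert filter_length_outliers(locus) == [0, 1, 2, 3]


class TestCountMutations:
    CONS = "ACGTTGCAGGATCCATGGTACGATCGGATATCGCAT"  # 36-mer

    def test_identical_repeat_zero(self):
        rec = count_mutations(NS("r", self.CONS), NS("c", self.CONS))
        assert rec.mutations == 0 and rec.positions == ()

    def test_two_substitutions_at_2_and_9(self):
        rep = list(self.CONS)
        rep[1] = "G"   # position 2
        rep[8] = "T"   # position 9
        rec = count_mutations(NS("r", "".join(rep)), NS("c", self.CONS))
        assert rec.mutations == 2 and rec.positions == (2, 9)

    def test_single_deletion_counts_one(self):
        rep = self.CONS[:17] + self.CONS[18:]
        rec = count_mutations(NS("r", rep), NS("c", self.CONS))
        assert rec.mutations == 1

    def test_gap_run_modes(self):
        rep = self.CONS[:17] + self.CONS[20:]  # 3-nt deletion
        as_columns = count_mutations(NS("r", rep), NS("c", self.CONS))
        as_run = count_mutations(NS("r", rep), NS("c", self.CONS),
                                 gap_run_as_one=True)
        assert as_columns.mutations == 3
        assert as_run.mutations == 1


class TestSummary:
    def test_planted_focus_mutations_only(self):
        cfg = SynthConfig(n_loci=10, p_mutation=1.0,
                          mutation_count_probs=((1, 1.0),),
                          p_nonextra_mutated=0.0)
        res = qc_cohort(cfg, seed=5)
        summary = res.mutation
        assert summary.focus_frac_mutated == 1.0
        assert summary.nonfocus_frac_mutated == 0.0

    def test_zero_plant_cohort_is_exactly_zero(self):
        cfg = SynthConfig(n_loci=10, p_mutation=0.0, p_nonextra_mutated=0.0)
        res = qc_cohort(cfg, seed=6)
        assert res.mutation.focus_frac_mutated == 0.0
        assert res.mutation.nonfocus_frac_mutated == 0.0

    def test_positions_respect_first15_plant(self):
        cfg = SynthConfig(n_loci=40, p_mutation=1.0, p_position_first15=1.0,
                          mutation_count_probs=((2, 1.0),), p_nonextra_mutated=0.0)
        res = qc_cohort(cfg, seed=7)
        pos = res.mutation.focus_positions
        total = sum(pos.values())
        within = sum(c for p, c in pos.items() if p <= 15)
        assert total > 0 and within / total >= 0.95

    def test_order_invariance(self):
        cfg = SynthConfig(n_loci=8, p_mutation=0.7)
        loci = [l for l in generate_cohort(cfg, seed=8).loci]
        for l in loci:
            l.consensus = l.compute_consensus()
        a = mutation_summary(loci, focus="first")
        b = mutation_summary(list(reversed(loci)), focus="first")
        assert a.focus_frac_mutated == b.focus_frac_mutated
        assert a.nonfocus_hist == b.nonfocus_hist

    def test_focus_last_selects_final_repeat(self):
        cfg = SynthConfig(n_loci=6, subtype="II-A", p_mutation=0.0,
                          p_nonextra_mutated=0.0)
        loci = generate_cohort(cfg, seed=9).loci
        for l in loci:
            l.consensus = l.compute_consensus()
        s = mutation_summary(loci, focus="last")
        assert s.focus_frac_mutated == 0.0
        assert sum(1 for r in s.records if r.is_focus) == len(loci)
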