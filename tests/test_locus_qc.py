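"""Leader trimming and mutated-repeat rescue with the empirical e-value gate."""

import random

import pytest

from ecrmech.locus_qc import CrisprLocus, rescue_mutated_repeat, trim_upstream
from ecrmech.seqcore import GenomicInterval, NucleotideSequence

NS = NucleotideSequence


def build_locus(rng, gap_to_gene=400, plant=None, plant_gap=30, n_spacers=3,
                repeat_len=36, comp_weights=(12, 3, 3, 2)):
    """Hand-rolled locus: gene ... intergenic ... array, plus-strand."""
    consensus = "".join(rng.choice("ACGT") for _ in range(repeat_len))
    gene_len = 300
    intergenic = list("".join(rng.choices("ACGT", weights=comp_weights, k=gap_to_gene)))
    if plant is not None:
        pos = len(intergenic) - plant_gap - len(plant)
        intergenic[pos:pos + len(plant)] = list(plant)
    parts = ["".join(rng.choice("ACGT") for _ in range(gene_len)), "".join(intergenic)]
    pos = gene_len + len(intergenic)
    repeat_ivs = []
    for i in range(n_spacers + 1):
        repeat_ivs.append((pos, pos + repeat_len))
        parts.append(consensus)
        pos += repeat_len
        if i < n_spacers:
            parts.append("".join(rng.choice("ACGT") for _ in range(30)))
            pos += 30
    contig = NS("ctg", "".join(parts))
    locus = CrisprLocus.from_annotation("loc1", "II-C", contig, "+", repeat_ivs)
    genes = [GenomicInterval("ctg", 0, gene_len)]
    return locus, genes, consensus


def mutate(rng, seq, k):
    out = list(seq)
    for p in rng.sample(range(len(seq)), k):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestTrimUpstream:
    def test_distant_gene_caps_at_180(self, rng):
        locus, genes, _ = build_locus(rng, gap_to_gene=400)
        out = trim_upstream(locus, genes)
        assert len(out.upstream) == 180 and out.qc_action == "kept"

    def test_close_gene_shortens(self, rng):
        locus, genes, _ = build_locus(rng, gap_to_gene=100)
        out = trim_upstream(locus, genes)
        assert len(out.upstream) == 100 and out.qc_action == "trimmed"

    def test_very_close_gene_rejects(self, rng):
        locus, genes, _ = build_locus(rng, gap_to_gene=20)
        out = trim_upstream(locus, genes)
        assert out.rejected and "30" in out.reject_reason

    def test_upstream_abuts_repeat_one(self, rng):
        locus, genes, _ = build_locus(rng, gap_to_gene=250)
        out = trim_upstream(locus, genes)
        r1 = out.repeats[0]
        assert out.contig.residues[r1.start - len(out.upstream):r1.start] \
            == out.upstream.residues

    def test_guide_window_is_last_25(self, rng):
        locus, genes, _ = build_locus(rng)
        out = trim_upstream(locus, genes)
        assert out.guide_window == (155, 180)


class TestRescue:
    def test_planted_degraded_repeat_is_rescued(self):
        rng = random.Random(1)
        _, _, consensus = build_locus(rng)
        plant = mutate(random.Random(99), consensus, 3)  # 33/36 = 92% identity
        rng = random.Random(1)  # same stream: same consensus and background
        locus, genes, consensus = build_locus(rng, plant=plant, plant_gap=30)
        locus = trim_upstream(locus, genes)
        locus.consensus = locus.compute_consensus()
        n_rep, n_spc = len(locus.repeats), len(locus.spacers)
        out, cand = rescue_mutated_repeat(locus, n_shuffles=200, seed=1)
        assert cand is not None and cand.accepted
        assert cand.empirical_e < 0.01
        assert cand.implied_spacer_len == 30
        assert len(out.repeats) == n_rep + 1 and len(out.spacers) == n_spc + 1
        assert len(out.repeats) == len(out.spacers) + 1
        assert cand.identity > 0.70
        # idempotent once nothing is left to rescue
        out2, cand2 = rescue_mutated_repeat(out, n_shuffles=200, seed=2)
        if cand2 is None or not cand2.accepted:
            assert len(out2.repeats) == len(out.repeats)

    def test_plant_outside_distance_window_rejected(self):
        rng = random.Random(2)
        _, _, consensus = build_locus(rng)
        rng = random.Random(2)
        locus, genes, consensus = build_locus(rng, plant=None)
        plant = mutate(random.Random(3), consensus, 2)
        rng = random.Random(2)
        locus, genes, consensus = build_locus(rng, plant=plant, plant_gap=50)
        locus = trim_upstream(locus, genes)
        locus.consensus = locus.compute_consensus()
        out, cand = rescue_mutated_repeat(locus, n_shuffles=200, seed=3)
        assert cand is None or not cand.accepted
        assert len(out.repeats) == len(locus.repeats)

    def test_low_identity_plant_rejected(self):
        rng = random.Random(4)
        locus, genes, consensus = build_locus(rng)
        plant = mutate(random.Random(5), consensus, 15)  # ~58% identity
        rng = random.Random(4)
        locus, genes, consensus = build_locus(rng, plant=plant, plant_gap=30)
        locus = trim_upstream(locus, genes)
        locus.consensus = locus.compute_consensus()
        out, cand = rescue_mutated_repeat(locus, n_shuffles=200, seed=5)
        assert cand is None or not cand.accepted

    def test_missing_consensus_raises(self, rng):
        locus, genes, _ = build_locus(rng)
        locus = trim_upstream(locus, genes)
        with pytest.raises(ValueError):
            rescue_mutated_repeat(locus, n_shuffles=100, seed=0)

    def test_null_acceptance_rate_below_two_percent(self):
        accepted = 0
        n = 100
        for i in range(n):
            rng = random.Random(1000 + i)
            locus, genes, _ = build_locus(rng, gap_to_gene=250)
            locus = trim_upstream(locus, genes)
            locus.consensus = locus.compute_consensus()
            _, cand = rescue_mutated_repeat(locus, n_shuffles=100, seed=i)
            if cand is not None and cand.accepted:
                accepted += 1
        assert accepted / n < 0.02


class TestOrientation:
    def test_minus_strand_locus_is_normalised(self, rng):
        locus, genes, consensus = build_locus(rng)
        # rebuild the same locus annotated on the minus strand
        rc = locus.contig.reverse_complement("ctg")
        L = len(rc)
        ivs = [(L - iv.end, L - iv.start) for iv in locus.repeats]
        flipped = CrisprLocus.from_annotation("loc1", "II-C", rc, "-", ivs)
        assert flipped.extra_repeat_seq().residues == locus.extra_repeat_seq().residues
        assert [len(s) for s in flipped.spacers] == [len(s) for s in locus.spacers]

    def test_repeat_spacer_invariant_enforced(self, rng):
        locus, _, _ = build_locus(rng)
        with pytest.raises(ValueError):
            CrisprLocus("bad", "II-C", locus.contig, "+", locus.repeats,
                        locus.spacers[:-1])
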