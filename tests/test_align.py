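"""Alignment engines against brute-force enumeration oracles.

The global oracle enumerates every alignment op-string of two short
sequences and prices it directly from the stated cost model (gap run of
length L costs open + L*extend; runs in the leading/trailing all-gap
blocks use the end-gap prices).  The local oracle enumerates substring
pairs and their gapped alignments.  Both are exponential and therefore
restricted to short inputs.
"""

import random

import pytest

from ecrmech.align import (AlignmentParams, best_local_score, global_align,
                           local_align)
from ecrmech.seqcore import NucleotideSequence

NS = NucleotideSequence


def price_alignment(ops, a, b, p: AlignmentParams) -> float:
    """Score an op-string (M/X/Y; X = gap in b consuming a) under the model."""
    k0 = 0
    while k0 < len(ops) and ops[k0] != "M":
        k0 += 1
    k1 = len(ops)
    while k1 > k0 and ops[k1 - 1] != "M":
        k1 -= 1
    score = 0.0
    i = j = 0
    run = None
    for idx, op in enumerate(ops):
        terminal = idx < k0 or idx >= k1
        if op == "M":
            score += p.match if (a[i] == b[j] and a[i] != "N") else p.mismatch
            i += 1
            j += 1
            run = None
        else:
            if op == "X":
                i += 1
            else:
                j += 1
            opn, ext = (p.end_open, p.end_extend) if terminal else (p.gap_open, p.gap_extend)
            score -= ext if run == (op, terminal) else opn + ext
            run = (op, terminal)
    return score


def brute_force_global(a: str, b: str, p: AlignmentParams) -> float:
    best = [float("-inf")]
    ops: list[str] = []
    n, m = len(a), len(b)

    def rec(i, j):
        if i == n and j == m:
            s = price_alignment(ops, a, b, p)
            if s > best[0]:
                best[0] = s
            return
        if i < n and j < m:
            ops.append("M")
            rec(i + 1, j + 1)
            ops.pop()
        if i < n:
            ops.append("X")
            rec(i + 1, j)
            ops.pop()
        if j < m:
            ops.append("Y")
            rec(i, j + 1)
            ops.pop()

    rec(0, 0)
    return best[0]


def brute_force_local(q: str, s: str, p: AlignmentParams) -> float:
    """Best substring-vs-substring alignment score, floored at 0."""
    best = 0.0
    for i0 in range(len(q)):
        for i1 in range(i0 + 1, len(q) + 1):
            for j0 in range(len(s)):
                for j1 in range(j0 + 1, len(s) + 1):
                    sub_q, sub_s = q[i0:i1], s[j0:j1]
                    sc = _best_internal(sub_q, sub_s, p)
                    if sc > best:
                        best = sc
    return best


def _best_internal(a, b, p):
    # all alignments of a vs b, all gaps priced internally
    best = [float("-inf")]
    ops: list[str] = []

    def rec(i, j):
        if i == len(a) and j == len(b):
            score = 0.0
            run = None
            x = y = 0
            for op in ops:
                if op == "M":
                    score += p.match if a[x] == b[y] else p.mismatch
                    x += 1
                    y += 1
                    run = None
                else:
                    if op == "X":
                        x += 1
                    else:
                        y += 1
                    score -= p.gap_extend if run == op else p.gap_open + p.gap_extend
                    run = op
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            ops.append("M"); rec(i + 1, j + 1); ops.pop()
        if i < len(a):
            ops.append("X"); rec(i + 1, j); ops.pop()
        if j < len(b):
            ops.append("Y"); rec(i, j + 1); ops.pop()

    rec(0, 0)
    return best[0]


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align(NS("a", "ACGT"), NS("b", "ACGT"))
        assert aln.mismatches == 0 and aln.gap_columns == 0 and aln.identity == 1.0

    def test_single_substitution_scores_eleven(self):
        p = AlignmentParams(match=5, mismatch=-4, gap_open=99, gap_extend=99,
                            end_open=99, end_extend=99)
        aln = global_align(NS("a", "ACGT"), NS("b", "ACTT"), p)
        assert aln.mismatches == 1 and aln.score == 11

    def test_single_deletion(self):
        aln = global_align(NS("a", "ACGTACGT"), NS("b", "ACGACGT"))
        assert aln.gap_columns == 1 and aln.mismatches == 0

    def test_degap_recovers_inputs(self, rng):
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
            aln = global_align(NS("a", a), NS("b", b))
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    def test_column_accounting(self, rng):
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 20)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 20)))
            aln = global_align(NS("a", a), NS("b", b))
            matches = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                          if x == y and x != "-")
            assert matches + aln.mismatches + aln.gap_columns == len(aln.aligned_a)

    def test_mutation_count_symmetry(self, rng):
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 25)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 25)))
            f = global_align(NS("a", a), NS("b", b))
            r = global_align(NS("b", b), NS("a", a))
            assert f.score == r.score
            assert f.mismatches + f.gap_columns == r.mismatches + r.gap_columns

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align(NS("a", "ACGT"), NS("b", ""))

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_enumeration_oracle(self, trial):
        rng = random.Random(100 + trial)
        p = AlignmentParams.needle_defaults()
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 7)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 7)))
            expect = brute_force_global(a, b, p)
            got = global_align(NS("a", a), NS("b", b), p).score
            assert got == pytest.approx(expect), (a, b)

    def test_matches_oracle_with_distinct_end_costs(self):
        rng = random.Random(7)
        p = AlignmentParams(match=3, mismatch=-2, gap_open=4, gap_extend=2,
                            end_open=1, end_extend=1)
        for _ in range(40):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 6)))
            expect = brute_force_global(a, b, p)
            got = global_align(NS("a", a), NS("b", b), p).score
            assert got == pytest.approx(expect), (a, b)


class TestLocalAlign:
    def test_embedded_exact_match(self, rng):
        bg = "".join(rng.choice("ACGT") for _ in range(100))
        q = bg[40:50]
        hits = local_align(NS("q", q), NS("s", bg))
        assert hits[0].score == 10 and hits[0].identity == 1.0
        assert hits[0].interval.start == 40 or bg.count(q) > 1

    def test_one_substitution_scores_eight(self, rng):
        bg = "".join(rng.choice("ACGT") for _ in range(100))
        q = list(bg[40:50])
        q[5] = "A" if q[5] != "A" else "C"
        hits = local_align(NS("q", "".join(q)), NS("s", bg), min_score=6)
        assert hits[0].score == 8

    def test_no_shared_seed_gives_no_hits(self):
        hits = local_align(NS("q", "A" * 20), NS("s", "C" * 100))
        assert hits == []

    def test_hits_sorted_and_non_overlapping(self, rng):
        bg = "".join(rng.choice("ACGT") for _ in range(200))
        q = bg[50:70]
        seq = bg[:120] + bg[50:70] + bg[120:]  # second copy
        hits = local_align(NS("q", q), NS("s", seq), min_score=10)
        assert len(hits) >= 2
        assert hits[0].score >= hits[1].score
        for i, h in enumerate(hits):
            for other in hits[i + 1:]:
                assert not h.interval.overlaps(other.interval)

    @pytest.mark.parametrize("trial", range(2))
    def test_matches_enumeration_oracle(self, trial):
        rng = random.Random(200 + trial)
        p = AlignmentParams(mode="local", match=1, mismatch=-1, gap_open=2,
                            gap_extend=1, word_size=0)
        for _ in range(15):
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 6)))
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 6)))
            assert best_local_score(NS("q", q), NS("s", s), p) == \
                pytest.approx(brute_force_local(q, s, p)), (q, s)
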