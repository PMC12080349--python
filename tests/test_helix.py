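"""Helix finder vs an independent recursive oracle, shuffle nulls, and
cohort aggregation."""

import random
from functools import lru_cache

import pytest

from ecrmech.helix import (HelixParams, aggregate_enrichment, find_helix,
                           has_qualifying_helix, pairing_profile, parameter_scan,
                           system_null_prob)
from ecrmech.seqcore import NucleotideSequence, reverse_complement

NS = NucleotideSequence
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def oracle_best(s: str, max_unpaired: int, min_loop: int = 3,
                win_start: int | None = None) -> tuple[int, int]:
    """(best bp, unpaired at best) by top-down recursion over chain starts.

    A chain starting at pair (i, j) extends inward to (i2 > i, j2 < j);
    because the guide window is a suffix of the sequence, a chain touches
    it iff its outermost j lies in the window.
    """
    n = len(s)
    pairs = [(i, j) for i in range(n) for j in range(i + min_loop + 1, n)
             if (s[i], s[j]) in _WC]

    @lru_cache(maxsize=None)
    def f(i: int, j: int, b: int) -> int:
        best = 1
        for i2 in range(i + 1, min(n, i + 2 + b)):
            ga = i2 - i - 1
            for j2 in range(j - 1, max(i2 + min_loop, j - 2 - (b - ga)), -1):
                used = ga + (j - j2 - 1)
                if used > b or (s[i2], s[j2]) not in _WC:
                    continue
                v = 1 + f(i2, j2, b - used)
                if v > best:
                    best = v
        return best

    best_bp, best_g = 0, 0
    for b in range(max_unpaired + 1):
        for i, j in pairs:
            if win_start is not None and j < win_start:
                continue
            v = f(i, j, b)
            if v > best_bp:
                best_bp, best_g = v, b
    return best_bp, best_g


class TestFindHelix:
    def test_planted_perfect_duplex_intra(self):
        # GC-only stem in a poly-A background: only the plant can pair
        stem = "GCCGGCAGCGGC"[:12].replace("A", "G")
        up = "A" * 20 + stem + "A" * 20 + reverse_complement(stem) + "A" * 20
        m = find_helix(NS("u", up), HelixParams.intra_defaults())
        assert m is not None and m.bp_count == 12 and m.unpaired_count == 0

    def test_guide_mode_eight_found_seven_not(self):
        # poly-C guide window; planted poly-G arm is the only pairing partner
        for arm_len, expect in [(8, True), (7, False)]:
            up = "A" * 40 + "G" * arm_len + "A" * (60 - arm_len) + "C" * 25
            m = find_helix(NS("u", up), HelixParams.guide_defaults())
            if expect:
                assert m is not None and m.bp_count == 8 and m.unpaired_count == 0
            else:
                assert m is None

    def test_poly_a_has_no_helix(self):
        assert find_helix(NS("u", "A" * 120), HelixParams.guide_defaults()) is None
        assert find_helix(NS("u", "A" * 120), HelixParams.intra_defaults()) is None

    def test_too_short_sequence(self):
        assert find_helix(NS("u", "ACGU"), HelixParams.intra_defaults()) is None

    def test_arms_disjoint_and_loop_respected(self, rng):
        for _ in range(30):
            s = "".join(rng.choices("ACGT", weights=[2, 2, 2, 2], k=50))
            m = find_helix(NS("u", s), HelixParams(min_bp=4, max_unpaired=2))
            if m is None:
                continue
            innermost_i = m.pairs[-1][0]
            innermost_j = m.pairs[-1][1]
            assert innermost_j - innermost_i - 1 >= 3
            assert m.arm_a[1] <= m.arm_b[0]
            for (i1, j1), (i2, j2) in zip(m.pairs, m.pairs[1:]):
                assert i2 > i1 and j2 < j1
                assert (s[i2], s[j2]) in _WC

    @pytest.mark.parametrize("mode", ["intra", "guide"])
    def test_matches_recursive_oracle(self, mode):
        rng = random.Random(314 if mode == "intra" else 159)
        params = (HelixParams.intra_defaults() if mode == "intra"
                  else HelixParams.guide_defaults())
        relaxed = HelixParams(min_bp=5, max_unpaired=params.max_unpaired,
                              mode=params.mode)
        checked = 0
        for _ in range(120):
            n = rng.randint(40, 60)
            s = "".join(rng.choices("ACGT", weights=[3, 2, 2, 2], k=n))
            ws = None if mode == "intra" else max(0, n - 25)
            bp, g = oracle_best(s, params.max_unpaired, win_start=ws)
            m = find_helix(NS("u", s), params)
            if bp >= params.min_bp:
                assert m is not None, s
                assert (m.bp_count, m.unpaired_count) == (bp, g), s
            else:
                assert m is None, s
            # relaxed threshold exercises the optimum on nearly every input
            mr = find_helix(NS("u", s), relaxed)
            if bp >= 5:
                assert mr is not None and (mr.bp_count, mr.unpaired_count) == (bp, g), s
                checked += 1
            else:
                assert mr is None, s
        assert checked > 60

    def test_monotone_in_params(self, rng):
        for _ in range(40):
            s = "".join(rng.choices("ACGT", weights=[3, 2, 2, 3], k=70))
            base = has_qualifying_helix(NS("u", s), HelixParams(min_bp=9, max_unpaired=1))
            if base:
                assert has_qualifying_helix(NS("u", s), HelixParams(min_bp=8, max_unpaired=1))
                assert has_qualifying_helix(NS("u", s), HelixParams(min_bp=9, max_unpaired=2))


class TestSystemNull:
    def test_poly_a_null_zero(self):
        q = system_null_prob(NS("u", "A" * 100), HelixParams.guide_defaults(),
                             n_shuffles=30, seed=1)
        assert q == 0.0

    def test_alternating_gc_null_near_one(self):
        q = system_null_prob(NS("u", "GC" * 30), HelixParams.guide_defaults(),
                             n_shuffles=30, seed=2)
        assert q > 0.9

    def test_planted_duplex_in_skewed_background_null_low(self, rng):
        stem = "GCGACGCTGCAG"
        bg = "".join(rng.choices("ACGT", weights=[13, 2, 2, 3], k=60))
        up = bg[:15] + stem + bg[20:40] + reverse_complement(stem) + bg[45:]
        assert find_helix(NS("u", up), HelixParams.intra_defaults()) is not None
        q = system_null_prob(NS("u", up), HelixParams.intra_defaults(),
                             n_shuffles=100, seed=3)
        assert q < 0.2

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            system_null_prob(NS("u", "ACGT" * 20), HelixParams.guide_defaults(),
                             n_shuffles=5, seed=0)


class TestAggregation:
    def test_two_fair_systems(self):
        res = aggregate_enrichment([(True, 0.5), (True, 0.5)])
        assert res.aggregate_p == pytest.approx(0.25)
        assert res.expected == pytest.approx(1.0)

    def test_zero_observed_gives_one(self):
        res = aggregate_enrichment([(False, 0.1)] * 10)
        assert res.aggregate_p == 1.0

    def test_zero_null_floored(self):
        res = aggregate_enrichment([(True, 0.0), (False, 0.0)], prob_floor=1 / 101)
        assert min(res.null_probs) == pytest.approx(1 / 101)
        assert 0.0 < res.aggregate_p < 1.0

    def test_needs_two_systems(self):
        with pytest.raises(ValueError):
            aggregate_enrichment([(True, 0.5)])


class TestPairingProfile:
    def test_uniform_block(self):
        # every system's helix pairs guide positions 10-17 (1-based)
        matches = []
        ulen = 100
        win0 = ulen - 25
        for _ in range(6):
            pairs = tuple((5 + k, win0 + 16 - k) for k in range(8))
            from ecrmech.helix import HelixMatch
            matches.append(HelixMatch(pairs, 8, 0))
        prof = pairing_profile(matches, [ulen] * 6)
        for pos in range(25):
            if 9 <= pos <= 16:
                assert prof[pos] == 1.0
            else:
                assert prof[pos] == 0.0

    def test_no_helices_all_zero(self):
        assert pairing_profile([None] * 5, [100] * 5) == [0.0] * 25


class TestParameterScan:
    def test_single_cell_grid(self, make_seq):
        ups = [make_seq(60, id=f"u{i}", weights=[3, 2, 2, 3]) for i in range(6)]
        chosen, grid, _ = parameter_scan(ups, [8], [2], mode="guide",
                                         n_shuffles=25, seed=4)
        assert (chosen.min_bp, chosen.max_unpaired) == (8, 2)
        assert set(grid) == {(8, 2)}

    def test_planted_twelve_bp_cohort_selects_twelve(self, rng):
        ups = []
        for i in range(25):
            stem = "".join(rng.choices("GC", k=6)) + "".join(rng.choices("AT", k=6))
            bg = "".join(rng.choices("ACGT", weights=[13, 2, 2, 3], k=70))
            ups.append(NS(f"u{i}", bg[:20] + stem + bg[25:45]
                          + reverse_complement(stem) + bg[50:]))
        chosen, grid, selected = parameter_scan(
            ups, range(8, 14), range(0, 3), mode="intra", n_shuffles=25, seed=5)
        assert selected
        assert chosen.min_bp >= 12  # the planted geometry, or a tie broken larger

    def test_pure_null_cohort_selects_nothing(self, rng):
        ups = [NS(f"u{i}", "".join(rng.choices("ACGT", weights=[13, 2, 2, 3], k=70)))
               for i in range(25)]
        _, grid, selected = parameter_scan(ups, range(10, 13), range(0, 2),
                                           mode="intra", n_shuffles=25, seed=6)
        assert not selected
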