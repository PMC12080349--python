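"""Helix detection in upstream regions and shuffle-null enrichment testing.

A qualifying helix is a mismatch-free antiparallel duplex between two
disjoint arms of the upstream region: at least ``min_bp`` Watson–Crick
pairs (G·U optionally allowed) interrupted by at most ``max_unpaired``
bulged/internal-loop nucleotides in total, with the two arms separated by
at least ``min_loop`` nt.  Two search modes mirror the two statistics of
the analysis:

- ``intra``: any helix within the upstream region (default 12 bp / 3
  unpaired);
- ``guide``: the 3' arm must overlap the 25-nt guide window immediately
  upstream of the extra repeat — the putative ecrRNA spacer (default
  8 bp / 2 unpaired).

Per-system significance comes from dinucleotide-shuffled nulls, and
cohort-level enrichment aggregates per-system helix presence through an
exact Poisson-binomial upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .seqcore import NucleotideSequence, child_seed, dinucleotide_shuffle
from .stats import poisson_binomial_tail

__all__ = [
    "HelixParams",
    "HelixMatch",
    "EnrichmentResult",
    "find_helix",
    "has_qualifying_helix",
    "system_null_prob",
    "system_null_profile",
    "aggregate_enrichment",
    "pairing_profile",
    "parameter_scan",
    "GUIDE_WINDOW_LEN",
]

GUIDE_WINDOW_LEN = 25

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class HelixParams:
    min_bp: int = 12
    max_unpaired: int = 3
    mode: str = "intra"  # or "guide"
    allow_GU: bool = False
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.min_bp < 4:
            raise ValueError("min_bp must be >= 4")
        if self.max_unpaired < 0:
            raise ValueError("max_unpaired must be >= 0")
        if self.mode not in ("intra", "guide"):
            raise ValueError(f"mode must be intra or guide, got {self.mode!r}")

    @classmethod
    def intra_defaults(cls) -> "HelixParams":
        return cls(min_bp=12, max_unpaired=3, mode="intra")

    @classmethod
    def guide_defaults(cls) -> "HelixParams":
        return cls(min_bp=8, max_unpaired=2, mode="guide")


@dataclass(frozen=True)
class HelixMatch:
    pairs: tuple[tuple[int, int], ...]  # (i, j) paired positions, i < j, 0-based
    bp_count: int
    unpaired_count: int

    @property
    def arm_a(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0] + 1)

    @property
    def arm_b(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1] + 1)


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    params: HelixParams
    n_systems: int
    n_with_helix: int
    null_probs: tuple[float, ...]
    expected: float
    aggregate_p: float
    profile: tuple[float, ...] = ()


_CODE_TABLE = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
_PAIR_WC = np.zeros((5, 5), dtype=np.uint8)
_PAIR_GU = np.zeros((5, 5), dtype=np.uint8)
for _x, _y in _WC:
    _PAIR_WC["ACGT".index(_x), "ACGT".index(_y)] = 1
    _PAIR_GU["ACGT".index(_x), "ACGT".index(_y)] = 1
for _x, _y in _GU:
    _PAIR_GU["ACGT".index(_x), "ACGT".index(_y)] = 1


def _comp_matrix(s: str, allow_GU: bool) -> np.ndarray:
    codes = np.frombuffer(s.encode("ascii").translate(_CODE_TABLE), dtype=np.uint8)
    table = _PAIR_GU if allow_GU else _PAIR_WC
    return np.ascontiguousarray(table[codes[:, None], codes[None, :]])


def _window(seq_len: int, p: HelixParams, guide_window: tuple[int, int] | None):
    if p.mode != "guide":
        return 0, 0, 0
    if guide_window is None:
        end = seq_len
        start = max(0, seq_len - GUIDE_WINDOW_LEN)
    else:
        start, end = guide_window
    return start, end, 1


def find_helix(upstream: NucleotideSequence, p: HelixParams,
               guide_window: tuple[int, int] | None = None) -> HelixMatch | None:
    """Best qualifying helix, or None.

    Maximizes base-pair count, then minimizes unpaired nucleotides; the
    remaining tie is broken by the 5'-most innermost pair.  In guide mode
    ``guide_window`` defaults to the last 25 nt of the sequence.
    """
    s = upstream.residues
    n = len(s)
    if n < 2 * p.min_bp + p.min_loop:
        return None
    comp = _comp_matrix(s, p.allow_GU)
    ws, we, need = _window(n, p, guide_window)
    best_bp, best_g, _, dp = K.helix_best(comp, n, p.max_unpaired, p.min_loop,
                                          p.min_bp, ws, we, need)
    if best_bp < p.min_bp:
        return None
    return _traceback(dp, comp, s, best_bp, best_g, p, ws, we, need)


def has_qualifying_helix(upstream: NucleotideSequence, p: HelixParams,
                         guide_window: tuple[int, int] | None = None) -> bool:
    s = upstream.residues
    n = len(s)
    if n < 2 * p.min_bp + p.min_loop:
        return False
    comp = _comp_matrix(s, p.allow_GU)
    ws, we, need = _window(n, p, guide_window)
    return bool(K.helix_exists(comp, n, p.max_unpaired, p.min_loop, p.min_bp, ws, we, need))


def _traceback(dp, comp, s, best_bp, best_g, p: HelixParams, ws, we, need) -> HelixMatch:
    n = len(s)
    T = dp.shape[3]
    t_req = 1 if need else 0
    # terminal (innermost) pair: first by ascending i, then descending j
    terminal = None
    for i in range(n):
        for j in range(n - 1, i + p.min_loop, -1):
            if comp[i, j] and dp[i, j, best_g, t_req] == best_bp:
                terminal = (i, j)
                break
        if terminal:
            break
    assert terminal is not None
    pairs = []
    i, j = terminal
    g, t = best_g, t_req
    while True:
        pairs.append((i, j))
        cur = dp[i, j, g, t]
        tj = 1 if (need and ws <= j < we) else 0
        if cur == 1 and g == 0 and (T == 1 or t == tj):
            break
        moved = False
        for da in range(0, g + 1):
            i2 = i - 1 - da
            if i2 < 0:
                break
            for db in range(0, g + 1 - da):
                j2 = j + 1 + db
                if j2 >= n or not comp[i2, j2]:
                    continue
                gprev = g - da - db
                if T == 1:
                    cand_ts = [0]
                elif tj == 1:
                    cand_ts = [1, 0] if t == 1 else []
                else:
                    cand_ts = [t]
                for t2 in cand_ts:
                    if dp[i2, j2, gprev, t2] == cur - 1:
                        i, j, g, t = i2, j2, gprev, t2
                        moved = True
                        break
                if moved:
                    break
            if moved:
                break
        if not moved:  # pragma: no cover - defensive
            break
    pairs.reverse()  # outermost (5'-most i) first
    unpaired = best_g
    return HelixMatch(tuple(pairs), len(pairs), unpaired)


def system_null_prob(upstream: NucleotideSequence, p: HelixParams,
                     n_shuffles: int = 100, seed: int = 0,
                     guide_window: tuple[int, int] | None = None) -> float:
    """Fraction of dinucleotide-shuffled upstreams containing a qualifying helix.

    The guide window is shuffled along with the rest of the region; its
    coordinates (relative to the sequence end) stay fixed.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles < 20 gives an unstable null estimate")
    hits = 0
    for r in range(n_shuffles):
        sh = dinucleotide_shuffle(upstream, child_seed(seed, "nullhx", r))
        if has_qualifying_helix(sh, p, guide_window):
            hits += 1
    return hits / n_shuffles


def system_null_profile(upstream: NucleotideSequence, p: HelixParams,
                        observed: HelixMatch, n_shuffles: int = 100, seed: int = 0,
                        guide_window: tuple[int, int] | None = None) -> tuple[float, float]:
    """(q_any, q_as_good) over dinucleotide-shuffled upstream regions.

    ``q_any`` is the fraction of shuffles containing any qualifying helix
    (the cohort-aggregation null); ``q_as_good`` the fraction whose best
    helix is at least as good as the observed configuration — more base
    pairs, or equally many with no more unpaired nucleotides.  The
    mechanism caller derives its occurrence probability from
    ``1 - q_as_good``.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles < 20 gives an unstable null estimate")
    s = upstream.residues
    n = len(s)
    ws, we, need = _window(n, p, guide_window)
    any_hits = 0
    good_hits = 0
    for r in range(n_shuffles):
        sh = dinucleotide_shuffle(upstream, child_seed(seed, "nullhx", r))
        comp = _comp_matrix(sh.residues, p.allow_GU)
        best_bp, best_g, _, _ = K.helix_best(comp, n, p.max_unpaired, p.min_loop,
                                             p.min_bp, ws, we, need)
        if best_bp >= p.min_bp:
            any_hits += 1
        if best_bp > observed.bp_count or (
                best_bp == observed.bp_count and best_g <= observed.unpaired_count):
            good_hits += 1
    return any_hits / n_shuffles, good_hits / n_shuffles


def aggregate_enrichment(per_system: list[tuple[bool, float]], label: str = "",
                         params: HelixParams | None = None,
                         prob_floor: float | None = None) -> EnrichmentResult:
    """Cohort enrichment of helix presence over per-system shuffle nulls.

    Under independence the number of helix-positive systems follows the
    Poisson-binomial distribution of the per-system null probabilities;
    the one-sided p-value is the exact upper tail at the observed count.
    Null probabilities of zero are floored (default 1/101, matching the
    default 100 shuffles) to avoid a degenerate zero-variance null.
    """
    if len(per_system) < 2:
        raise ValueError("enrichment needs at least 2 systems")
    if prob_floor is None:
        prob_floor = 1.0 / 101.0
    probs = [max(q, prob_floor) for _, q in per_system]
    x_obs = sum(1 for h, _ in per_system if h)
    p_val = poisson_binomial_tail(probs, x_obs)
    return EnrichmentResult(
        label=label, params=params or HelixParams.guide_defaults(),
        n_systems=len(per_system), n_with_helix=x_obs,
        null_probs=tuple(probs), expected=float(np.sum(probs)), aggregate_p=p_val)


def pairing_profile(matches: list[HelixMatch | None], upstream_lens: list[int],
                    window_len: int = GUIDE_WINDOW_LEN) -> list[float]:
    """Fraction of systems whose best helix pairs each guide-window position.

    Positions are reported 1..window_len in 5'->3' order over the window
    (position ``window_len`` abuts the extra repeat).  ``upstream_lens``
    gives each system's upstream length so window coordinates can be
    recovered; systems without a helix contribute zeros.
    """
    n = len(matches)
    counts = np.zeros(window_len)
    for m, ulen in zip(matches, upstream_lens):
        if m is None:
            continue
        win0 = ulen - window_len
        hit = set()
        for i, j in m.pairs:
            for pos in (i, j):
                off = pos - win0
                if 0 <= off < window_len:
                    hit.add(off)
        for off in hit:
            counts[off] += 1
    if n == 0:
        return [0.0] * window_len
    return list(counts / n)


def parameter_scan(upstreams: list[NucleotideSequence], k_range, m_range,
                   mode: str = "intra", n_shuffles: int = 50, seed: int = 0,
                   allow_GU: bool = False, alpha: float = 0.05):
    """Scan (min_bp, max_unpaired) over a training cohort.

    One DP per sequence (at the largest unpaired budget) yields helix
    presence for every grid cell; nulls are estimated the same way.  The
    cell minimizing the aggregate p wins, ties broken toward larger
    min_bp then smaller max_unpaired.  If no cell survives a Bonferroni
    correction over the grid, ``selected`` is False.

    Returns (chosen HelixParams, p-value grid dict, selected flag).
    """
    k_range = list(k_range)
    m_range = list(m_range)
    m_max = max(m_range)
    need = 1 if mode == "guide" else 0

    def presence_by_budget(seq: NucleotideSequence) -> np.ndarray:
        s = seq.residues
        comp = _comp_matrix(s, allow_GU)
        ws, we, _ = _window(len(s), HelixParams(min_bp=min(k_range), max_unpaired=m_max,
                                                mode=mode, allow_GU=allow_GU), None)
        _, _, maxbp, _ = K.helix_best(comp, len(s), m_max, 3, min(k_range), ws, we, need)
        return np.maximum.accumulate(maxbp)  # best bp at budget <= g

    obs = [presence_by_budget(u) for u in upstreams]
    null_counts = {(k, m): [] for k in k_range for m in m_range}
    for idx, u in enumerate(upstreams):
        per_budget_hits = np.zeros((n_shuffles, m_max + 1), dtype=np.int16)
        for r in range(n_shuffles):
            sh = dinucleotide_shuffle(u, child_seed(seed, "scan", u.id, r))
            per_budget_hits[r] = presence_by_budget(sh)
        for k in k_range:
            for m in m_range:
                frac = float(np.mean(per_budget_hits[:, m] >= k))
                null_counts[(k, m)].append(frac)

    grid: dict[tuple[int, int], float] = {}
    for k in k_range:
        for m in m_range:
            per_system = [
                (bool(obs[i][m] >= k), null_counts[(k, m)][i]) for i in range(len(upstreams))
            ]
            res = aggregate_enrichment(per_system, prob_floor=1.0 / (n_shuffles + 1))
            grid[(k, m)] = res.aggregate_p
    best_cell = min(grid, key=lambda km: (grid[km], -km[0], km[1]))
    selected = grid[best_cell] < alpha / len(grid)
    chosen = HelixParams(min_bp=best_cell[0], max_unpaired=best_cell[1],
                         mode=mode, allow_GU=allow_GU)
    return chosen, grid, selected
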