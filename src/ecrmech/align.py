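"""Pairwise alignment engines.

Two engines mirror the roles of the EMBOSS Needle and blastn steps of the
analysis: a global affine-gap aligner with separately priced terminal
gaps (for counting repeat mutations against the consensus) and a seeded
Smith–Waterman local aligner (for finding degraded repeat copies in the
upstream region).

Gap convention: a gap run of length L costs ``gap_open + L * gap_extend``.
In the global aligner, runs inside the leading block (before the first
aligned column) or the trailing block (after the last aligned column) are
priced with ``end_open + L * end_extend`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._kernels import M, X, Y, XL, YL, XT, YT
from .seqcore import GenomicInterval, NucleotideSequence

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "LocalHit",
    "global_align",
    "local_align",
    "best_local_score",
]

_CODE_TABLE = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii").translate(_CODE_TABLE), dtype=np.uint8)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for either engine.

    ``mode`` is "global" or "local".  ``end_open``/``end_extend`` apply to
    terminal gaps in global mode only; ``word_size`` seeds local hits (0
    disables seeding).
    """

    mode: str = "global"
    match: int = 5
    mismatch: int = -4
    gap_open: int = 10
    gap_extend: int = 4
    end_open: int = 10
    end_extend: int = 4
    word_size: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError(f"mode must be global or local, got {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend < 0 or self.end_open < 0 or self.end_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if self.word_size < 0:
            raise ValueError("word_size must be >= 0")

    @classmethod
    def needle_defaults(cls) -> "AlignmentParams":
        """Global parameters used for repeat-vs-consensus mutation counting."""
        return cls(mode="global", match=5, mismatch=-4, gap_open=10, gap_extend=4,
                   end_open=10, end_extend=4)

    @classmethod
    def blast_qc_defaults(cls) -> "AlignmentParams":
        """Local parameters used for the mutated-repeat rescue search."""
        return cls(mode="local", match=1, mismatch=-1, gap_open=2, gap_extend=1,
                   word_size=5)


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    mismatches: int = field(init=False)
    gap_columns: int = field(init=False)
    identity: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        mm = gc = mt = 0
        for a, b in zip(self.aligned_a, self.aligned_b):
            if a == "-" or b == "-":
                gc += 1
            elif a == b and a != "N":
                mt += 1
            else:
                mm += 1
        object.__setattr__(self, "mismatches", mm)
        object.__setattr__(self, "gap_columns", gc)
        object.__setattr__(self, "identity", mt / len(self.aligned_a) if self.aligned_a else 0.0)


@dataclass(frozen=True)
class LocalHit:
    """One local alignment of the query inside the subject."""

    interval: GenomicInterval          # span on the subject, 0-based half-open
    score: float
    identity: float                    # matches / alignment length
    aligned_query: str
    aligned_subject: str
    query_start: int
    query_end: int


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

_TOL = 1e-6

# traceback preference: substitution, then gap in a (Y states), then gap in b
_FINAL_PREF = (M, YT, YL, XT, XL)
_PRED_PREF = {
    M: (M, Y, YL, X, XL),
    X: (M, Y, X),
    Y: (M, Y, X),
    XL: (YL, XL),
    YL: (YL, XL),
    XT: (M, Y, YT, XT),
    YT: (M, YT, X, XT),
}


def global_align(a: NucleotideSequence, b: NucleotideSequence,
                 p: AlignmentParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of `a` against `b` under affine gap costs.

    Ties during traceback are broken deterministically: substitution is
    preferred over a gap in `a`, which is preferred over a gap in `b`.
    """
    p = p or AlignmentParams.needle_defaults()
    if p.mode != "global":
        raise ValueError("global_align requires mode='global' params")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot globally align an empty sequence")
    ca, cb = _codes(a.residues), _codes(b.residues)
    S = K.gotoh_endgap_fill(ca, cb, float(p.match), float(p.mismatch),
                            float(p.gap_open), float(p.gap_extend),
                            float(p.end_open), float(p.end_extend))
    n, m_len = len(a), len(b)
    final = max(S[n, m_len, st] for st in _FINAL_PREF)
    state = next(st for st in _FINAL_PREF if S[n, m_len, st] >= final - _TOL)

    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = n, m_len
    while i > 0 or j > 0:
        cur = S[i, j, state]
        if state == M:
            sub = p.match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else p.mismatch
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _pick_pred(S, i, j, cur - sub, _PRED_PREF[M])
        elif state in (X, XL, XT):
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            if i == 0 and j == 0:
                break
            state = _gap_pred(S, i, j, cur, state, p, gap_in_b=True)
        else:  # Y, YL, YT
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            if i == 0 and j == 0:
                break
            state = _gap_pred(S, i, j, cur, state, p, gap_in_b=False)
    return PairwiseAlignment("".join(reversed(cols_a)), "".join(reversed(cols_b)), final)


def _pick_pred(S, i, j, target, prefs):
    for st in prefs:
        if abs(S[i, j, st] - target) < _TOL:
            return st
    raise AssertionError("traceback failed: no predecessor matches score")


def _gap_pred(S, i, j, cur, state, p, gap_in_b):
    if state in (X, Y):
        open_cost, ext_cost = p.gap_open + p.gap_extend, p.gap_extend
    else:
        open_cost, ext_cost = p.end_open + p.end_extend, p.end_extend
    same = state  # continuing the run costs ext only
    for st in _PRED_PREF[state]:
        cost = ext_cost if st == same else open_cost
        if abs(S[i, j, st] - (cur + cost)) < _TOL:
            return st
    raise AssertionError("traceback failed in gap state")


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

def local_align(query: NucleotideSequence, subject: NucleotideSequence,
                p: AlignmentParams | None = None, min_score: float = 1.0,
                max_hits: int = 50) -> list[LocalHit]:
    """Maximal-scoring non-overlapping local alignments, best first.

    Hits are extracted greedily: the best-scoring alignment is reported,
    its subject span masked, and the flanks searched recursively.  With
    ``word_size`` > 0 only alignments containing a run of that many
    consecutive identical columns (an exact seed) are reported — the
    documented sensitivity trade-off of seeded search.
    """
    p = p or AlignmentParams.blast_qc_defaults()
    if p.mode != "local":
        raise ValueError("local_align requires mode='local' params")
    if len(query) == 0 or len(subject) == 0:
        raise ValueError("cannot locally align an empty sequence")
    hits: list[LocalHit] = []
    _local_recurse(query, subject.residues, 0, subject.id, p, min_score, hits, max_hits)
    hits.sort(key=lambda h: (-h.score, h.interval.start))
    return hits


def best_local_score(query: NucleotideSequence, subject: NucleotideSequence,
                     p: AlignmentParams | None = None) -> float:
    """Maximum Smith–Waterman score only (no traceback, no seed filter)."""
    p = p or AlignmentParams.blast_qc_defaults()
    H, _, _ = K.sw_fill(_codes(query.residues), _codes(subject.residues),
                        float(p.match), float(p.mismatch),
                        float(p.gap_open), float(p.gap_extend))
    return float(H.max())


def _local_recurse(query, subj_str, offset, subj_id, p, min_score, hits, max_hits):
    if len(hits) >= max_hits or len(subj_str) == 0:
        return
    ca, cb = _codes(query.residues), _codes(subj_str)
    H, E, F = K.sw_fill(ca, cb, float(p.match), float(p.mismatch),
                        float(p.gap_open), float(p.gap_extend))
    score = float(H.max())
    if score < min_score:
        return
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    qa, qb, i0, j0 = _local_traceback(query.residues, subj_str, H, E, F, int(i), int(j), p)
    j1 = int(j)
    seeded = p.word_size == 0 or _has_seed(qa, qb, p.word_size)
    if seeded:
        matches = sum(1 for x, y in zip(qa, qb) if x == y and x != "-")
        hits.append(LocalHit(
            interval=GenomicInterval(subj_id, offset + j0, offset + j1),
            score=score, identity=matches / len(qa),
            aligned_query=qa, aligned_subject=qb,
            query_start=i0, query_end=int(i)))
    # mask the span and search the flanks either way (avoids re-finding it)
    _local_recurse(query, subj_str[:j0], offset, subj_id, p, min_score, hits, max_hits)
    _local_recurse(query, subj_str[j1:], offset + j1, subj_id, p, min_score, hits, max_hits)


def _local_traceback(qs, ss, H, E, F, i, j, p):
    cols_q: list[str] = []
    cols_s: list[str] = []
    state = "H"
    openc, extc = p.gap_open + p.gap_extend, p.gap_extend
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] <= 0:
                break
            sub = p.match if (qs[i - 1] == ss[j - 1] and qs[i - 1] != "N") else p.mismatch
            cols_q.append(qs[i - 1])
            cols_s.append(ss[j - 1])
            prev = H[i, j] - sub
            i, j = i - 1, j - 1
            if prev < _TOL:
                break  # alignment starts here (prefer the shortest)
            if abs(H[i, j] - prev) < _TOL:
                state = "H"
            elif abs(E[i, j] - prev) < _TOL:
                state = "E"
            elif abs(F[i, j] - prev) < _TOL:
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":  # gap in subject, consumes query
            cols_q.append(qs[i - 1])
            cols_s.append("-")
            cur = E[i, j]
            i -= 1
            if abs(E[i, j] - (cur + extc)) < _TOL:
                state = "E"
            else:
                state = "H"
        else:  # F: gap in query, consumes subject
            cols_q.append("-")
            cols_s.append(ss[j - 1])
            cur = F[i, j]
            j -= 1
            if abs(F[i, j] - (cur + extc)) < _TOL:
                state = "F"
            else:
                state = "H"
    return "".join(reversed(cols_q)), "".join(reversed(cols_s)), i, j


def _has_seed(qa: str, qb: str, w: int) -> bool:
    run = 0
    for x, y in zip(qa, qb):
        if x == y and x != "-" and x != "N":
            run += 1
            if run >= w:
                return True
        else:
            run = 0
    return False
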