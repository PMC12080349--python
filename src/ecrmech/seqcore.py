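"""Core sequence types and sequence-level primitives.

Everything downstream of I/O works on :class:`NucleotideSequence` (DNA
alphabet internally; RNA input is mapped U->T) and 0-based half-open
:class:`GenomicInterval` coordinates.  The module also houses the exact
dinucleotide shuffle used to build composition-matched null sequences,
greedy identity clustering (CD-HIT-style dereplication), and consensus
building over a CRISPR array's repeats.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "NucleotideSequence",
    "GenomicInterval",
    "reverse_complement",
    "dinucleotide_shuffle",
    "dinucleotide_counts",
    "greedy_identity_cluster",
    "consensus_repeat",
    "child_seed",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _normalize(residues: str) -> str:
    s = residues.upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide residues {sorted(bad)!r} in sequence")
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T,N}.

    Lower-case and RNA (U) input are accepted and normalised on
    construction.  Sequences entering an alignment or a shuffle must be
    non-empty; emptiness is checked at the point of use.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def reverse_complement(self, new_id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(new_id or self.id, reverse_complement(self.residues))

    def subseq(self, start: int, end: int, new_id: str | None = None) -> "NucleotideSequence":
        if not (0 <= start <= end <= len(self.residues)):
            raise ValueError(f"subseq [{start},{end}) out of range for length {len(self.residues)}")
        return NucleotideSequence(new_id or f"{self.id}:{start}-{end}", self.residues[start:end])


def reverse_complement(s: str) -> str:
    return s.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.contig, self.start + offset, self.end + offset, self.strand)


def child_seed(master: int, *tokens) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and tokens.

    Used so that per-locus / per-stage randomness is independent of
    processing order while still flowing from a single user seed.
    """
    h = 0x811C9DC5
    for part in (master, *tokens):
        for ch in str(part):
            h = ((h ^ ord(ch)) * 0x01000193) & 0xFFFFFFFF
    return h % (2**31 - 1)


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul–Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_counts(s: str) -> Counter:
    return Counter(s[i : i + 2] for i in range(len(s) - 1))


def dinucleotide_shuffle(seq: NucleotideSequence, seed: int) -> NucleotideSequence:
    """Shuffle preserving the exact dinucleotide count multiset.

    Altschul–Erickson construction: treat residues as vertices of a
    multigraph whose edges are the observed dinucleotides, draw a random
    last-edge assignment that keeps the graph's Eulerian path ending at
    the original terminal residue, permute the remaining out-edges, and
    walk the path.  The first and last residues of the output equal those
    of the input, and every one of the 16 dinucleotide counts is
    preserved exactly.
    """
    s = seq.residues
    if len(s) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    rng = random.Random(seed)
    first, last = s[0], s[-1]

    edges: dict[str, list[str]] = {}
    for i in range(len(s) - 1):
        edges.setdefault(s[i], []).append(s[i + 1])

    vertices = list(edges.keys())
    if len(vertices) == 1 and len(set(edges[vertices[0]])) == 1:
        return NucleotideSequence(f"{seq.id}|shuf", s)  # homopolymer: unique arrangement

    # pick random last edges such that following them from any vertex reaches `last`
    non_terminal = [v for v in vertices if v != last]
    while True:
        last_edge = {v: rng.choice(edges[v]) for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen = set()
            u = v
            while u != last and u in last_edge and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break

    out: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        out[v] = rest

    walk = [first]
    pos = {v: 0 for v in vertices}
    u = first
    for _ in range(len(s) - 1):
        nxt = out[u][pos[u]]
        pos[u] += 1
        walk.append(nxt)
        u = nxt
    return NucleotideSequence(f"{seq.id}|shuf", "".join(walk))


# ---------------------------------------------------------------------------
# Clustering and consensus
# ---------------------------------------------------------------------------

def greedy_identity_cluster(
    seqs: list[NucleotideSequence], threshold: float
) -> tuple[list[NucleotideSequence], dict[str, str]]:
    """Greedy longest-first clustering at a global-identity threshold.

    Identity follows the CD-HIT convention: matching columns of a global
    alignment divided by the length of the shorter sequence.  Returns the
    representatives (first/longest member of each cluster) and a map from
    every input id to its representative's id.
    """
    from .align import AlignmentParams, global_align  # local import: avoid cycle

    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: list[NucleotideSequence] = []
    assignment: dict[str, str] = {}
    params = AlignmentParams.needle_defaults()
    for i in order:
        s = seqs[i]
        placed = False
        for rep in reps:
            if threshold == 1.0:
                ident = 1.0 if s.residues == rep.residues else 0.0
            else:
                aln = global_align(s, rep, params)
                matches = sum(
                    1 for a, b in zip(aln.aligned_a, aln.aligned_b) if a == b and a != "-"
                )
                ident = matches / min(len(s), len(rep))
            if ident >= threshold:
                assignment[s.id] = rep.id
                placed = True
                break
        if not placed:
            reps.append(s)
            assignment[s.id] = s.id
    return reps, assignment


def consensus_repeat(repeats: list[NucleotideSequence]) -> NucleotideSequence:
    """Column-majority consensus over a star alignment of the repeats.

    The anchor is the most frequent exact repeat sequence (ties broken
    alphabetically); every repeat is globally aligned to the anchor and
    votes per anchor column.  Columns whose majority vote is a gap are
    dropped; residue ties are broken alphabetically.
    """
    from .align import AlignmentParams, global_align

    if not repeats:
        raise ValueError("consensus requires at least one repeat")
    freq = Counter(r.residues for r in repeats)
    top = max(freq.values())
    anchor_str = min(s for s, c in freq.items() if c == top)
    if len(freq) == 1:
        return NucleotideSequence("consensus", anchor_str)

    anchor = NucleotideSequence("anchor", anchor_str)
    params = AlignmentParams.needle_defaults()
    votes: list[Counter] = [Counter() for _ in range(len(anchor_str))]
    for r in repeats:
        if r.residues == anchor_str:
            for i, ch in enumerate(anchor_str):
                votes[i][ch] += 1
            continue
        aln = global_align(r, anchor, params)
        col = 0
        for a, b in zip(aln.aligned_a, aln.aligned_b):
            if b == "-":
                continue  # insertion relative to anchor: no anchor column
            votes[col][a] += 1  # a may be '-' (deletion in this repeat)
            col += 1
    out = []
    for counter in votes:
        best = max(counter.values())
        winners = sorted(ch for ch, c in counter.items() if c == best)
        residue_winners = [w for w in winners if w != "-"]
        if not residue_winners:  # strict gap majority: drop the column
            continue
        # residue beats a tying gap; residue ties break alphabetically
        out.append(residue_winners[0])
    return NucleotideSequence("consensus", "".join(out))
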