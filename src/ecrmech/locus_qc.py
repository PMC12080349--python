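"""Locus model and stage-1 quality control.

A :class:`CrisprLocus` is normalised to transcription orientation on
construction: repeat 1 is the first repeat in transcription order (the
extra repeat — in II-C also the oldest), and all coordinates refer to the
oriented contig.  QC then (a) delimits the upstream intergenic region
(<= 180 nt, shortened by the nearest upstream gene, discarded below
30 nt) and (b) rescues mutated repeat copies hidden in that region using
a seeded local search gated by an empirical shuffle e-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import AlignmentParams, LocalHit, best_local_score, local_align
from .seqcore import GenomicInterval, NucleotideSequence, child_seed, dinucleotide_shuffle

__all__ = [
    "CrisprLocus",
    "RescueCandidate",
    "rescue_mutated_repeat",
    "trim_upstream",
    "UPSTREAM_CAP",
    "UPSTREAM_MIN",
]

UPSTREAM_CAP = 180
UPSTREAM_MIN = 30
GUIDE_LEN = 25


@dataclass
class CrisprLocus:
    """One CRISPR-Cas locus in transcription orientation.

    ``repeats``/``spacers`` are intervals on the *oriented* contig;
    ``source_strand`` records the original annotation strand.  The
    invariant |repeats| = |spacers| + 1 always holds.
    """

    id: str
    subtype: str
    contig: NucleotideSequence
    source_strand: str
    repeats: list[GenomicInterval]
    spacers: list[GenomicInterval]
    consensus: NucleotideSequence | None = None
    upstream: NucleotideSequence | None = None
    upstream_start: int | None = None  # oriented-contig coordinate of upstream[0]
    tracrRNA: NucleotideSequence | None = None
    qc_action: str = "pending"
    rejected: bool = False
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if len(self.repeats) != len(self.spacers) + 1:
            raise ValueError(
                f"{self.id}: {len(self.repeats)} repeats require "
                f"{len(self.repeats) - 1} spacers, got {len(self.spacers)}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_annotation(cls, id: str, subtype: str, contig: NucleotideSequence,
                        strand: str, repeat_intervals: list[tuple[int, int]],
                        tracrRNA: NucleotideSequence | None = None) -> "CrisprLocus":
        """Build a locus from plus-strand annotation coordinates.

        ``repeat_intervals`` are 0-based half-open on the given contig; for
        a minus-strand locus the contig is reverse-complemented and all
        coordinates flipped so that downstream code sees transcription
        order.
        """
        L = len(contig)
        if strand == "-":
            oriented = contig.reverse_complement()
            ivs = sorted((L - e, L - s) for s, e in repeat_intervals)
        else:
            oriented = contig
            ivs = sorted(repeat_intervals)
        reps = [GenomicInterval(contig.id, s, e) for s, e in ivs]
        spacers = [GenomicInterval(contig.id, reps[i].end, reps[i + 1].start)
                   for i in range(len(reps) - 1)]
        return cls(id=id, subtype=subtype, contig=oriented, source_strand=strand,
                   repeats=reps, spacers=spacers, tracrRNA=tracrRNA)

    def map_interval(self, iv: GenomicInterval) -> GenomicInterval:
        """Map an original-coordinate interval into the oriented frame."""
        if self.source_strand == "+":
            return iv
        L = len(self.contig)
        flip = {"+": "-", "-": "+"}
        return GenomicInterval(iv.contig, L - iv.end, L - iv.start, flip[iv.strand])

    # -- accessors ----------------------------------------------------------

    def repeat_seq(self, index: int) -> NucleotideSequence:
        iv = self.repeats[index]
        return self.contig.subseq(iv.start, iv.end, f"{self.id}|repeat{index + 1}")

    def extra_repeat_seq(self) -> NucleotideSequence:
        return self.repeat_seq(0)

    def compute_consensus(self) -> NucleotideSequence:
        """Array-internal consensus: majority over the non-extra repeats
        when at least 3 exist, else over all repeats."""
        from .seqcore import consensus_repeat

        seqs = [self.repeat_seq(i) for i in range(len(self.repeats))]
        pool = seqs[1:] if len(seqs) - 1 >= 3 else seqs
        cons = consensus_repeat(pool)
        return NucleotideSequence(f"{self.id}|consensus", cons.residues)

    @property
    def guide_window(self) -> tuple[int, int] | None:
        """Coordinates (on the upstream sequence) of the putative ecrRNA guide:
        the last min(25, |upstream|) nt before the extra repeat."""
        if self.upstream is None:
            return None
        n = len(self.upstream)
        return (max(0, n - GUIDE_LEN), n)


@dataclass(frozen=True)
class RescueCandidate:
    hit: LocalHit                  # on upstream coordinates
    score: float
    identity: float
    implied_spacer_len: int
    empirical_e: float | None = None
    accepted: bool = False

    @property
    def e_label(self) -> str:
        if self.empirical_e is None:
            return "NA"
        return "<1/n_shuffles" if self.empirical_e == 0.0 else f"{self.empirical_e:g}"


def trim_upstream(locus: CrisprLocus, genes: list[GenomicInterval],
                  cap: int = UPSTREAM_CAP, min_len: int = UPSTREAM_MIN) -> CrisprLocus:
    """Delimit the upstream intergenic region before repeat 1.

    The region extends min(cap, distance to the nearest upstream gene
    boundary on either strand) nt before repeat 1, clipped at the contig
    edge; the locus is flagged rejected when fewer than ``min_len`` nt
    remain.  ``genes`` are given in original annotation coordinates.
    """
    r1 = locus.repeats[0].start
    nearest_end = 0
    for g in genes:
        if g.contig != locus.repeats[0].contig:
            continue
        og = locus.map_interval(g)
        if og.end <= r1:
            nearest_end = max(nearest_end, og.end)
    length = min(cap, r1 - nearest_end)
    start = r1 - length
    out = replace(locus)
    if length < min_len:
        out.rejected = True
        out.reject_reason = f"upstream region {length} nt < {min_len} nt"
        out.qc_action = "discarded"
        out.upstream = None
        out.upstream_start = None
        return out
    out.upstream = locus.contig.subseq(start, r1, f"{locus.id}|upstream")
    out.upstream_start = start
    out.qc_action = "trimmed" if length < cap else "kept"
    return out


def rescue_mutated_repeat(
    locus: CrisprLocus,
    n_shuffles: int = 1000,
    seed: int = 0,
    params: AlignmentParams | None = None,
    spacer_range: tuple[int, int] = (20, 45),
    min_identity: float = 0.70,
    score_floor: float = 10.0,
    e_threshold: float = 0.01,
) -> tuple[CrisprLocus, RescueCandidate | None]:
    """One iteration of mutated-repeat rescue in the upstream region.

    The consensus repeat is searched against the upstream region with the
    seeded local aligner.  A hit is a candidate iff the implied spacer
    (gap between hit 3' end and repeat 1) is 20-45 nt, identity exceeds
    70%, and the raw score clears the floor.  Its empirical e-value is
    the fraction of dinucleotide-shuffled upstream regions containing any
    hit with a strictly better score; below ``e_threshold`` the candidate
    becomes the new repeat 1 (the intervening sequence a spacer) and the
    upstream region is re-extracted.  At most one rescue per call.
    """
    if locus.consensus is None:
        raise ValueError(f"{locus.id}: rescue requires a consensus repeat")
    if locus.upstream is None or locus.upstream_start is None:
        raise ValueError(f"{locus.id}: rescue requires a delimited upstream region")
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    params = params or AlignmentParams.blast_qc_defaults()
    up = locus.upstream
    hits = local_align(locus.consensus, up, params, min_score=score_floor)
    lo, hi = spacer_range
    cands = []
    for h in hits:
        implied = len(up) - h.interval.end
        if lo <= implied <= hi and h.identity > min_identity:
            cands.append((h, implied))
    if not cands:
        return locus, None
    cands.sort(key=lambda t: (-t[0].score, t[1], t[0].interval.start))
    hit, implied = cands[0]

    exceed = 0
    for r in range(n_shuffles):
        sh = dinucleotide_shuffle(up, child_seed(seed, locus.id, "rescue", r))
        if best_local_score(locus.consensus, sh, params) > hit.score:
            if local_align(locus.consensus, sh, params, min_score=hit.score + 1):
                exceed += 1
    emp_e = exceed / n_shuffles
    cand = RescueCandidate(hit=hit, score=hit.score, identity=hit.identity,
                           implied_spacer_len=implied, empirical_e=emp_e,
                           accepted=emp_e < e_threshold)
    if not cand.accepted:
        return locus, cand

    u0 = locus.upstream_start
    new_rep = GenomicInterval(locus.repeats[0].contig,
                              u0 + hit.interval.start, u0 + hit.interval.end)
    new_spacer = GenomicInterval(locus.repeats[0].contig,
                                 new_rep.end, locus.repeats[0].start)
    out = replace(locus)
    out.repeats = [new_rep] + list(locus.repeats)
    out.spacers = [new_spacer] + list(locus.spacers)
    # re-extract the upstream region before the new repeat 1, never extending
    # past the previously validated (gene-checked) boundary
    out.upstream = locus.contig.subseq(u0, new_rep.start, f"{locus.id}|upstream")
    out.upstream_start = u0
    out.qc_action = "rescued"
    if len(out.upstream) < UPSTREAM_MIN:
        out.rejected = True
        out.reject_reason = f"upstream region {len(out.upstream)} nt < {UPSTREAM_MIN} nt after rescue"
    return out, cand
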