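"""Rho-independent (intrinsic) terminator calling and intergenic enrichment.

A Rho-independent terminator (RIT) is modelled as its canonical anatomy: a
stem-loop (hairpin) immediately followed by a poly-U tract that releases
RNA polymerase.  The native detector is a geometric heuristic — it makes
no attempt to reproduce covariance-model bit scores — and an import
adapter accepts externally produced terminator calls so a dedicated
predictor can be slotted in.  The downstream statistic (Table-1-style
observed vs expected intergenic RIT ratio) only consumes presence calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import GenomicInterval, NucleotideSequence, reverse_complement

__all__ = [
    "TerminatorConfig",
    "TerminatorCall",
    "RitRatioReport",
    "call_terminators",
    "enumerate_intergenic",
    "rit_ratio_report",
    "read_terminator_gff",
]

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class TerminatorConfig:
    """Detector geometry and thresholds (calibrated once, then frozen).

    stem_min consecutive pairs (WC plus G·U); one internal mismatch is
    tolerated only in stems of stem_min+2 or longer; loop 3-10 nt; the 3'
    side of the stem must be followed within ``tail_gap_max`` nt by a
    ``tail_window``-nt window containing at least ``u_min`` T residues.
    """

    stem_min: int = 8
    stem_max: int = 18
    loop_min: int = 3
    loop_max: int = 10
    u_min: int = 6
    tail_window: int = 8
    tail_gap_max: int = 3
    gc_bonus: float = 1.0


@dataclass(frozen=True)
class TerminatorCall:
    interval: GenomicInterval  # hairpin start .. end of U-tract window, half-open
    stem_bp: int
    loop_len: int
    u_count: int
    score: float
    source: str = "native"  # or "imported"


@dataclass(frozen=True)
class RitRatioReport:
    label: str
    avg_intergenic_len: float
    observed_rits: int
    systems_analyzed: int
    observed_ratio: float
    expected_ratio: float


def _stem_pairs(s: str, start: int, stem: int, loop: int) -> tuple[int, int] | None:
    """Validate a candidate stem; returns (paired count, GC pairs) or None."""
    mism = 0
    gc = 0
    for k in range(stem):
        x = s[start + k]
        y = s[start + 2 * stem + loop - 1 - k]
        if (x, y) in _PAIRS:
            if {x, y} == {"G", "C"}:
                gc += 1
        else:
            mism += 1
            if mism > 1 or k == 0 or k == stem - 1:
                return None  # terminal pairs must close the stem
    return stem - mism, gc


def call_terminators(seq: NucleotideSequence, config: TerminatorConfig | None = None,
                     min_len: int = 30) -> list[TerminatorCall]:
    """Scan one strand of `seq` for hairpin + U-tract terminators.

    Overlapping candidates are merged, keeping the highest score
    (score = paired stem positions + GC-pair bonus + U-tract T count).
    """
    cfg = config or TerminatorConfig()
    s = seq.residues
    n = len(s)
    if n < min_len:
        return []
    candidates: list[TerminatorCall] = []
    for stem in range(cfg.stem_min, cfg.stem_max + 1):
        for loop in range(cfg.loop_min, cfg.loop_max + 1):
            span = 2 * stem + loop
            for start in range(0, n - span + 1):
                res = _stem_pairs(s, start, stem, loop)
                if res is None:
                    continue
                paired, gc = res
                if paired < cfg.stem_min:
                    continue
                if paired < stem and stem < cfg.stem_min + 2:
                    continue  # mismatch only tolerated in longer stems
                tail_at = None
                u_count = 0
                for gap in range(cfg.tail_gap_max + 1):
                    w0 = start + span + gap
                    w1 = w0 + cfg.tail_window
                    if w1 > n:
                        break
                    ts = s[w0:w1].count("T")
                    if ts >= cfg.u_min and ts > u_count:
                        u_count = ts
                        tail_at = (w0, w1)
                if tail_at is None:
                    continue
                score = paired + cfg.gc_bonus * gc + u_count
                candidates.append(TerminatorCall(
                    interval=GenomicInterval(seq.id, start, tail_at[1]),
                    stem_bp=paired, loop_len=loop, u_count=u_count, score=score))
    return _merge_overlapping(candidates)


def _merge_overlapping(calls: list[TerminatorCall]) -> list[TerminatorCall]:
    calls = sorted(calls, key=lambda c: (-c.score, c.interval.start, c.interval.end))
    kept: list[TerminatorCall] = []
    for c in calls:
        if not any(c.interval.overlaps(k.interval) for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.interval.start)
    return kept


def has_terminator(seq: NucleotideSequence, config: TerminatorConfig | None = None,
                   both_strands: bool = False) -> bool:
    if call_terminators(seq, config):
        return True
    if both_strands:
        rc = NucleotideSequence(seq.id + "|rc", reverse_complement(seq.residues))
        return bool(call_terminators(rc, config))
    return False


def enumerate_intergenic(genes: list[GenomicInterval], contig: str,
                         contig_len: int, min_len: int = 30) -> list[GenomicInterval]:
    """Complement of the merged gene spans, keeping regions longer than min_len.

    Contig-end gaps count as intergenic.  Overlapping genes are merged
    before complementing, so gene spans and returned regions tile the
    contig exactly (up to the length filter).
    """
    spans = sorted((g.start, g.end) for g in genes if g.contig == contig)
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out: list[GenomicInterval] = []
    prev = 0
    for a, b in merged + [[contig_len, contig_len]]:
        if a - prev > min_len:
            out.append(GenomicInterval(contig, prev, a))
        prev = max(prev, b)
    return out


def rit_ratio_report(
    upstream_has_rit: list[bool],
    per_genome_intergenic_fracs: list[float],
    avg_intergenic_len: float = 0.0,
    label: str = "",
) -> RitRatioReport:
    """Observed vs expected RIT ratio, Table-1 style.

    observed_ratio = loci with an upstream call / loci; expected_ratio =
    mean over genomes of the fraction of >30-nt intergenic regions
    containing a call (region-level presence, so the ratio stays <= 1).
    Genomes contributing no intergenic regions must be excluded upstream.
    """
    n = len(upstream_has_rit)
    observed = sum(upstream_has_rit)
    expected = (sum(per_genome_intergenic_fracs) / len(per_genome_intergenic_fracs)
                if per_genome_intergenic_fracs else 0.0)
    return RitRatioReport(
        label=label, avg_intergenic_len=avg_intergenic_len,
        observed_rits=observed, systems_analyzed=n,
        observed_ratio=observed / n if n else 0.0,
        expected_ratio=expected)


def read_terminator_gff(path) -> list[TerminatorCall]:
    """Import adapter: GFF3-like terminator lines (seqid, start, end, strand, score).

    Coordinates in the file are 1-based inclusive; calls are returned in
    internal 0-based half-open convention with source="imported".
    """
    calls: list[TerminatorCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                continue
            score = 0.0 if f[5] in (".", "") else float(f[5])
            calls.append(TerminatorCall(
                interval=GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]),
                stem_bp=0, loop_len=0, u_count=0, score=score, source="imported"))
    return calls
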