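"""Stage 2: mutation burden of extra vs non-extra repeats.

Arrays are dereplicated on the exact concatenation of their repeat
sequences, length-outlier repeats (>= 2 nt away from the consensus
length) are excluded from counting, and every remaining repeat is
pairwise-aligned to the array consensus; gap and mismatch columns both
count as mutations.  Positions are reported 1-based on the consensus,
5'->3' in transcription orientation, so "the first 15 nt" is the region
that base-pairs the tracrRNA anti-repeat after RNase III processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentParams, global_align
from .locus_qc import CrisprLocus
from .seqcore import NucleotideSequence

__all__ = [
    "RepeatMutationRecord",
    "MutationSummary",
    "dereplicate_arrays",
    "filter_length_outliers",
    "count_mutations",
    "mutation_summary",
]


@dataclass(frozen=True)
class RepeatMutationRecord:
    locus_id: str
    repeat_index: int          # 1-based; 1 = extra repeat (first in transcription order)
    is_focus: bool
    mutations: int
    positions: tuple[int, ...]  # 1-based consensus positions


@dataclass(frozen=True)
class MutationSummary:
    label: str
    n_arrays: int
    n_repeats: int
    focus_frac_mutated: float
    nonfocus_frac_mutated: float
    focus_hist: dict            # keys "0","1","2","3+"
    nonfocus_hist: dict
    focus_positions: dict       # 1-based consensus position -> count
    nonfocus_positions: dict
    records: tuple[RepeatMutationRecord, ...] = ()


def dereplicate_arrays(loci: list[CrisprLocus]) -> list[CrisprLocus]:
    """Drop loci whose concatenated repeat string duplicates an earlier one."""
    seen: set[str] = set()
    out = []
    for loc in loci:
        key = "".join(loc.repeat_seq(i).residues for i in range(len(loc.repeats)))
        if key in seen:
            continue
        seen.add(key)
        out.append(loc)
    return out


def filter_length_outliers(locus: CrisprLocus,
                           consensus: NucleotideSequence | None = None) -> list[int]:
    """Indices (0-based) of repeats within 1 nt of the consensus length.

    Repeats differing by two or more nucleotides in length are excluded
    from mutation counting but stay part of the locus.
    """
    cons = consensus or locus.consensus or locus.compute_consensus()
    keep = []
    for i in range(len(locus.repeats)):
        if abs(len(locus.repeats[i]) - len(cons)) < 2:
            keep.append(i)
    return keep


def count_mutations(repeat: NucleotideSequence, consensus: NucleotideSequence,
                    params: AlignmentParams | None = None,
                    gap_run_as_one: bool = False,
                    locus_id: str = "", repeat_index: int = 1,
                    is_focus: bool = False) -> RepeatMutationRecord:
    """Mutations of one repeat relative to the consensus.

    Mismatch columns and gap columns of the global alignment each count
    as one mutation (``gap_run_as_one`` collapses a contiguous gap run to
    a single event instead).  A gap column is assigned the nearest 5'
    consensus position.
    """
    params = params or AlignmentParams.needle_defaults()
    aln = global_align(repeat, consensus, params)
    positions: list[int] = []
    cons_pos = 0
    prev_gap = False
    for a, c in zip(aln.aligned_a, aln.aligned_b):
        if c != "-":
            cons_pos += 1
        if a == "-" or c == "-":
            if not (gap_run_as_one and prev_gap):
                positions.append(max(1, cons_pos))
            prev_gap = True
        else:
            prev_gap = False
            if a != c:
                positions.append(cons_pos)
    return RepeatMutationRecord(locus_id, repeat_index, is_focus,
                                len(positions), tuple(positions))


def mutation_summary(loci: list[CrisprLocus], focus: str = "first",
                     label: str = "", params: AlignmentParams | None = None,
                     gap_run_as_one: bool = False) -> MutationSummary:
    """Cohort summary of mutation burden, focus class vs the rest.

    ``focus`` selects which repeat is compared against the others:
    "first" (the extra repeat, II-C) or "last" (the oldest repeat of a
    II-A array, acquired-through-the-first-repeat architecture).
    """
    if not loci:
        raise ValueError("mutation_summary needs at least one locus")
    if focus not in ("first", "last"):
        raise ValueError("focus must be 'first' or 'last'")
    records: list[RepeatMutationRecord] = []
    for loc in loci:
        cons = loc.consensus or loc.compute_consensus()
        keep = filter_length_outliers(loc, cons)
        focus_idx = 0 if focus == "first" else len(loc.repeats) - 1
        for i in keep:
            records.append(count_mutations(
                loc.repeat_seq(i), cons, params, gap_run_as_one,
                locus_id=loc.id, repeat_index=i + 1, is_focus=(i == focus_idx)))

    def _hist(rs):
        h = {"0": 0, "1": 0, "2": 0, "3+": 0}
        for r in rs:
            h[str(r.mutations) if r.mutations < 3 else "3+"] += 1
        return h

    def _positions(rs):
        out: dict[int, int] = {}
        for r in rs:
            for p in r.positions:
                out[p] = out.get(p, 0) + 1
        return out

    foc = [r for r in records if r.is_focus]
    non = [r for r in records if not r.is_focus]
    return MutationSummary(
        label=label, n_arrays=len(loci), n_repeats=len(records),
        focus_frac_mutated=(sum(1 for r in foc if r.mutations > 0) / len(foc)) if foc else 0.0,
        nonfocus_frac_mutated=(sum(1 for r in non if r.mutations > 0) / len(non)) if non else 0.0,
        focus_hist=_hist(foc), nonfocus_hist=_hist(non),
        focus_positions=_positions(foc), nonfocus_positions=_positions(non),
        records=tuple(records))
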