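"""Synthetic locus cohorts and mini-genomes with planted ground truth.

The generator emulates the sequence features the analysis assumes — it
does not simulate transcription or spacer acquisition.  Each locus gets:

- a CRISPR array (repeats = spacers + 1) whose first repeat in
  transcription order is the extra repeat;
- an upstream intergenic region whose length follows the subtype's
  intergenic-length distribution (II-C mean 247 nt, II-A mean 68 nt,
  truncated at 30 nt; quality control later caps the analysed window at
  180 nt);
- an A-rich background composition (defaults A .60 / C .14 / G .14 /
  T .12), emulating AT-rich leader/intergenic sequence in which spurious
  qualifying helices are rare — see the methods note for why a balanced
  composition saturates the helix-presence statistic;
- optional plants, each recorded in the ground truth: 5'-biased extra-
  repeat mutations, a stem-loop + U-tract terminator, a helix pairing the
  25-nt guide window, a degraded repeat copy 20-45 nt upstream
  (rescuable by QC), and a tracrRNA whose anti-repeat is complementary to
  the consensus repeat.

Everything is reproducible from the master seed; per-locus randomness is
derived per locus id.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

from .locus_qc import CrisprLocus
from .seqcore import GenomicInterval, NucleotideSequence, child_seed, reverse_complement

__all__ = ["SynthConfig", "GroundTruth", "CohortData", "generate_cohort", "generate_null_genome"]

DEFAULT_COMPOSITION = (0.60, 0.14, 0.14, 0.12)  # A, C, G, T
_BASES = "ACGT"


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the cohort conditions used
    throughout the analysis."""

    n_loci: int = 100
    subtype: str = "II-C"
    repeat_length: int = 36
    spacer_length: int = 30
    spacers_range: tuple[int, int] = (3, 8)
    upstream_mean: float | None = None     # None: 247 (II-C) / 68 (II-A)
    upstream_sd: float = 60.0
    upstream_min: int = 30
    composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    # extra-repeat mutation mechanism
    p_mutation: float = 0.6                # P(extra repeat carries >= 1 mutation)
    mutation_count_probs: tuple[tuple[int, float], ...] = ((1, 0.5), (2, 0.3), (3, 0.2))
    p_position_first15: float = 0.85       # 5' bias of planted mutations
    p_nonextra_mutated: float = 0.05       # background: non-extra repeats, 1 mutation
    # terminator mechanism
    p_rit: float = 0.12
    rit_stem: int = 9
    rit_loop: int = 4
    rit_tail: int = 8
    p_rit_background: float = 0.12         # per non-upstream intergenic gap
    # helix mechanism
    p_helix: float = 0.3
    helix_arm_len: int = 10
    # QC rescue plant
    p_rescuable: float = 0.0
    rescue_substitutions: int = 3
    # tracrRNA
    anti_repeat_len: int = 24
    tracr_scaffold_len: int = 60
    # architecture
    gene_len: int = 600
    n_extra_genes: int = 3
    p_reverse: float = 0.5                 # locus annotated on the minus strand

    def upstream_mean_resolved(self) -> float:
        if self.upstream_mean is not None:
            return self.upstream_mean
        return 68.0 if self.subtype == "II-A" else 247.0


@dataclass
class GroundTruth:
    """Planted features of one locus, in trimmed-upstream coordinates."""

    locus_id: str
    upstream_len: int                  # analysed window (after the 180-nt cap)
    extra_mutations: int = 0
    extra_mutation_positions: tuple[int, ...] = ()
    nonextra_mutated_indices: tuple[int, ...] = ()
    has_rit: bool = False
    rit_span: tuple[int, int] | None = None
    has_helix: bool = False
    helix_arm_span: tuple[int, int] | None = None
    helix_guide_span: tuple[int, int] | None = None
    has_rescue: bool = False
    rescue_span: tuple[int, int] | None = None
    rescue_gap: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortData:
    loci: list[CrisprLocus]
    contigs: dict[str, NucleotideSequence]
    genes: list[GenomicInterval]
    truth: dict[str, GroundTruth]
    descriptors: list[dict]


def _rand_seq(rng: random.Random, n: int, comp) -> str:
    return "".join(rng.choices(_BASES, weights=comp, k=n))


def _uniform_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _make_terminator(rng: random.Random, cfg: SynthConfig) -> str:
    stem = "".join(rng.choices("GC" if rng.random() < 0.8 else "AT", k=1)[0]
                   for _ in range(cfg.rit_stem))
    loop = _uniform_seq(rng, cfg.rit_loop)
    return stem + loop + reverse_complement(stem) + "T" * cfg.rit_tail


def _plant(upstream: list[str], pos: int, payload: str) -> None:
    upstream[pos : pos + len(payload)] = list(payload)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _mutate_repeat(rng: random.Random, seq: str, count: int, first15_bias: float) -> tuple[str, tuple[int, ...]]:
    n = len(seq)
    positions: set[int] = set()
    while len(positions) < count:
        if rng.random() < first15_bias:
            p = rng.randint(1, min(15, n))
        else:
            p = rng.randint(min(16, n), n)
        positions.add(p)
    out = list(seq)
    for p in positions:
        out[p - 1] = rng.choice([b for b in _BASES if b != out[p - 1]])
    return "".join(out), tuple(sorted(positions))


def generate_cohort(cfg: SynthConfig, seed: int = 0) -> CohortData:
    """Generate a cohort of annotated loci on mini-contigs.

    Each contig holds an upstream gene, the intergenic region with any
    planted features, the array, and downstream genes separated by
    background intergenic gaps (which receive terminator plants at the
    background rate, supporting the expected-RIT denominator).
    Infeasible plant geometries trigger regeneration of the locus with a
    fresh derived seed.
    """
    loci: list[CrisprLocus] = []
    contigs: dict[str, NucleotideSequence] = {}
    genes: list[GenomicInterval] = []
    truths: dict[str, GroundTruth] = {}
    descriptors: list[dict] = []
    for idx in range(cfg.n_loci):
        for attempt in range(20):
            built = _generate_locus(cfg, seed, idx, attempt)
            if built is not None:
                break
        else:  # pragma: no cover - geometry is feasible at sane configs
            raise RuntimeError(f"locus {idx}: could not satisfy plant geometry")
        locus, contig, locus_genes, truth, descriptor = built
        loci.append(locus)
        contigs[contig.id] = contig
        genes.extend(locus_genes)
        truths[locus.id] = truth
        descriptors.append(descriptor)
    return CohortData(loci, contigs, genes, truths, descriptors)


def _generate_locus(cfg: SynthConfig, seed: int, idx: int, attempt: int):
    locus_id = f"locus{idx:04d}"
    rng = random.Random(child_seed(seed, "locus", idx, attempt))
    comp = cfg.composition

    # intergenic length (full), analysed window W (post-QC cap)
    L = 0
    while L < cfg.upstream_min:
        L = int(round(rng.gauss(cfg.upstream_mean_resolved(), cfg.upstream_sd)))
    W = min(180, L)
    upstream = list(_rand_seq(rng, L, comp))
    w0 = L - W  # window start within the intergenic region
    truth = GroundTruth(locus_id=locus_id, upstream_len=W)
    occupied: list[tuple[int, int]] = []  # spans in window coordinates

    # consensus repeat and array
    consensus = _uniform_seq(rng, cfg.repeat_length)
    n_spacers = rng.randint(*cfg.spacers_range)
    repeats = [consensus] * (n_spacers + 1)
    if rng.random() < cfg.p_mutation:
        counts, weights = zip(*cfg.mutation_count_probs)
        k = rng.choices(counts, weights=weights)[0]
        mutated, positions = _mutate_repeat(rng, consensus, k, cfg.p_position_first15)
        repeats[0] = mutated
        truth.extra_mutations = k
        truth.extra_mutation_positions = positions
    bg_mut = []
    for i in range(1, len(repeats)):
        if rng.random() < cfg.p_nonextra_mutated:
            repeats[i], _ = _mutate_repeat(rng, repeats[i], 1, 0.5)
            bg_mut.append(i)
    truth.nonextra_mutated_indices = tuple(bg_mut)

    # plants in the analysed window (window coordinates)
    guide = (W - 25, W)
    if rng.random() < cfg.p_rit:
        rit = _make_terminator(rng, cfg)
        hi = W - 25 - len(rit)
        if hi < 0:
            return None
        pos = rng.randint(0, hi)
        _plant(upstream, w0 + pos, rit)
        occupied.append((pos, pos + len(rit)))
        truth.has_rit = True
        truth.rit_span = (pos, pos + len(rit))

    if rng.random() < cfg.p_rescuable:
        gap = rng.randint(20, 45)
        span = (W - gap - cfg.repeat_length, W - gap)
        if span[0] < 0 or any(_overlaps(span, o) for o in occupied):
            return None
        degraded, _ = _mutate_repeat(rng, consensus, cfg.rescue_substitutions, 0.5)
        _plant(upstream, w0 + span[0], degraded)
        occupied.append(span)
        truth.has_rescue = True
        truth.rescue_span = span
        truth.rescue_gap = gap

    if rng.random() < cfg.p_helix:
        arm = cfg.helix_arm_len
        placed = False
        for _ in range(50):
            o = rng.randint(0, 25 - arm)
            frag = "".join(upstream[w0 + guide[0] + o : w0 + guide[0] + o + arm])
            hi = W - 25 - arm - 3
            if hi < 0:
                return None
            pos = rng.randint(0, hi)
            span = (pos, pos + arm)
            if any(_overlaps(span, o2) for o2 in occupied):
                continue
            _plant(upstream, w0 + pos, reverse_complement(frag))
            occupied.append(span)
            truth.has_helix = True
            truth.helix_arm_span = span
            truth.helix_guide_span = (guide[0] + o, guide[0] + o + arm)
            placed = True
            break
        if not placed:
            return None

    # assemble the contig (plus-strand frame first)
    parts: list[str] = []
    gene_spans: list[tuple[int, int]] = []
    bg_rit_spans: list[tuple[int, int]] = []

    def _append_gene():
        start = sum(map(len, parts))
        parts.append(_rand_seq(rng, cfg.gene_len, comp))
        gene_spans.append((start, start + cfg.gene_len))

    _append_gene()
    up_start = sum(map(len, parts))
    parts.append("".join(upstream))
    array_start = sum(map(len, parts))
    repeat_ivs: list[tuple[int, int]] = []
    pos = array_start
    for i, rep in enumerate(repeats):
        repeat_ivs.append((pos, pos + len(rep)))
        parts.append(rep)
        pos += len(rep)
        if i < n_spacers:
            parts.append(_uniform_seq(rng, cfg.spacer_length))
            pos += cfg.spacer_length
    parts.append(_rand_seq(rng, 20, comp))
    _append_gene()
    for _ in range(cfg.n_extra_genes):
        gap = 0
        while gap < cfg.upstream_min + 1:
            gap = int(round(rng.gauss(cfg.upstream_mean_resolved(), cfg.upstream_sd)))
        gap_seq = _rand_seq(rng, gap, comp)
        if rng.random() < cfg.p_rit_background:
            rit = _make_terminator(rng, cfg)
            if gap > len(rit):
                p = rng.randint(0, gap - len(rit))
                gap_seq = gap_seq[:p] + rit + gap_seq[p + len(rit):]
                bg_rit_spans.append((sum(map(len, parts)) + p,))
        parts.append(gap_seq)
        _append_gene()

    contig_str = "".join(parts)
    contig_id = f"contig_{locus_id}"
    strand = "-" if rng.random() < cfg.p_reverse else "+"
    Lc = len(contig_str)
    if strand == "-":
        contig_str = reverse_complement(contig_str)
        repeat_ivs = [(Lc - e, Lc - s) for s, e in repeat_ivs]
        gene_spans = [(Lc - e, Lc - s) for s, e in gene_spans]
    contig = NucleotideSequence(contig_id, contig_str)

    tracr = None
    if cfg.anti_repeat_len > 0:
        anti = reverse_complement(consensus[: cfg.anti_repeat_len])
        tracr = NucleotideSequence(f"{locus_id}|tracr",
                                   anti + _uniform_seq(rng, cfg.tracr_scaffold_len))

    locus = CrisprLocus.from_annotation(
        id=locus_id, subtype=cfg.subtype, contig=contig, strand=strand,
        repeat_intervals=repeat_ivs, tracrRNA=tracr)
    locus_genes = [GenomicInterval(contig_id, s, e, "+") for s, e in sorted(gene_spans)]
    descriptor = {
        "id": locus_id, "subtype": cfg.subtype, "contig": contig_id, "strand": strand,
        "repeats": [[s + 1, e] for s, e in sorted(repeat_ivs)],  # 1-based inclusive
        "tracrRNA": tracr.residues if tracr else None,
    }
    return locus, contig, locus_genes, truth, descriptor


def synthesize_upstream(length: int, seed: int,
                        composition=DEFAULT_COMPOSITION,
                        plant_helix_arm: int | None = None,
                        guide_len: int = 25) -> NucleotideSequence:
    """One stand-alone upstream region, optionally with a planted guide helix.

    Mirrors the cohort generator's construction: background drawn from the
    configured composition; when ``plant_helix_arm`` is set, the reverse
    complement of a random guide-window substring of that length is
    embedded at least 3 nt 5' of the window.  Used for cohort-free null
    and power experiments.
    """
    rng = random.Random(child_seed(seed, "upstream"))
    s = list(_rand_seq(rng, length, composition))
    if plant_helix_arm:
        arm = plant_helix_arm
        if length < guide_len + arm + 3:
            raise ValueError("upstream too short for the requested plant")
        o = rng.randint(0, guide_len - arm)
        frag = "".join(s[length - guide_len + o : length - guide_len + o + arm])
        pos = rng.randint(0, length - guide_len - arm - 3)
        s[pos : pos + arm] = list(reverse_complement(frag))
    return NucleotideSequence(f"up{seed}", "".join(s))


def generate_null_genome(n_genes: int, contig_len: int,
                         composition=DEFAULT_COMPOSITION, seed: int = 0,
                         gene_len_mean: float = 900.0, gene_len_sd: float = 150.0,
                         gap_mean: float = 200.0):
    """Random annotated mini-genome for expected-ratio denominators.

    Genes of ~N(900, 150) nt are separated by exponential(mean 200) + 31 nt
    intergenic gaps on a composition-controlled background; generation
    stops early if the contig fills up.
    """
    rng = random.Random(child_seed(seed, "nullgenome"))
    contig_id = f"nullgenome_{seed}"
    seq = list(_rand_seq(rng, contig_len, composition))
    genes: list[GenomicInterval] = []
    pos = int(rng.expovariate(1.0 / gap_mean)) + 31
    for _ in range(n_genes):
        glen = max(300, int(rng.gauss(gene_len_mean, gene_len_sd)))
        if pos + glen > contig_len:
            break
        genes.append(GenomicInterval(contig_id, pos, pos + glen, "+"))
        pos += glen + int(rng.expovariate(1.0 / gap_mean)) + 31
    return NucleotideSequence(contig_id, "".join(seq)), genes
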