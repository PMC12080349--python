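"""Repeat:tracrRNA hybridization energies under a nearest-neighbor model.

The engine finds the minimum-free-energy intermolecular duplex between two
RNAs (DNA input is treated as RNA, T≡U): Watson–Crick stacks use the
standard 37°C nearest-neighbor parameters (Xia et al. free energies),
stacks involving a G·U pair use a coarse uniform value, helix formation
pays a duplex initiation penalty, and bulge/internal-loop nucleotides pay
a fixed per-nucleotide penalty.  Intramolecular accessibility is
deliberately not modelled: the analysis only needs the *relative*
extra-repeat vs consensus-repeat comparison, which a hybridization-only
model preserves.  An external-engine adapter accepts tabulated energies
for exact replication with a full predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .seqcore import NucleotideSequence
from .stats import MannWhitneyResult, mann_whitney_u

__all__ = [
    "DuplexResult",
    "DuplexEnergyResult",
    "CohortEnergyComparison",
    "interaction_energy",
    "filter_redundant_tracrs",
    "compare_cohort",
    "INIT_PENALTY",
    "UNPAIRED_PENALTY",
]

INIT_PENALTY = 4.09      # kcal/mol, duplex initiation
UNPAIRED_PENALTY = 2.0   # kcal/mol per bulged / internal-loop nucleotide
MAX_GAP = 10             # max unpaired stretch per strand between stacked pairs
GU_STACK = -0.8          # coarse uniform stack value when a G·U pair is involved

# Watson–Crick nearest-neighbor stacks, 5'x1x2/3'y1y2 keys (T stands for U)
_WC_STACKS = {
    "AA/TT": -0.93, "AT/TA": -1.10, "TA/AT": -1.33, "CT/GA": -2.08,
    "CA/GT": -2.11, "GT/CA": -2.24, "GA/CT": -2.35, "CG/GC": -2.36,
    "GG/CC": -3.26, "GC/CG": -3.42,
}
_PAIRS_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "T"), ("T", "G")}
_PAIRS = _PAIRS_WC | _PAIRS_GU


def _stack_table() -> dict[str, float]:
    table = dict(_WC_STACKS)
    for key, v in list(_WC_STACKS.items()):
        x1, x2 = key[0], key[1]
        y1, y2 = key[3], key[4]
        table.setdefault(f"{y2}{y1}/{x2}{x1}", v)  # read from the other strand
    return table


_STACKS = _stack_table()


def stack_energy(x1: str, y1: str, x2: str, y2: str) -> float:
    """Energy of stacking pair (x2,y2) onto (x1,y1); x strand 5'->3'."""
    if (x1, y1) not in _PAIRS or (x2, y2) not in _PAIRS:
        raise ValueError("stack requires two canonical pairs")
    key = f"{x1}{x2}/{y1}{y2}"
    if key in _STACKS:
        return _STACKS[key]
    return GU_STACK


@dataclass(frozen=True)
class DuplexResult:
    energy: float | None               # kcal/mol; None = no favourable duplex
    pairs: tuple[tuple[int, int], ...]  # (i on a, j on b), i ascending / j descending
    length: int                        # paired nucleotides on the a (repeat) side

    @property
    def interacts(self) -> bool:
        return self.energy is not None


def interaction_energy(rna_a: NucleotideSequence, rna_b: NucleotideSequence) -> DuplexResult:
    """Minimum-free-energy intermolecular duplex between two RNAs.

    Returns "no interaction" (energy None, zero length) when no duplex
    with energy < 0 exists.
    """
    a, b = rna_a.residues, rna_b.residues
    if len(a) < 8 or len(b) < 8:
        raise ValueError("interaction_energy requires sequences of >= 8 nt")
    comp_pairs = [(i, j) for i in range(len(a)) for j in range(len(b))
                  if (a[i], b[j]) in _PAIRS]
    if not comp_pairs:
        return DuplexResult(None, (), 0)
    comp_pairs.sort()
    D: dict[tuple[int, int], float] = {}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    by_pos = set(comp_pairs)
    for i, j in comp_pairs:
        best = INIT_PENALTY
        par: tuple[int, int] | None = None
        for da in range(1, MAX_GAP + 2):
            i2 = i - da
            if i2 < 0:
                break
            for db in range(1, MAX_GAP + 2):
                j2 = j + db
                if j2 >= len(b) or (i2, j2) not in by_pos:
                    continue
                if da == 1 and db == 1:
                    cost = stack_energy(a[i2], b[j2], a[i], b[j])
                else:
                    cost = UNPAIRED_PENALTY * ((da - 1) + (db - 1))
                cand = D[(i2, j2)] + cost
                if cand < best - 1e-12:
                    best = cand
                    par = (i2, j2)
        D[(i, j)] = best
        parent[(i, j)] = par
    end = min(D, key=lambda k: (D[k], k))
    if D[end] >= 0:
        return DuplexResult(None, (), 0)
    chain = []
    cur: tuple[int, int] | None = end
    while cur is not None:
        chain.append(cur)
        cur = parent[cur]
    chain.reverse()
    return DuplexResult(float(D[end]), tuple(chain), len(chain))


@dataclass(frozen=True)
class DuplexEnergyResult:
    locus_id: str
    energy_extra: float | None
    energy_consensus: float | None
    length_extra: int
    length_consensus: int
    engine: str = "native"


@dataclass(frozen=True)
class CohortEnergyComparison:
    n: int
    median_extra: float | None
    median_consensus: float | None
    U: float | None
    p_value: float | None
    alternative: str


def filter_redundant_tracrs(loci, threshold: float = 0.70):
    """Keep one locus per tracrRNA identity cluster (CD-HIT convention).

    Loci without a tracrRNA are dropped; the list of excluded locus ids is
    returned alongside the retained loci.
    """
    from .seqcore import greedy_identity_cluster

    with_tracr = [loc for loc in loci if loc.tracrRNA is not None]
    skipped = [loc.id for loc in loci if loc.tracrRNA is None]
    if not with_tracr:
        return [], skipped
    tracrs = [NucleotideSequence(loc.id, loc.tracrRNA.residues) for loc in with_tracr]
    reps, assignment = greedy_identity_cluster(tracrs, threshold)
    rep_ids = {r.id for r in reps}
    return [loc for loc in with_tracr if loc.id in rep_ids], skipped


def compare_cohort(loci, alternative: str = "two-sided",
                   external_energies: dict[str, tuple[float, float]] | None = None,
                   no_interaction_energy: float = 0.0):
    """Per-locus tracrRNA energies against extra vs consensus repeat, plus MWU.

    ``external_energies`` (locus id -> (extra, consensus)) swaps in a full
    external predictor's values.  Loci where an energy is "no interaction"
    contribute ``no_interaction_energy`` (default 0 kcal/mol) to the
    cohort samples so the weaker-interaction direction is preserved.
    Returns (per-locus results, CohortEnergyComparison); the test is
    skipped (p None) for cohorts of fewer than 2 loci.
    """
    results: list[DuplexEnergyResult] = []
    for loc in loci:
        if external_energies is not None:
            e_x, e_c = external_energies[loc.id]
            results.append(DuplexEnergyResult(loc.id, e_x, e_c, 0, 0, engine="external"))
            continue
        extra = loc.extra_repeat_seq()
        dx = interaction_energy(extra, loc.tracrRNA)
        dc = interaction_energy(loc.consensus, loc.tracrRNA)
        results.append(DuplexEnergyResult(
            loc.id, dx.energy, dc.energy, dx.length, dc.length))
    xs = [r.energy_extra if r.energy_extra is not None else no_interaction_energy
          for r in results]
    ys = [r.energy_consensus if r.energy_consensus is not None else no_interaction_energy
          for r in results]
    if not xs:
        return results, CohortEnergyComparison(0, None, None, None, None, alternative)
    med_x, med_y = float(median(xs)), float(median(ys))
    if len(xs) < 2 or xs == ys:
        p = 1.0 if (len(xs) >= 2 and xs == ys) else None
        u = None
        if xs == ys and len(xs) >= 2:
            u = len(xs) * len(ys) / 2.0
        return results, CohortEnergyComparison(len(xs), med_x, med_y, u, p, alternative)
    mw: MannWhitneyResult = mann_whitney_u(xs, ys, alternative)
    return results, CohortEnergyComparison(len(xs), med_x, med_y, mw.U, mw.p_value, alternative)
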