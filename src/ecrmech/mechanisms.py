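"""Stage 6: per-locus assignment of candidate ecrRNA-suppression mechanisms.

Three thresholds, one per mechanism:

- repeat-mutation: at least two mutations in the extra repeat;
- RIT: at least one terminator call in the upstream region;
- helix: a qualifying helix (intra or guide mode) whose occurrence
  probability exceeds 75% — interpreted as the empirical shuffle-null
  probability of such a helix being below 25%, i.e. at least 75%
  confidence that the observed helix is not a composition artifact.

An upstream RIT within the guide window naturally re-registers as a
guide helix (its stem pairs the window); no de-duplication is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = ["MechanismAssignment", "VennSummary", "assign_mechanisms", "venn_summary"]

MUTATION_THRESHOLD = 2
HELIX_OCCURRENCE_THRESHOLD = 0.75


@dataclass(frozen=True)
class MechanismAssignment:
    locus_id: str
    has_mutation_mechanism: bool
    has_rit_mechanism: bool
    has_helix_mechanism: bool

    @property
    def assigned(self) -> bool:
        return (self.has_mutation_mechanism or self.has_rit_mechanism
                or self.has_helix_mechanism)

    @property
    def key(self) -> str:
        parts = [name for flag, name in [
            (self.has_mutation_mechanism, "mutation"),
            (self.has_rit_mechanism, "rit"),
            (self.has_helix_mechanism, "helix")] if flag]
        return "+".join(parts) if parts else "none"


@dataclass(frozen=True)
class VennSummary:
    counts: dict          # 7 intersection keys + "none"
    total: int
    assigned_fraction: float


def assign_mechanisms(
    locus_id: str,
    extra_repeat_mutations: int | None,
    n_upstream_rits: int | None,
    helix_calls: list[tuple[bool, float]] | None,
    mutation_threshold: int = MUTATION_THRESHOLD,
    occurrence_threshold: float = HELIX_OCCURRENCE_THRESHOLD,
) -> MechanismAssignment:
    """Flag the candidate mechanisms of one locus.

    ``helix_calls`` holds (has_helix, null_prob) per search mode; the
    helix flag requires some mode with a helix whose null probability is
    below 1 - occurrence_threshold.  Any missing stage output raises — the
    caller excludes such loci and logs them.
    """
    if extra_repeat_mutations is None or n_upstream_rits is None or helix_calls is None:
        raise ValueError(f"{locus_id}: missing stage output for mechanism assignment")
    helix_flag = any(h and q < 1.0 - occurrence_threshold for h, q in helix_calls)
    return MechanismAssignment(
        locus_id=locus_id,
        has_mutation_mechanism=extra_repeat_mutations >= mutation_threshold,
        has_rit_mechanism=n_upstream_rits >= 1,
        has_helix_mechanism=helix_flag)


def venn_summary(assignments: list[MechanismAssignment]) -> VennSummary:
    """Exact counts of the 7 mechanism intersections plus the unassigned rest."""
    if not assignments:
        raise ValueError("venn_summary needs at least one assignment")
    keys = ["+".join(n for f, n in zip(combo, ("mutation", "rit", "helix")) if f) or "none"
            for combo in product([True, False], repeat=3)]
    counts = {k: 0 for k in keys}
    for a in assignments:
        counts[a.key] += 1
    total = len(assignments)
    return VennSummary(counts=counts, total=total,
                       assigned_fraction=1.0 - counts["none"] / total)
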