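# ecrmech

Every CRISPR array carries one repeat more than it has spacers. The
extra repeat — first in transcription order in type II systems — would
be processed into an "extraneous" crRNA (ecrRNA) whose guide is just the
25 nt of intergenic sequence upstream of the array: an RNA that occupies
Cas9 without targeting anything. `ecrmech` implements a sequence-level
pipeline for asking how type II-C systems may suppress this ecrRNA, and
scores three candidate mechanisms per locus:

1. **repeat mutation** — the extra repeat accumulates mutations
   (counted by global alignment to the array consensus) that weaken the
   repeat:tracrRNA duplex needed for crRNA processing;
2. **Rho-independent terminator (RIT)** — a hairpin + poly-U tract in
   the upstream region insulates the array from read-through
   transcription;
3. **guide-sequestering helix** — an RNA helix within the upstream
   region, or pairing the 25-nt guide window itself, blocks ecrRNA
   processing or targeting.

The statistical core: per-locus nulls from exact dinucleotide shuffles
(Altschul–Erickson), cohort-level helix enrichment by the exact
Poisson-binomial upper tail of per-system null probabilities, an
observed/expected intergenic RIT ratio, a nearest-neighbor
hybridization-energy comparison (extra vs consensus repeat against the
tracrRNA, Mann–Whitney U), and a per-locus mechanism classifier
(≥ 2 extra-repeat mutations; ≥ 1 upstream RIT; helix occurrence
probability > 75%) with a Venn decomposition. A synthetic-locus
generator with planted ground truth makes every stage testable without
downloads; see `docs/methods.md` for the models, defaults, and
limitations.

## Worked example

Simulate a 30-locus II-C cohort and run the stages (each driver is a
thin wrapper over `ecrmech.pipeline`; all randomness flows from
`--seed`):

```
cd analysis
python 01_simulate_cohort.py --n-loci 30 --seed 1 --outdir results
python 03_repeat_mutations.py --n-loci 30 --seed 1 --outdir results
python 05_helix_enrichment.py --n-loci 30 --seed 1 --outdir results
python 07_mechanism_venn.py  --n-loci 30 --seed 1 --outdir results
```

prints (abridged):

```
simulated 30 loci -> results/cohort
  planted: 17 mutated extra repeats, 4 terminators, 7 guide helices, 0 rescuable repeats

30 nonredundant arrays, 207 repeats
extra repeats with >=1 mutation:     57%
non-extra repeats with >=1 mutation: 2%
extra-repeat mutations in the first 15 nt: 78%

intra : 11/30 systems with a helix, expected 1.0, aggregate P = 7.52e-11
guide : 14/30 systems with a helix, expected 6.7, aggregate P = 0.000446
guide (RIT-positive systems removed): P = 6.62e-05 (n=26)

30 systems; assigned fraction 0.633 (63%)
  helix                  11
  none                   11
  mutation               3
  ...
```

Reading this: 17 of 30 extra repeats were simulated with mutations and
57% are recovered as mutated (the 2% non-extra rate is the planted
background); helix presence (14 systems) far exceeds the
shuffle-null expectation (6.7), giving a small Poisson-binomial tail
probability; and 63% of loci end up with at least one candidate
mechanism. Stage tables (QC actions, per-repeat mutations, per-system
helices, Table-1-style RIT ratios, per-locus energies, assignments) land
under `results/pipeline/`.

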