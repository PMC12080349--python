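#!/usr/bin/env python
"""Stage 2: mutation burden of extra vs non-extra repeats after array
dereplication and repeat length filtering (pairwise alignment to the
array consensus; gaps and mismatches both count)."""
from common import parser, run


def main():
    args = parser(__doc__).parse_args()
    res = run(args, skip=("rit", "helix", "energy", "mechanisms"))
    s = res.mutation
    print(f"{s.n_arrays} nonredundant arrays, {s.n_repeats} repeats")
    print(f"extra repeats with >=1 mutation:     {100*s.focus_frac_mutated:.0f}%")
    print(f"non-extra repeats with >=1 mutation: {100*s.nonfocus_frac_mutated:.0f}%")
    first15 = sum(c for p, c in s.focus_positions.items() if p <= 15)
    total = sum(s.focus_positions.values())
    if total:
        print(f"extra-repeat mutations in the first 15 nt: {100*first15/total:.0f}%")


if __name__ == "__main__":
    main()
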