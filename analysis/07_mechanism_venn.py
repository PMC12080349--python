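#!/usr/bin/env python
"""Stage 6: per-locus mechanism assignment (>=2 extra-repeat mutations;
>=1 upstream RIT; helix with occurrence probability > 75%) and the Venn
decomposition of the cohort."""
from common import parser, run


def main():
    args = parser(__doc__).parse_args()
    res = run(args)
    v = res.venn
    print(f"{v.total} systems; assigned fraction "
          f"{v.assigned_fraction:.3f} ({100*v.assigned_fraction:.0f}%)")
    for key in sorted(v.counts, key=lambda k: -v.counts[k]):
        print(f"  {key:22s} {v.counts[key]}")


if __name__ == "__main__":
    main()
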