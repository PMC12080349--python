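#!/usr/bin/env python
"""Stage 5: nearest-neighbor hybridization energy of the tracrRNA against
the extra repeat vs the consensus repeat, after 70% tracrRNA redundancy
filtering; two-sided Mann-Whitney U on the two energy samples."""
from common import parser, run


def main():
    args = parser(__doc__).parse_args()
    res = run(args, skip=("helix", "rit", "mechanisms"))
    c = res.energy
    print(f"{c.n} loci after tracrRNA redundancy filtering")
    print(f"median interaction energy, extra repeat:     {c.median_extra:.1f} kcal/mol")
    print(f"median interaction energy, consensus repeat: {c.median_consensus:.1f} kcal/mol")
    print(f"Mann-Whitney U = {c.U:.1f}, two-sided P = {c.p_value:.3g}")


if __name__ == "__main__":
    main()
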