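#!/usr/bin/env python
"""Stage 4: call Rho-independent terminators in upstream regions and
compare against the expected rate in intergenic regions (> 30 nt) of the
cohort's genomes (Table-1-style observed/expected ratios)."""
from common import parser, run


def main():
    args = parser(__doc__).parse_args()
    res = run(args, skip=("helix", "energy", "mechanisms"))
    rr = res.rit_report
    print(f"cohort {rr['label']}: avg upstream intergenic length "
          f"{rr['avg_intergenic_len']:.0f} nt")
    print(f"observed RITs {rr['observed_rits']} / {rr['systems_analyzed']} systems "
          f"-> ratio {rr['observed_ratio']:.2f} ({100*rr['observed_ratio']:.0f}%)")
    print(f"expected intergenic ratio {rr['expected_ratio']:.2f}")


if __name__ == "__main__":
    main()
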