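#!/usr/bin/env python
"""Stage 1 QC: orient loci, trim the upstream region at the nearest gene
(cap 180 nt, discard < 30 nt), and rescue mutated repeats hidden in the
upstream region via the empirical shuffle e-value (< 0.01)."""
from collections import Counter

from common import parser, run


def main():
    args = parser(__doc__).parse_args()
    res = run(args, skip=("mutations", "rit", "helix", "energy", "mechanisms"))
    actions = Counter(r["action"] for r in res.qc_rows)
    print(f"QC over {len(res.qc_rows)} loci: {dict(actions)}")
    print(f"kept {len(res.loci)} loci; report -> {args.outdir/'pipeline'/'qc_report.tsv'}")


if __name__ == "__main__":
    main()
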