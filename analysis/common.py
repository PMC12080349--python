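"""Shared plumbing for the numbered analysis drivers."""

import argparse
from pathlib import Path

from ecrmech.pipeline import RunConfig, load_cohort, run_pipeline
from ecrmech.synth import SynthConfig, generate_cohort


def parser(description: str) -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-loci", type=int, default=100)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--cohort-dir", type=Path, default=None,
                    help="existing cohort (from 01_simulate_cohort.py); "
                         "regenerated from --seed when absent")
    return ap


def get_cohort(args):
    d = args.cohort_dir or (args.outdir / "cohort")
    if (Path(d) / "contigs.fasta").exists():
        return load_cohort(d / "contigs.fasta", d / "genes.gff3",
                           d / "loci.json", d / "truth.json")
    return generate_cohort(SynthConfig(n_loci=args.n_loci), seed=args.seed)


def run(args, skip=(), n_shuffles_helix=100):
    cfg = RunConfig(seed=args.seed, skip_stages=tuple(skip),
                    n_shuffles_helix=n_shuffles_helix,
                    outdir=str(args.outdir / "pipeline"))
    return run_pipeline(cfg, cohort=get_cohort(args))
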