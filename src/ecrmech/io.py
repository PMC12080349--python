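"""File I/O: FASTA (via Biopython), GFF3 gene features, locus descriptors,
ground truth, and TSV report writing.

Coordinates are 1-based inclusive in files and 0-based half-open in
memory, converting at this boundary only.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import GenomicInterval, NucleotideSequence

__all__ = [
    "read_fasta", "write_fasta", "read_gff_features", "write_gff_features",
    "read_locus_descriptors", "write_locus_descriptors", "write_tsv",
]


def read_fasta(path) -> dict[str, NucleotideSequence]:
    return {rec.id: NucleotideSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, NucleotideSequence] | list[NucleotideSequence]) -> None:
    if isinstance(seqs, dict):
        seqs = list(seqs.values())
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_gff_features(path, feature_types: set[str] | None = None) -> list[GenomicInterval]:
    """Gene features from GFF3: columns 1 (seqid), 4/5 (1-based inclusive
    span), 7 (strand); attributes are treated as opaque."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                continue
            if feature_types and f[2] not in feature_types:
                continue
            strand = f[6] if f[6] in "+-" else "+"
            out.append(GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), strand))
    return out


def write_gff_features(path, features: list[GenomicInterval],
                       source: str = "ecrmech", ftype: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(features):
            fh.write(f"{g.contig}\t{source}\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={ftype}{i + 1}\n")


def write_locus_descriptors(path, descriptors: list[dict]) -> None:
    Path(path).write_text(json.dumps(descriptors, indent=1) + "\n")


def read_locus_descriptors(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_tsv(path, header: list[str], rows: list[list], meta: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for m in meta or []:
            fh.write(f"# {m}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
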