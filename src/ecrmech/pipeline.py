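"""End-to-end orchestration: QC -> mutations -> RIT -> helix -> energy ->
mechanism assignment, with TSV/JSON artifact writing and a run manifest.

The stage order follows the analysis logic: terminator calls are made
before helix aggregation so the guide-mode enrichment can be re-run with
RIT-positive systems excluded, and mechanism assignment consumes all
three stage outputs.  Every stage is importable on its own; this module
only wires them together.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from . import __version__
from .energy import CohortEnergyComparison, compare_cohort, filter_redundant_tracrs
from .helix import (EnrichmentResult, HelixParams, aggregate_enrichment, find_helix,
                    pairing_profile, system_null_prob, system_null_profile)
from .locus_qc import CrisprLocus, rescue_mutated_repeat, trim_upstream
from .mechanisms import MechanismAssignment, assign_mechanisms, venn_summary
from .repeat_mutations import count_mutations, dereplicate_arrays, mutation_summary
from .seqcore import GenomicInterval, NucleotideSequence, child_seed, reverse_complement
from .synth import CohortData, SynthConfig, generate_cohort
from .terminators import TerminatorConfig, call_terminators, enumerate_intergenic

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "summary_report",
           "train_test_split", "load_cohort", "write_cohort"]


def load_cohort(fasta_path, gff_path, descriptor_path, truth_path=None) -> CohortData:
    """Assemble a cohort from on-disk inputs.

    Locus descriptors carry 1-based inclusive repeat coordinates on the
    annotation strand; sequences come from FASTA, gene features from GFF3.
    """
    from .io import read_fasta, read_gff_features, read_locus_descriptors
    from .synth import GroundTruth

    contigs = read_fasta(fasta_path)
    genes = read_gff_features(gff_path)
    descriptors = read_locus_descriptors(descriptor_path)
    loci = []
    for d in descriptors:
        tracr = (NucleotideSequence(f"{d['id']}|tracr", d["tracrRNA"])
                 if d.get("tracrRNA") else None)
        loci.append(CrisprLocus.from_annotation(
            id=d["id"], subtype=d.get("subtype", "II-C"),
            contig=contigs[d["contig"]], strand=d.get("strand", "+"),
            repeat_intervals=[(s - 1, e) for s, e in d["repeats"]],
            tracrRNA=tracr))
    truth = {}
    if truth_path is not None and Path(truth_path).exists():
        raw = json.loads(Path(truth_path).read_text())
        truth = {k: GroundTruth(**v) for k, v in raw.items()}
    return CohortData(loci, contigs, genes, truth, descriptors)


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write a cohort in the formats the pipeline ingests."""
    from .io import write_fasta, write_gff_features, write_locus_descriptors

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "contigs.fasta", cohort.contigs)
    write_gff_features(outdir / "genes.gff3", cohort.genes)
    write_locus_descriptors(outdir / "loci.json", cohort.descriptors)
    (outdir / "truth.json").write_text(json.dumps(
        {k: v.to_dict() for k, v in cohort.truth.items()}, indent=1) + "\n")


@dataclass
class RunConfig:
    synth: SynthConfig | None = None
    seed: int = 0
    outdir: str | None = None
    # stage parameters
    max_rescue_iterations: int = 3
    n_shuffles_rescue: int = 1000
    n_shuffles_helix: int = 100
    helix_intra: HelixParams = field(default_factory=HelixParams.intra_defaults)
    helix_guide: HelixParams = field(default_factory=HelixParams.guide_defaults)
    terminator: TerminatorConfig = field(default_factory=TerminatorConfig)
    train_fraction: float = 147.0 / 260.0
    skip_stages: tuple[str, ...] = ()
    mechanisms_without_energy: bool = True
    # optional helix parameter scan on the training split; chosen parameters
    # are frozen before the test split is touched
    run_scan: bool = False
    scan_k_range: tuple[int, ...] = (8, 10, 12, 14)
    scan_m_range: tuple[int, ...] = (0, 1, 2, 3)
    scan_shuffles: int = 50


@dataclass
class PipelineResult:
    loci: list[CrisprLocus]
    qc_rows: list[dict]
    mutation: object | None = None
    extra_mutation_counts: dict[str, int] = field(default_factory=dict)
    rit_calls: dict[str, int] = field(default_factory=dict)
    rit_report: dict | None = None
    helix: dict = field(default_factory=dict)
    helix_scan: dict | None = None
    energy: CohortEnergyComparison | None = None
    energy_records: list = field(default_factory=list)
    assignments: list[MechanismAssignment] = field(default_factory=list)
    venn: object | None = None
    manifest: dict = field(default_factory=dict)


def train_test_split(ids: list[str], train_fraction: float) -> tuple[set[str], set[str]]:
    """Deterministic id-hash split (stable across runs and input order)."""
    train, test = set(), set()
    for i in sorted(ids):
        h = int(hashlib.md5(i.encode()).hexdigest(), 16) % 10_000
        (train if h < train_fraction * 10_000 else test).add(i)
    return train, test


def run_pipeline(cfg: RunConfig, cohort: CohortData | None = None) -> PipelineResult:
    if cohort is None:
        if cfg.synth is None:
            raise ValueError("RunConfig needs either a synth config or a cohort")
        cohort = generate_cohort(cfg.synth, seed=cfg.seed)

    # ---- stage 1: QC --------------------------------------------------
    qc_rows: list[dict] = []
    kept: list[CrisprLocus] = []
    upstream_gap: dict[str, int] = {}  # full repeat-1-to-gene distance, uncapped
    for locus in cohort.loci:
        r1 = locus.repeats[0].start
        nearest = 0
        for g in cohort.genes:
            if g.contig != locus.repeats[0].contig:
                continue
            og = locus.map_interval(g)
            if og.end <= r1:
                nearest = max(nearest, og.end)
        upstream_gap[locus.id] = r1 - nearest
        loc = trim_upstream(locus, cohort.genes)
        rescue_e = None
        if not loc.rejected:
            loc.consensus = loc.compute_consensus()
            for _ in range(cfg.max_rescue_iterations):
                loc, cand = rescue_mutated_repeat(
                    loc, n_shuffles=cfg.n_shuffles_rescue,
                    seed=child_seed(cfg.seed, "rescue", loc.id))
                if cand is not None:
                    rescue_e = cand.empirical_e
                if cand is None or not cand.accepted or loc.rejected:
                    break
        qc_rows.append({
            "locus": loc.id, "action": loc.qc_action,
            "upstream_len": len(loc.upstream) if loc.upstream else 0,
            "empirical_e": rescue_e if rescue_e is not None else "",
            "reason": loc.reject_reason or ""})
        if not loc.rejected:
            kept.append(loc)
    result = PipelineResult(loci=kept, qc_rows=qc_rows)

    # ---- stage 2: mutation pattern ------------------------------------
    if "mutations" not in cfg.skip_stages and kept:
        focus = "last" if kept[0].subtype == "II-A" else "first"
        unique = dereplicate_arrays(kept)
        result.mutation = mutation_summary(unique, focus=focus,
                                           label=kept[0].subtype)
        for loc in kept:
            rec = count_mutations(loc.extra_repeat_seq(), loc.consensus,
                                  locus_id=loc.id)
            result.extra_mutation_counts[loc.id] = rec.mutations

    # ---- stage 3: terminators -----------------------------------------
    if "rit" not in cfg.skip_stages and kept:
        upstream_flags = []
        for loc in kept:
            calls = call_terminators(loc.upstream, cfg.terminator)
            result.rit_calls[loc.id] = len(calls)
            upstream_flags.append(bool(calls))
        genome_fracs = []
        by_contig: dict[str, list[GenomicInterval]] = {}
        for g in cohort.genes:
            by_contig.setdefault(g.contig, []).append(g)
        for loc in kept:
            cid = loc.repeats[0].contig
            contig = cohort.contigs.get(cid)
            if contig is None:
                continue
            regions = enumerate_intergenic(by_contig.get(cid, []), cid, len(contig))
            if not regions:
                continue
            with_call = 0
            for r in regions:
                seq = contig.subseq(r.start, r.end)
                fwd = call_terminators(seq, cfg.terminator)
                rev = [] if fwd else call_terminators(
                    NucleotideSequence(seq.id, reverse_complement(seq.residues)),
                    cfg.terminator)
                if fwd or rev:
                    with_call += 1
            genome_fracs.append(with_call / len(regions))
        n = len(kept)
        observed = sum(upstream_flags)
        gaps = [upstream_gap[l.id] for l in kept]
        result.rit_report = {
            "label": kept[0].subtype,
            "avg_intergenic_len": (sum(gaps) / len(gaps)) if gaps else 0.0,
            "observed_rits": observed, "systems_analyzed": n,
            "observed_ratio": observed / n if n else 0.0,
            "expected_ratio": (sum(genome_fracs) / len(genome_fracs))
                              if genome_fracs else 0.0}

    # ---- stage 4: helices ---------------------------------------------
    if "helix" not in cfg.skip_stages and kept:
        train_ids, test_ids = train_test_split([l.id for l in kept], cfg.train_fraction)
        floor = 1.0 / (cfg.n_shuffles_helix + 1)
        helix_intra, helix_guide = cfg.helix_intra, cfg.helix_guide
        if cfg.run_scan:
            from .helix import parameter_scan

            train_ups = [l.upstream for l in kept if l.id in train_ids]
            scans = {}
            for mode in ("intra", "guide"):
                chosen, grid, selected = parameter_scan(
                    train_ups, cfg.scan_k_range, cfg.scan_m_range, mode=mode,
                    n_shuffles=cfg.scan_shuffles,
                    seed=child_seed(cfg.seed, "scan", mode))
                scans[mode] = {"chosen": asdict(chosen), "selected": selected,
                               "grid": {f"{k},{m}": p for (k, m), p in grid.items()}}
                if selected:
                    if mode == "intra":
                        helix_intra = chosen
                    else:
                        helix_guide = chosen
            result.helix_scan = scans
        for mode, params in (("intra", helix_intra), ("guide", helix_guide)):
            per_system = {}
            matches = {}
            config_null = {}  # null prob of the observed helix configuration
            for loc in kept:
                m = find_helix(loc.upstream, params, loc.guide_window)
                null_seed = child_seed(cfg.seed, "helixnull", mode, loc.id)
                if m is None:
                    q = system_null_prob(loc.upstream, params,
                                         n_shuffles=cfg.n_shuffles_helix,
                                         seed=null_seed,
                                         guide_window=loc.guide_window)
                    q_good = 1.0
                else:
                    q, q_good = system_null_profile(
                        loc.upstream, params, m,
                        n_shuffles=cfg.n_shuffles_helix, seed=null_seed,
                        guide_window=loc.guide_window)
                per_system[loc.id] = (m is not None, q)
                config_null[loc.id] = q_good
                matches[loc.id] = m
            entry = {"per_system": per_system, "matches": matches, "params": params,
                     "config_null": config_null}
            ids = [l.id for l in kept]
            entry["enrichment_all"] = aggregate_enrichment(
                [per_system[i] for i in ids], label=f"{mode}/all",
                params=params, prob_floor=floor)
            test = [i for i in ids if i in test_ids]
            if len(test) >= 2:
                entry["enrichment_test"] = aggregate_enrichment(
                    [per_system[i] for i in test], label=f"{mode}/test",
                    params=params, prob_floor=floor)
            if mode == "guide":
                no_rit = [i for i in ids if result.rit_calls.get(i, 0) == 0]
                if len(no_rit) >= 2:
                    entry["enrichment_no_rit"] = aggregate_enrichment(
                        [per_system[i] for i in no_rit], label="guide/no-RIT",
                        params=params, prob_floor=floor)
                entry["profile"] = pairing_profile(
                    [matches[l.id] for l in kept],
                    [len(l.upstream) for l in kept])
            result.helix[mode] = entry

    # ---- stage 5: duplex energies -------------------------------------
    if "energy" not in cfg.skip_stages and kept:
        nonredundant, _skipped = filter_redundant_tracrs(kept)
        if nonredundant:
            result.energy_records, result.energy = compare_cohort(nonredundant)

    # ---- stage 6: mechanisms ------------------------------------------
    if "mechanisms" not in cfg.skip_stages and kept:
        can_assign = ("mutations" not in cfg.skip_stages
                      and "rit" not in cfg.skip_stages
                      and "helix" not in cfg.skip_stages)
        if not can_assign and not cfg.mechanisms_without_energy:
            raise RuntimeError("mechanism assignment requires mutation, RIT and helix stages")
        if can_assign:
            for loc in kept:
                helix_calls = [
                    (result.helix[m]["per_system"][loc.id][0],
                     result.helix[m]["config_null"][loc.id])
                    for m in ("intra", "guide")]
                result.assignments.append(assign_mechanisms(
                    loc.id,
                    result.extra_mutation_counts.get(loc.id),
                    result.rit_calls.get(loc.id),
                    helix_calls))
            if result.assignments:
                result.venn = venn_summary(result.assignments)

    result.manifest = _manifest(cfg, cohort, result)
    if cfg.outdir:
        _write_artifacts(cfg, result)
    return result


def _manifest(cfg: RunConfig, cohort: CohortData, result: PipelineResult) -> dict:
    digest = hashlib.md5()
    for cid in sorted(cohort.contigs):
        digest.update(cohort.contigs[cid].residues.encode())
    return {
        "version": __version__,
        "seed": cfg.seed,
        "synth": asdict(cfg.synth) if cfg.synth else None,
        "helix_intra": asdict(cfg.helix_intra),
        "helix_guide": asdict(cfg.helix_guide),
        "n_shuffles_helix": cfg.n_shuffles_helix,
        "n_shuffles_rescue": cfg.n_shuffles_rescue,
        "input_digest": digest.hexdigest(),
        "counts": {
            "input_loci": len(cohort.loci),
            "kept": len(result.loci),
            "assigned": sum(1 for a in result.assignments if a.assigned),
        },
        "stages_skipped": list(cfg.skip_stages),
    }


def summary_report(result: PipelineResult) -> dict:
    """Consolidated machine-readable report (unrounded values)."""
    out: dict = {"n_loci": len(result.loci)}
    if result.mutation:
        out["mutation"] = {
            "focus_frac_mutated": result.mutation.focus_frac_mutated,
            "nonfocus_frac_mutated": result.mutation.nonfocus_frac_mutated,
            "n_arrays": result.mutation.n_arrays,
        }
    if result.rit_report:
        rr = dict(result.rit_report)
        rr["ratio_rounded"] = round(rr["observed_ratio"], 2)
        rr["percent"] = f"{round(100 * rr['observed_ratio']):d}%"
        out["rit"] = rr
    for mode, entry in result.helix.items():
        out[f"helix_{mode}_p"] = entry["enrichment_all"].aggregate_p
        if "enrichment_no_rit" in entry:
            out["helix_guide_no_rit_p"] = entry["enrichment_no_rit"].aggregate_p
    if result.energy:
        out["energy"] = {
            "n": result.energy.n,
            "median_extra": result.energy.median_extra,
            "median_consensus": result.energy.median_consensus,
            "p_value": result.energy.p_value,
        }
    if result.venn:
        out["venn"] = {"counts": result.venn.counts, "total": result.venn.total,
                       "assigned_fraction": result.venn.assigned_fraction,
                       "assigned_percent": f"{round(100 * result.venn.assigned_fraction):d}%"}
    return out


def _write_artifacts(cfg: RunConfig, result: PipelineResult) -> None:
    from .io import write_tsv

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(outdir / "qc_report.tsv",
              ["locus", "action", "upstream_len", "empirical_e", "reason"],
              [[r["locus"], r["action"], r["upstream_len"], r["empirical_e"], r["reason"]]
               for r in result.qc_rows])
    if result.mutation:
        write_tsv(outdir / "repeat_mutations.tsv",
                  ["locus", "repeat_index", "is_focus", "mutations", "positions"],
                  [[r.locus_id, r.repeat_index, int(r.is_focus), r.mutations,
                    ";".join(map(str, r.positions))]
                   for r in result.mutation.records])
        pos_rows = []
        for cls, table in (("focus", result.mutation.focus_positions),
                           ("nonfocus", result.mutation.nonfocus_positions)):
            for p in sorted(table):
                pos_rows.append([cls, p, table[p]])
        write_tsv(outdir / "mutation_positions.tsv",
                  ["class", "position", "count"], pos_rows)
    if result.helix:
        rows = []
        for mode, entry in result.helix.items():
            for lid, (has, q) in entry["per_system"].items():
                m = entry["matches"][lid]
                rows.append([lid, mode, int(has),
                             m.bp_count if m else 0, m.unpaired_count if m else "",
                             f"{m.arm_a[0]}-{m.arm_a[1]}" if m else "",
                             f"{m.arm_b[0]}-{m.arm_b[1]}" if m else "", q])
        write_tsv(outdir / "helix_systems.tsv",
                  ["locus", "mode", "has_helix", "bp", "unpaired", "arm_a", "arm_b",
                   "null_prob"], rows)
        if "profile" in result.helix.get("guide", {}):
            write_tsv(outdir / "pairing_profile.tsv", ["position", "frequency"],
                      [[i + 1, f] for i, f in enumerate(result.helix["guide"]["profile"])])
        enrich = {}
        for mode, entry in result.helix.items():
            for key in ("enrichment_all", "enrichment_test", "enrichment_no_rit"):
                if key in entry:
                    e = entry[key]
                    enrich[e.label] = {
                        "n_systems": e.n_systems, "n_with_helix": e.n_with_helix,
                        "expected": e.expected, "aggregate_p": e.aggregate_p,
                        "min_bp": e.params.min_bp, "max_unpaired": e.params.max_unpaired}
        (outdir / "enrichment.json").write_text(json.dumps(enrich, indent=1) + "\n")
    if result.rit_report:
        rr = result.rit_report
        write_tsv(outdir / "rit_report.tsv",
                  ["cohort", "avg_intergenic_len", "observed_rits", "systems_analyzed",
                   "ratio", "expected_ratio"],
                  [[rr["label"], round(rr["avg_intergenic_len"]), rr["observed_rits"],
                    rr["systems_analyzed"], round(rr["observed_ratio"], 2),
                    round(rr["expected_ratio"], 2)]])
    if result.energy_records:
        write_tsv(outdir / "duplex_energies.tsv",
                  ["locus", "energy_extra", "energy_consensus",
                   "length_extra", "length_consensus"],
                  [[r.locus_id, r.energy_extra, r.energy_consensus,
                    r.length_extra, r.length_consensus] for r in result.energy_records])
    if result.assignments:
        write_tsv(outdir / "mechanisms.tsv",
                  ["locus", "mutation", "rit", "helix", "assigned"],
                  [[a.locus_id, int(a.has_mutation_mechanism), int(a.has_rit_mechanism),
                    int(a.has_helix_mechanism), int(a.assigned)] for a in result.assignments])
    (outdir / "summary.json").write_text(json.dumps(summary_report(result), indent=1) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1) + "\n")
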