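"""End-to-end study-shaped workflow over the synthetic dataset.

simulate -> trim -> species screen -> iterative assembly (with simulated
PCR verification of problem regions) -> fixed-point check -> damage
profile -> pairwise comparison & annotation lift -> phylogenetic placement.

Every stage writes its artifact under the run directory and contributes to
one machine-readable ``summary.json``; identical configuration and seed
give an identical summary.  All thresholds actually applied are logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import yaml

from . import annotate as annot
from . import consensus as cns
from . import damageprof, mitocompare, phylo, simdata, speciesid
from .mapping import deduplicate, map_reads, trim_reads, EditDistanceSchedule, ReferenceIndex
from .mitogenome import build_study_genomes
from .seq import CircularSequence, write_fasta, write_fastq

log = logging.getLogger("paleomito")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the workflow; defaults are the study's stated settings."""

    seed: int = 17
    n_reads: int = 3851
    delta5: float = 0.3
    delta3: float = 0.3
    decay: float = 0.5
    seq_error: float = 0.002
    min_len: int = 20  # reads shorter than this are discarded after trimming
    species_min_len: int = 30  # perfect-match screen length threshold
    min_mapq: int = 25
    min_evidence: int = 2
    discordance: float = 0.25
    damage_window: int = 10
    adapter: str = simdata.DEFAULT_ADAPTER
    contamination: float = 0.0  # fraction of reads drawn from the divergent control
    bootstrap_reps: int = 1000
    outdir: str = "results/pipeline"

    def policy(self) -> cns.ConsensusPolicy:
        return cns.ConsensusPolicy(
            self.min_evidence, self.min_mapq, self.discordance, self.damage_window
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig(**yaml.safe_load(fh))


def project_to_frame(genome: CircularSequence, frame: CircularSequence) -> str:
    """Genome expressed on the frame's coordinates via global alignment.

    Frame positions deleted in the genome become '-'; genome insertions are
    dropped.  Equal-length co-linear genomes (substitution-only panels) are
    taken as already aligned.
    """
    if len(genome) == len(frame):
        return genome.seq
    row_f, row_g = mitocompare.global_alignment(frame.seq, genome.seq)
    out = []
    for x, y in zip(row_f, row_g):
        if x != "-":
            out.append(y if y != "-" else "-")
    return "".join(out)


def run_pipeline(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    policy = config.policy()
    summary: dict = {"config": dataclasses.asdict(config)}

    # --- stage 0: genomes and reads ---------------------------------------
    log.info("simulate: building study genomes (seed %d)", config.seed)
    genomes = build_study_genomes(config.seed)
    ref, ancient = genomes.ref, genomes.ancient
    frag = simdata.FragmentModel(min_len=config.min_len)
    dmg = simdata.DamageModel(config.delta5, config.delta3, config.decay, config.seq_error)
    reads, truth = simdata.simulate_reads(
        ancient, config.n_reads, frag, dmg, seed=config.seed + 11, id_prefix="sge"
    )
    if config.contamination > 0.0:
        cont_reads, _ = simdata.simulate_reads(
            genomes.contaminant,
            max(int(config.contamination * config.n_reads * 2), 10),
            frag,
            dmg,
            seed=config.seed + 13,
            id_prefix="cont",
        )
        reads, labels = simdata.mix_contaminants(
            [(reads, "ancient"), (cont_reads, "contaminant")],
            (1.0 - config.contamination, config.contamination),
            config.n_reads,
            seed=config.seed + 15,
        )
        truth.labels.update(labels)
    raw = simdata.with_adapter(reads, config.adapter, seed=config.seed + 17)
    write_fastq(raw, outdir / "reads_raw.fastq")
    simdata.truth_reads_to_tsv(truth, outdir / "truth_reads.tsv")
    simdata.variants_to_tsv(genomes.plan.records, outdir / "truth_variants.tsv")
    write_fasta([ref, ancient, *genomes.moderns, *genomes.outgroups.values()],
                outdir / "genomes.fasta")

    # --- stage 1: trimming -------------------------------------------------
    log.info("trim: adapter=%s... min_len=%d", config.adapter[:12], config.min_len)
    trimmed = trim_reads(raw, config.adapter, min_len=config.min_len)
    write_fastq(trimmed, outdir / "reads_trimmed.fastq")
    summary["trim"] = {"raw_reads": len(raw), "kept_reads": len(trimmed)}

    # --- stage 2: competitive species screen -------------------------------
    log.info("speciesid: perfect match, min_len=%d", config.species_min_len)
    screen_refs = [ref] + list(genomes.outgroups.values())
    report = speciesid.competitive_counts(trimmed, screen_refs, config.species_min_len)
    speciesid.report_to_tsv(report, outdir / "species_screen.tsv")
    human_screen = speciesid.competitive_counts(
        trimmed, [genomes.contaminant, ref], config.species_min_len
    )
    summary["species"] = {
        "counts": report.counts,
        "assigned": report.assigned,
        "human_like_reads": human_screen.counts["human_like"],
    }

    # --- stage 3: assembly with PCR verification ---------------------------
    log.info(
        "assemble: min_evidence=%d min_mapq=%d discordance=%.2f damage_window=%d",
        policy.min_evidence, policy.min_mapq, policy.discordance_threshold,
        policy.damage_window,
    )
    if not trimmed:
        raise PipelineError("assemble", "no reads after trimming: all positions zero_coverage")
    first = cns.assemble(trimmed, ref, (), policy)
    problem = sorted(
        set(
            [p - 1 for p in first.gap_positions]
            + [p - 1 for p in first.single_positions]
            + [p - 1 for p in first.no_consensus_positions]
        )
    )
    regions = cns.merge_positions(problem, gap=150, n=len(first.frame))
    regions += cns.indel_candidates(first.records, len(first.frame))
    regions = _merge_intervals(regions, gap=150)
    log.info("assemble: %d PCR verification regions", len(regions))
    pcr = simdata.simulate_pcr_fragments(
        ancient, first.frame, regions, seed=config.seed + 19
    )
    result = cns.assemble(trimmed, ref, pcr, policy)
    if result.round_stats["round2"]["unique_reads"] == 0:
        raise PipelineError("assemble", "zero_coverage at every position")
    consensus = result.consensus
    write_fasta([consensus], outdir / "consensus.fasta")
    cns.calls_to_tsv(result.calls, outdir / "consensus_calls.tsv")
    cns.intervals_to_bed(result.gap_positions, "gap", consensus.id, outdir / "gaps.bed")
    cns.intervals_to_bed(
        result.single_positions + result.no_consensus_positions,
        "verify", consensus.id, outdir / "verification.bed",
    )
    cns.stats_to_json(result, outdir / "assembly_stats.json")
    ok, discrepancies = cns.verify_fixed_point(trimmed, consensus, policy)
    summary["assembly"] = {
        "consensus_length": len(consensus),
        "gap_positions": len(result.gap_positions),
        "single_evidence_positions": len(result.single_positions),
        "no_consensus_positions": len(result.no_consensus_positions),
        "pcr_fragments": len(pcr),
        "fixed_point": bool(ok),
        "fixed_point_discrepancies": len(discrepancies),
    }

    # --- stage 4: final alignment, coverage, damage profile ----------------
    index = ReferenceIndex([consensus])
    final_records = deduplicate(
        map_reads(trimmed, index, EditDistanceSchedule.fraction(0.1))
    )
    uniq = [r for r in final_records if not r.duplicate]
    read_map = {r.id: r for r in trimmed}
    profile = damageprof.damage_profile(uniq, read_map, consensus)
    damageprof.profile_to_tsv(profile, outdir / "damage_profile.tsv")
    read_bases = sum(r.length for r in uniq)
    pcr_bases = sum(len(s) for _, s in pcr)
    coverage = speciesid.fold_coverage(read_bases + pcr_bases, len(consensus))
    summary["final_alignment"] = {
        "unique_reads": len({r.read_id for r in uniq}),
        "aligned_bases": int(profile.total_aligned),
        "mismatches": int(profile.total_mismatches),
        "identity_pct": round(profile.identity_percent(), 1),
        "fold_coverage": round(coverage, 1),
        "ct_5p_offset0": round(profile.freq("C>T", "5p", 0), 4),
        "ga_3p_offset0": round(profile.freq("G>A", "3p", 0), 4),
    }

    # --- stage 5: comparison, annotation, polymorphism classes -------------
    log.info("compare: consensus vs reference, annotation lift-over")
    lifted = annot.lift_annotations(consensus, ref)
    consensus.features = lifted.features
    annot.features_to_tsv(lifted.features, outdir / "consensus_features.tsv")
    diffs = mitocompare.pairwise_differences(consensus, ref)
    mitocompare.classify_against_annotation(diffs, consensus)
    mitocompare.differences_to_tsv(diffs, outdir / "differences.tsv")
    specific = mitocompare.specific_polymorphisms(diffs, consensus, genomes.moderns)
    mitocompare.differences_to_tsv(specific, outdir / "specific_polymorphisms.tsv")
    dloop_len = sum(f.length for f in lifted.features if f.type == "D-loop")
    ratio = mitocompare.region_rate_ratio(diffs, lifted.features, "D-loop", len(consensus))
    subs = [d for d in diffs if d.kind == "substitution"]
    cds_subs = [d for d in subs if d.codon_position]
    validations = [
        annot.validate_cds(f, consensus)
        for f in lifted.features
        if f.type == "CDS"
    ]
    summary["comparison"] = {
        "total_differences": len(diffs),
        "transitions": sum(d.ts_tv == "t" for d in subs),
        "transversions": sum(d.ts_tv == "v" for d in subs),
        "indels": sum(d.kind != "substitution" for d in diffs),
        "dloop_differences": sum(
            _in_feature(d, lifted.features, "D-loop") for d in diffs
        ),
        "dloop_length": dloop_len,
        "dloop_rate_ratio": round(ratio, 2) if ratio else None,
        "codon_position_counts": {
            k: sum(d.codon_position == k for d in cds_subs) for k in (1, 2, 3)
        },
        "aa_changes": sum(
            d.aa_change not in (None, "silent") for d in cds_subs
        ),
        "specific_polymorphisms": len(specific),
        "content": annot.genome_content_summary(lifted.features),
        "cds_all_valid": all(v.passed for v in validations),
    }

    # --- stage 6: phylogenetic placement -----------------------------------
    log.info("phylo: NJ + %d bootstrap replicates", config.bootstrap_reps)
    taxa: dict[str, str] = {"ancient": project_to_frame(consensus, ref), "bison_ref": ref.seq}
    for m in genomes.moderns:
        taxa[m.id] = project_to_frame(m, ref)
    for og in genomes.outgroups.values():
        taxa[og.id] = og.seq
    tree = phylo.bootstrap_support(taxa, config.bootstrap_reps, seed=config.seed + 23)
    (outdir / "tree.nwk").write_text(tree.newick() + "\n")
    modern_clade = ["bison_ref"] + [m.id for m in genomes.moderns]
    summary["phylo"] = {
        "modern_clade_support": phylo.clade_support(tree, modern_clade),
        "bison_plus_ancient_support": phylo.clade_support(
            tree, modern_clade + ["ancient"]
        ),
        "newick": tree.newick(),
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _in_feature(diff, features, ftype: str) -> bool:
    return any(
        f.type == ftype and f.start <= diff.position <= f.end for f in features
    )


def _merge_intervals(intervals, gap: int):
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]
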