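"""Simulate the study-shaped dataset: an annotated reference mitogenome, an
ancient template carrying the full polymorphism profile (105 transitions,
6 transversions, a 1 bp control-region insertion, a 2 bp tRNA-Ser
deletion), a modern conspecific panel, outgroups, and 3,851 damaged
short-fragment reads padded to instrument length by adapter read-through.

Writes genomes, raw reads and truth tables under the run directory.
"""

from common import driver_args

from paleomito.annotate import features_to_tsv, genome_content_summary
from paleomito.mitogenome import build_study_genomes
from paleomito.pipeline import PipelineConfig
from paleomito.seq import write_fasta, write_fastq
from paleomito import simdata


def main() -> None:
    args = driver_args(__doc__)
    cfg = PipelineConfig(seed=args.seed)
    g = build_study_genomes(cfg.seed)
    frag = simdata.FragmentModel(min_len=cfg.min_len)
    dmg = simdata.DamageModel(cfg.delta5, cfg.delta3, cfg.decay, cfg.seq_error)
    reads, truth = simdata.simulate_reads(
        g.ancient, cfg.n_reads, frag, dmg, seed=cfg.seed + 11, id_prefix="sge"
    )
    raw = simdata.with_adapter(reads, cfg.adapter, seed=cfg.seed + 17)

    write_fasta([g.ref, g.ancient, *g.moderns, *g.outgroups.values(), g.contaminant],
                args.dir / "genomes.fasta")
    features_to_tsv(g.ref.features, args.dir / "reference_features.tsv")
    write_fastq(raw, args.dir / "reads_raw.fastq")
    simdata.truth_reads_to_tsv(truth, args.dir / "truth_reads.tsv")
    simdata.variants_to_tsv(g.plan.records, args.dir / "truth_variants.tsv")

    n_ts = sum(r.ts_tv == "t" for r in g.plan.records)
    n_tv = sum(r.ts_tv == "v" for r in g.plan.records)
    print(f"reference: {len(g.ref)} bp, {genome_content_summary(g.ref.features)}")
    print(f"ancient template: {len(g.ancient)} bp")
    print(f"planted events: {len(g.plan.records)} "
          f"({n_ts} transitions, {n_tv} transversions, 2 indels)")
    print(f"reads: {len(raw)} (mean fragment {frag.mean_length():.1f} nt, "
          f"delta5=delta3={cfg.delta5}, decay={cfg.decay}, error={cfg.seq_error})")
    print(f"-> {args.dir}")


if __name__ == "__main__":
    main()
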