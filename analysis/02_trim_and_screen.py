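"""Trim adapters, drop fragments shorter than 20 nt, and run the
competitive species screen: perfectly matching reads of >= 30 nt counted
against the conspecific reference and three related outgroup mitogenomes,
plus a human-like contamination control.  The sample should assign to the
conspecific reference by a wide margin, with the outgroup counts explained
by locally identical windows (overlap columns of the report).
"""

from common import driver_args

from paleomito.mapping import trim_reads
from paleomito.mitogenome import build_study_genomes
from paleomito.pipeline import PipelineConfig
from paleomito.seq import read_fastq, write_fastq
from paleomito.speciesid import competitive_counts, report_to_tsv


def main() -> None:
    args = driver_args(__doc__)
    cfg = PipelineConfig(seed=args.seed)
    g = build_study_genomes(cfg.seed)
    raw = read_fastq(args.dir / "reads_raw.fastq")
    trimmed = trim_reads(raw, cfg.adapter, min_len=cfg.min_len)
    write_fastq(trimmed, args.dir / "reads_trimmed.fastq")
    print(f"trimmed: kept {len(trimmed)}/{len(raw)} reads (min length {cfg.min_len})")

    screen_refs = [g.ref] + list(g.outgroups.values())
    report = competitive_counts(trimmed, screen_refs, cfg.species_min_len)
    report_to_tsv(report, args.dir / "species_screen.tsv")
    print(report.summary())

    human = competitive_counts(trimmed, [g.contaminant, g.ref], cfg.species_min_len)
    print(f"human-like contamination screen: {human.counts['human_like']} reads")


if __name__ == "__main__":
    main()
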