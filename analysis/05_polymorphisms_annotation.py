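"""Compare the assembled genome to the reference and classify every
difference: transition/transversion, feature context, codon position,
amino-acid effect; lift the reference annotation onto the consensus and
validate all 13 coding sequences; count the polymorphisms specific to the
ancient genome (absent from every modern panel genome); and measure the
control-region rate excess.
"""

from common import driver_args

from paleomito import annotate as an
from paleomito import mitocompare as mc
from paleomito.mitogenome import build_study_genomes
from paleomito.seq import read_fasta


def main() -> None:
    args = driver_args(__doc__)
    g = build_study_genomes(args.seed)
    consensus = read_fasta(args.dir / "consensus.fasta")[0]

    lifted = an.lift_annotations(consensus, g.ref)
    consensus.features = lifted.features
    an.features_to_tsv(lifted.features, args.dir / "consensus_features.tsv")
    an.features_to_gff3(lifted.features, consensus.id, args.dir / "consensus_features.gff3")

    diffs = mc.pairwise_differences(consensus, g.ref)
    mc.classify_against_annotation(diffs, consensus)
    mc.differences_to_tsv(diffs, args.dir / "differences.tsv")
    specific = mc.specific_polymorphisms(diffs, consensus, g.moderns)
    mc.differences_to_tsv(specific, args.dir / "specific_polymorphisms.tsv")

    subs = [d for d in diffs if d.kind == "substitution"]
    cds = [d for d in subs if d.codon_position]
    dloop = [f for f in lifted.features if f.type == "D-loop"][0]
    in_dloop = sum(dloop.start <= d.position <= dloop.end for d in diffs)
    ratio = mc.region_rate_ratio(diffs, lifted.features, "D-loop", len(consensus))

    print(f"{len(diffs)} differences vs the reference: "
          f"{sum(d.ts_tv == 't' for d in subs)} transitions, "
          f"{sum(d.ts_tv == 'v' for d in subs)} transversions, "
          f"{sum(d.kind != 'substitution' for d in diffs)} indels")
    print(f"control region: {in_dloop} differences in {dloop.length} nt "
          f"(rate ratio {ratio:.1f}x the rest of the genome)")
    print(f"coding: {len(cds)} substitutions at codon positions "
          f"{[sum(d.codon_position == k for d in cds) for k in (1, 2, 3)]}, "
          f"{sum(d.aa_change not in (None, 'silent') for d in cds)} amino-acid changes")
    print(f"specific polymorphisms (absent from {len(g.moderns)} modern genomes): "
          f"{len(specific)}")
    validations = [an.validate_cds(f, consensus) for f in lifted.features if f.type == "CDS"]
    bad = [v for v in validations if not v.passed]
    print(f"annotation: {an.genome_content_summary(lifted.features)}; "
          f"CDS validation: {len(validations) - len(bad)}/{len(validations)} pass")
    changed = [f.name for f in lifted.features if f.length_changed]
    print(f"length-changed features: {changed}")


if __name__ == "__main__":
    main()
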