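"""Phylogenetic placement of the ancient genome: K2P distances over the
projected whole-genome alignment, neighbor-joining, 1000 bootstrap
replicates.  The expectation mirroring the study is that the ancient
genome is basal to the modern conspecific clade, and that the clade of
(ancient + all moderns) is recovered with full support against the
outgroups.
"""

from common import driver_args

from paleomito import phylo
from paleomito.mitogenome import build_study_genomes
from paleomito.pipeline import project_to_frame
from paleomito.seq import read_fasta


def main() -> None:
    args = driver_args(__doc__)
    g = build_study_genomes(args.seed)
    consensus = read_fasta(args.dir / "consensus.fasta")[0]

    taxa = {"ancient": project_to_frame(consensus, g.ref), "bison_ref": g.ref.seq}
    for m in g.moderns:
        taxa[m.id] = project_to_frame(m, g.ref)
    for og in g.outgroups.values():
        taxa[og.id] = og.seq

    tree = phylo.bootstrap_support(taxa, 1000, seed=args.seed + 23)
    (args.dir / "tree.nwk").write_text(tree.newick() + "\n")

    moderns = ["bison_ref"] + [m.id for m in g.moderns]
    print(tree.newick())
    print(f"modern clade support (ancient excluded): "
          f"{phylo.clade_support(tree, moderns):.0f}%")
    print(f"ancient + modern clade support: "
          f"{phylo.clade_support(tree, moderns + ['ancient']):.0f}%")


if __name__ == "__main__":
    main()
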