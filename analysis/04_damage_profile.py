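"""Misincorporation profile of the unique reads against the consensus: the
12 substitution frequencies by distance from each read end.  Authentic
post-mortem damage shows as C->T inflation at 5' offsets and G->A at 3'
offsets decaying into the read; all other types stay at the sequencing
error floor.  Also reports the global read-vs-consensus identity.
"""

from common import driver_args

from paleomito.damageprof import damage_profile, plot_profile, profile_to_tsv
from paleomito.mapping import EditDistanceSchedule, ReferenceIndex, deduplicate, map_reads
from paleomito.seq import read_fasta, read_fastq


def main() -> None:
    args = driver_args(__doc__)
    consensus = read_fasta(args.dir / "consensus.fasta")[0]
    reads = read_fastq(args.dir / "reads_trimmed.fastq")
    records = deduplicate(
        map_reads(reads, ReferenceIndex([consensus]), EditDistanceSchedule.fraction(0.1))
    )
    uniq = [r for r in records if not r.duplicate]
    profile = damage_profile(uniq, {r.id: r for r in reads}, consensus)
    profile_to_tsv(profile, args.dir / "damage_profile.tsv")
    try:
        plot_profile(profile, args.dir / "damage_profile.png")
    except ImportError:
        pass

    print(f"unique reads: {len({r.read_id for r in uniq})}")
    print(f"identity: {profile.identity_percent():.1f}% "
          f"({profile.total_mismatches} mismatches / {profile.total_aligned} bases)")
    print("offset   C>T(5')   G>A(3')")
    for k in range(5):
        print(f"{k:6d}   {profile.freq('C>T', '5p', k):7.3f}   "
              f"{profile.freq('G>A', '3p', k):7.3f}")


if __name__ == "__main__":
    main()
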