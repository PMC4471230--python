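# Methods

This note documents the models, rules and numerical choices behind
paleomito, and what the synthetic experiments do and do not establish.

## The assembly problem and its evidence model

The target is a circular mitochondrial genome reconstructed from short,
damaged single-end reads against the reference of a related species. All
read alignment is ungapped: with gap opening disabled, an alignment is a
placement (start, strand) plus a Hamming mismatch count, which keeps every
placement enumerable and exactly testable against a brute-force scan.
Circularity is handled by scanning the doubled reference and reducing
start positions modulo the genome length; reads longer than the genome are
rejected.

Three mismatch-bound schedules are supported. The *fractional* schedule
reproduces the BWA rule with its default 2% base-error constant: the bound
for a read of length L is the smallest k with P(X > k) < n for
X ~ Poisson(0.02·L). With n = 0.1 this yields 1 mismatch for 20–26 nt
reads, 2 for 27–55, 3 for 56–87 and 4 for 88–101 — the two endpoint
anchors are asserted in the test suite. The *absolute* schedule (n = 2) is
used for the first pass against the heterospecific reference; *perfect*
(0 mismatches) for the competitive species screen.

Mapping quality is a deliberate proxy, not a BWA emulation: 37 when the
best placement is unique and no other placement is within one mismatch,
25 when unique but a next-best placement exists at best+1, 0 when the best
count is tied. Downstream, only the operative distinction matters: MQ ≥ 25
means "confidently unique" and admits the read as consensus evidence.
Duplicates are collapsed on (reference, start, end, strand) — standard
PCR-duplicate semantics — before the mapping-quality filter.

### Consensus calling

A column is called when at least `min_evidence = 2` concordant unique
evidences support a strict-majority base; evidence units are unique reads
passing the MQ filter and PCR consensus sequences (one unit each,
MQ-exempt). Ties yield no consensus. When the minority fraction exceeds
`discordance_threshold = 0.25` the column is flagged, with two mechanized
escape hatches replacing what would otherwise be manual review:

* **Damage resolution** — if every minority observation, expressed in its
  read's own orientation, is a G→A within `damage_window = 10` nt of the
  read's 3′ end or a C→T within the window of its 5′ end, the majority
  stands (`resolved_damage`). Reverse-strand reads are complemented before
  the check, so the two mirrored signatures are treated symmetrically.
* **PCR adjudication** — a column still flagged (or supported by a single
  read) whose PCR evidences number ≥ `min_evidence` and agree takes the
  PCR base. This encodes the practice of settling discordant or
  single-read positions by amplifying and cloning the region: the clone
  consensus, not the shotgun read, is authoritative there.

Assembly runs in three rounds: (1) map to the related reference under the
absolute bound, deduplicate, call a provisional consensus — uncalled
positions fall back to the reference base so round-2 coordinates stay
stable, and single-evidence positions carry their read's base forward for
the same reason; (2) remap everything to the provisional consensus under
the fractional bound and re-call; (3) place PCR sequences on the
provisional frame with a gapped infix alignment (edlib) and integrate
them. Gap columns in a PCR placement become deletion evidence ('-' in the
column vote; a '-' majority removes the position), and extra PCR bases
become insertion evidence, accepted at ≥ `min_evidence` concordant
placements. Ungapped reads can never call an indel; length differences
enter exclusively through PCR evidence, which is why indel territory must
reach the PCR round.

### Indel candidates

An indel in the template leaves a characteristic void in ungapped
coverage: no read alignment spans the locus with a margin on both sides
(a read crossing with m overhang bases accrues ~0.75·m mismatches and
exceeds any bound), while both flanks stay covered and alignment
boundaries pile up on either side. The detector flags positions with zero
margin-6 spanning alignments between covered flanks (or ≤1 spanning
alignment with ≥4 clustered ends on both sides) and merges them into
verification regions. False positives cost only a redundant PCR region;
a missed locus would cost the indel, so the thresholds favour recall.

### Fixed point

After assembly, all reads are re-aligned to the final consensus and
re-called; the assembly is accepted when every re-called position
reproduces the consensus base. On clean simulations this holds by
construction; the test suite also confirms that a single corrupted base
is detected at exactly its position.

## Damage model and profiling

Damage is applied on the read strand after fragmentation: C→T at 5′
offset k with probability δ₅·λᵏ, G→A at 3′ offset k with δ₃·λᵏ, plus a
uniform per-base error that always changes the base. A single-parameter
geometric decay is the simplest generative model reproducing the
canonical misincorporation shape; the profiling module recovers δ·λᵏ
within binomial error at each offset, which is the round-trip the tests
assert at n = 10,000 reads.

Defaults: δ₅ = δ₃ = 0.3, λ = 0.5, sequencing error 0.002, fragment
lengths truncated-geometric on [20, 101] with decay 0.966 (mean ≈ 43 nt).
These are realistic values for a Pleistocene bone library, chosen once:
with a mean fragment of ~43 nt they imply an expected read-vs-consensus
mismatch rate of 0.3/43.3 + 0.002 ≈ 0.89%, i.e. ~99.1% identity, matching
the accounting a real library of this type shows. Damage rates are free
parameters of the generator, not estimates fitted to any dataset.

The profile tallies mismatches by substitution type (reference→read, in
read orientation; reverse-strand placements complemented and flipped) and
by offset from each end, K = 10 offsets per end; frequencies are
normalised per occurrence of the source base at that offset. Reads
shorter than 2K contribute each position to its nearer end only (tie →
5′), so nothing is double-counted.

## Comparison, annotation, phylogenetics

Genome pairs are aligned globally with free end gaps and affine costs
(match +1, mismatch −1, open −4, extend −1; Biopython's PairwiseAligner
behind the module surface). On >99%-identity mitogenomes any sensible
scheme yields the same event list; an independent plain-DP oracle in the
tests pins the contract on small cases, and planted-variant round trips
pin it at genome scale. Each substitution and each contiguous indel run is
one difference record; a multi-nt indel counts as one event. The planted
events are placed so no gap can slide (flanking bases distinct from run
edges), making the round trip exact rather than merely score-equivalent.

Annotation lift-over maps feature boundaries through the same alignment;
a boundary landing in a target gap snaps inward (start right, end left),
never extending a feature into unaligned territory; features whose length
changed are flagged and fully deleted features are reported. CDS
validation uses the vertebrate mitochondrial code: starts ATG/ATA/ATT/GTG,
stops TAA/TAG/AGA/AGG, and bare T/TA terminal remainders accepted as
polyadenylation-completed incomplete stops (flagged). AGA/AGG internal
codons fail validation — they are stops in this code.

Distances are Kimura-2-parameter with pairwise deletion of gap/N sites;
saturated pairs return an undefined marker (bootstrap replicates
substitute a large finite distance so a replicate never aborts). The
distance stage substitutes K2P for composite-likelihood and
likelihood-based stages deliberately: the quantity under test is the
topological placement of the ancient genome, on which these methods agree
in this data regime. Neighbor joining is the Saitou–Nei algorithm with the
standard Q-criterion and deterministic tie-breaking by taxon label, exact
on additive matrices (asserted against enumerated topologies and an
independent implementation). Bootstrap resamples alignment columns —
implemented as multinomial draws over compressed site patterns — and maps
split frequencies onto the point tree rather than building a majority-rule
consensus, which is sufficient for a placement question.

## The synthetic study profile

`mitogenome.build_study_genomes` constructs the full experimental cast
from one seed: a 16,319 bp annotated reference with the standard
mammalian complement (13 CDS, 22 tRNA, 2 rRNA, 909 nt control region);
an ancient template differing by a fixed profile — 105 transitions and
6 transversions (73 coding substitutions at codon positions 16/3/54, of
which 11 change the amino acid; 24 in the control region; 14 in RNA
genes), a 1 bp control-region insertion and a 2 bp deletion at the end of
a serine tRNA, giving a 16,318 bp genome with 25 control-region
differences; a modern panel carrying 20 of the ancient alleles (19
substitutions plus the short tRNA-Ser allele), leaving 93
ancient-specific polymorphisms; and outgroups derived from an ancestral
sequence that retains the ancient allele at the modern-derived sites, so
the ancient genome is basal to the modern clade with the
(ancient + moderns) clade supported against the outgroups. Coding changes
are drawn from codon families in which the planted class is guaranteed:
third-position transitions are universally silent in the vertebrate
mitochondrial code, CTN/TTR first-position transitions are silent leucine
exchanges, GTN→ATN and GCN→GTN are stop-free missense changes.

Problem sizes: 3,851 simulated reads (~10.3× read coverage of the 16.3 kb
genome), 5 modern panel genomes, 3 outgroups, 1000 bootstrap replicates
in the acceptance script (300 in the test suite); property tests run on
0.3–2 kb toy genomes. The pipeline's wet-lab PCR step is emulated by
amplifying the true template over the regions the assembly itself flags,
three amplifications per region — the product consensus reflects the
sample, not the provisional assembly.

What passing does and does not show: the generator has no PCR
amplification bias, no indel sequencing errors, no base-quality model, no
reference bias beyond the planted divergence, and its "microbial
background" is only whatever contaminant genomes the user supplies. Exact
recovery of the planted genome therefore demonstrates the correctness of
the evidence rules and the end-to-end bookkeeping, not robustness to
every failure mode of real ancient libraries (tandem-repeat D-loop
indels, heteroplasmy, nuclear mitochondrial insertions).

## Degenerate inputs and edge rules

Empty read sets assemble to all-gap output and verify vacuously; a
majority tie is no consensus; N counts as a mismatch everywhere (two Ns
mismatch each other); substitutions involving N carry an undefined ts/tv
class and codons containing N translate to an undetermined amino acid;
homologous-locus matching for panel-specificity is by exact position for
substitutions and by position-and-kind for indels; the final consensus is
reported on a linear frame starting at the reference's position 1 and
flagged circular. Wrap-around features are not modelled (the synthetic
layout starts the frame at a feature boundary).

## Known limitations

Ungapped mapping cannot place reads across template indels, so indel
recovery depends entirely on the PCR round reaching the locus; the
indel-candidate detector is heuristic and tuned for ~10× coverage.
The mapping-quality proxy ignores base qualities. The free-end-gap
aligner may express a deletion within reach of a sequence end as end
trimming instead of an internal gap — immaterial for full-length
mitogenome pairs, visible on contrived fragments. Bootstrap supports are
attached to point-tree splits only.
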