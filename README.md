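# paleomito

Damage-aware, reference-guided assembly and analysis of ancient
mitochondrial genomes — built for the situation a paleogenomicist faces
with a subfossil bone extract: a shotgun library dominated by environmental
DNA, endogenous fragments of 20–101 nt carrying terminal deamination
damage, and no conspecific reference, only the mitogenome of a related
extant species.

The package implements the complete computational workflow as a tested
library with a CLI, and ships a fully ground-truthed synthetic
ancient-read generator so that every stage — and the workflow end to end —
is verifiable without any external data.

## What it does

- **Read simulation** (`simdata`): fragments with a short-favouring length
  distribution, strand-symmetric terminal damage (C→T at 5′ offset *k* and
  G→A at 3′ offset *k*, each Bernoulli(δ·λ<sup>k</sup>)), uniform
  sequencing error, adapter read-through, planted polymorphisms with a
  transitional bias, contamination mixtures — all with truth tables.
- **Mapping** (`mapping`): ungapped alignment of reads to circular
  references under BWA-equivalent bounded-mismatch semantics. The
  fractional rule returns the smallest *k* with
  P(X &gt; k) &lt; n for X ~ Poisson(0.02·L) — 1 mismatch for 20–26 nt reads
  up to 4 for 88–101 nt. Includes adapter trimming, duplicate collapsing,
  and a mapping-quality score (37 unique / 25 unique-but-close / 0 tied).
- **Species screen** (`speciesid`): competitive perfect-match assignment
  among candidate mitogenomes (≥30 nt reads), in-silico PCR, clone
  classification by Hamming distance, and fold-coverage arithmetic.
- **Consensus assembly** (`consensus`): the central algorithm. Three
  rounds: map to the related reference (−n 2), remap to the provisional
  consensus (−n 0.1), then integrate PCR evidence. A base is called from
  ≥2 concordant unique evidences with MQ ≥ 25; columns with &gt;25%
  minority are flagged unless every minority observation is terminal
  G→A/C→T damage (then resolved to the majority), or adjudicated by ≥2
  concordant PCR evidences. Ends with a fixed-point verification:
  re-aligning all reads to the final consensus must reproduce it.
- **Damage profiling** (`damageprof`): the 12 mismatch frequencies by
  distance from each read end, plus global read-vs-consensus identity.
- **Genome comparison** (`mitocompare`): end-free affine global alignment,
  per-event difference records (ts/tv, feature, codon position, amino-acid
  effect under the vertebrate mitochondrial code), panel-specific
  polymorphisms, regional rate ratios.
- **Annotation** (`annotate`): lift-over of a feature table through the
  alignment with boundary snapping, CDS validation (ATG/ATA/ATT/GTG
  starts, AGA/AGG/TAA/TAG stops, T/TA incomplete stops).
- **Phylogenetics** (`phylo`): Kimura-2-parameter distances
  (d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)), Saitou–Nei neighbor joining (exact on
  additive matrices), and site-resampling bootstrap supports.

## Worked example

The numbered drivers under `analysis/` run the study-shaped workflow on
the synthetic dataset (a 16,319 bp annotated reference, an "ancient"
template carrying 105 transitions, 6 transversions, a 1 bp control-region
insertion and a 2 bp tRNA-Ser deletion, a 5-genome modern panel, and
outgroups):

```bash
python analysis/01_simulate_dataset.py   # 3,851 damaged reads + truth
python analysis/02_trim_and_screen.py
python analysis/03_assemble_consensus.py
python analysis/04_damage_profile.py
python analysis/05_polymorphisms_annotation.py
python analysis/06_phylogeny.py
```

Output of the assembly and comparison stages (seed 17):

```
after reads-only rounds: 0 gap, 6 single-evidence, 9 discordant positions
PCR verification: 5 regions
consensus: 16318 bp, 10.3-fold evidence coverage, 3757 unique reads + 15 PCR fragments
matches the true template exactly: True
fixed point: True (0 discrepancies)

113 differences vs the reference: 105 transitions, 6 transversions, 2 indels
control region: 25 differences in 910 nt (rate ratio 4.8x the rest of the genome)
coding: 73 substitutions at codon positions [16, 3, 54], 11 amino-acid changes
specific polymorphisms (absent from 5 modern genomes): 93
annotation: {'tRNA': 22, 'rRNA': 2, 'CDS': 13, 'D-loop': 1}; CDS validation: 13/13 pass
```

Reading this: the 16,318 bp consensus recovered every planted event —
damage (26–27% terminal misincorporation, visible in stage 04) never
leaked into a called base; the two indels, invisible to ungapped mapping,
entered through the PCR round; and the fixed-point check closed the loop.
Stage 06 places the ancient genome outside the modern clade with 100%
bootstrap support (1000 replicates).

The same workflow is available as one command (`paleomito run`) and as
individual subcommands (`paleomito simdata|map|speciesid|assemble|damage|
compare|annotate|phylo|insilico-pcr`) for real FASTA/FASTQ inputs.

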