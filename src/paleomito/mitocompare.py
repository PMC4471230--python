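"""Pairwise mitogenome comparison and polymorphism classification.

Two near-identical (>90%) organellar genomes are globally aligned with free
end gaps and affine gap costs (match +1, mismatch -1, open -4, extend -1);
each substitution and each contiguous indel run is emitted as one
:class:`DifferenceRecord`, positioned on the first genome's frame (1-based).
Records are then classified against a feature annotation: feature context,
codon position, and amino-acid effect under the vertebrate mitochondrial
genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align
from Bio.Data import CodonTable

from .seq import CircularSequence, revcomp

TRANSITIONS = {frozenset("AG"), frozenset("CT")}

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

MITO_START_CODONS = ("ATG", "ATA", "ATT", "GTG")
MITO_STOP_CODONS = ("TAA", "TAG", "AGA", "AGG")

#: feature precedence for assigning a difference to a single context
FEATURE_PRECEDENCE = {"CDS": 0, "tRNA": 1, "rRNA": 1, "D-loop": 2}


def translate_codon(codon: str) -> str:
    """One codon -> one-letter amino acid ('*' for a stop) under the
    vertebrate mitochondrial code."""
    codon = codon.upper()
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table.get(codon, "X")  # X: undetermined (N base)


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in TRANSITIONS


def _ts_tv(a: str, b: str):
    if a not in "ACGT" or b not in "ACGT":
        return None  # substitution involving N: class undetermined
    return "t" if is_transition(a, b) else "v"


@dataclass
class DifferenceRecord:
    """One substitution or contiguous indel between two genomes.

    ``position`` is 1-based on genome A; for an insertion (bases present in B
    only) it is the A position after which the bases insert.  ``ts_tv`` is
    't'/'v' for substitutions, None otherwise.
    """

    position: int
    kind: str  # substitution | insertion | deletion
    base_a: str
    base_b: str
    context_a: str = ""
    context_b: str = ""
    ts_tv: Optional[str] = None
    feature: Optional[str] = None
    strand: Optional[str] = None
    codon_position: Optional[int] = None
    aa_change: Optional[str] = None  # e.g. "I/V", "silent", or None


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -5  # -4 open + -1 first extension
    al.extend_gap_score = -1
    # free end gaps
    al.open_end_insertion_score = 0
    al.extend_end_insertion_score = 0
    al.open_end_deletion_score = 0
    al.extend_end_deletion_score = 0
    return al


def global_alignment(a: str, b: str) -> tuple[str, str]:
    """End-free affine global alignment; returns the two gapped rows."""
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _identity(row_a: str, row_b: str) -> float:
    """Matched columns over the shorter sequence length: near 1 for
    homologous organellar genomes, near 0 for unrelated input (a free
    end-gap alignment of unrelated sequences aligns almost nothing)."""
    matched = sum(
        x == y for x, y in zip(row_a, row_b) if x != "-" and y != "-"
    )
    shorter = min(len(row_a.replace("-", "")), len(row_b.replace("-", "")))
    return matched / shorter if shorter else 0.0


def pairwise_differences(
    a: CircularSequence, b: CircularSequence
) -> list[DifferenceRecord]:
    """All differences between two genomes of the same locus.

    Raises ``ValueError`` when the alignment is degenerate (<50% identity),
    which indicates the inputs are not the same locus.
    """
    row_a, row_b = global_alignment(a.seq, b.seq)
    if _identity(row_a, row_b) < 0.5:
        raise ValueError("degenerate alignment (<50% identity): not the same locus")
    records: list[DifferenceRecord] = []
    pos_a = 0  # 1-based position of the most recent A base
    i = 0
    n = len(row_a)
    while i < n:
        x, y = row_a[i], row_b[i]
        if x != "-" and y != "-":
            pos_a += 1
            if x != y:
                records.append(
                    DifferenceRecord(
                        position=pos_a,
                        kind="substitution",
                        base_a=x,
                        base_b=y,
                        context_a=_context(a.seq, pos_a - 1),
                        context_b=y,
                        ts_tv=_ts_tv(x, y),
                    )
                )
            i += 1
        elif x == "-":
            # run of bases present only in B: insertion (A gains nothing)
            j = i
            ins = []
            while j < n and row_a[j] == "-":
                ins.append(row_b[j])
                j += 1
            records.append(
                DifferenceRecord(
                    position=pos_a,
                    kind="insertion",
                    base_a="-",
                    base_b="".join(ins),
                    context_a=_context(a.seq, pos_a - 1),
                )
            )
            i = j
        else:
            # run of bases present only in A: deletion in B
            j = i
            dele = []
            start_pos = pos_a + 1
            while j < n and row_b[j] == "-":
                dele.append(row_a[j])
                pos_a += 1
                j += 1
            records.append(
                DifferenceRecord(
                    position=start_pos,
                    kind="deletion",
                    base_a="".join(dele),
                    base_b="-",
                    context_a=_context(a.seq, start_pos - 1),
                )
            )
            i = j
    records.sort(key=lambda r: (r.position, r.kind))
    return records


def _context(seq: str, idx0: int, flank: int = 2) -> str:
    lo = max(0, idx0 - flank)
    return seq[lo : idx0 + flank + 1]


# ---------------------------------------------------------------------------
# Annotation-aware classification
# ---------------------------------------------------------------------------

def _feature_at(features, pos: int):
    """Feature containing 1-based ``pos``, resolved by precedence
    CDS > tRNA/rRNA > D-loop."""
    hits = [f for f in features if f.start <= pos <= f.end]
    if not hits:
        return None
    hits.sort(key=lambda f: FEATURE_PRECEDENCE.get(f.type, 9))
    return hits[0]


def classify_against_annotation(
    diffs: Sequence[DifferenceRecord],
    genome: CircularSequence,
    features: Optional[Sequence] = None,
) -> list[DifferenceRecord]:
    """Fill feature / strand / codon-position / amino-acid fields in place.

    ``diffs`` must be positioned on ``genome``'s frame.  Codon arithmetic
    follows the CDS frame and strand; amino acids use the vertebrate
    mitochondrial code.
    """
    feats = list(features) if features is not None else genome.features
    n = len(genome)
    for rec in diffs:
        if not (1 <= rec.position <= n):
            raise ValueError(f"difference position {rec.position} outside genome")
        feat = _feature_at(feats, rec.position)
        if feat is None:
            rec.feature = "intergenic"
            rec.strand = None
            continue
        rec.feature = feat.name
        rec.strand = feat.strand
        if feat.type != "CDS" or rec.kind != "substitution":
            continue
        if feat.strand == "+":
            offset = (rec.position - feat.start) % 3
            codon_start = rec.position - offset  # 1-based
            codon = genome.seq[codon_start - 1 : codon_start + 2]
            within = offset
            ref_base, alt_base = rec.base_a, rec.base_b
        else:
            offset = (feat.end - rec.position) % 3
            codon_end = rec.position + offset
            codon = revcomp(genome.seq[codon_end - 3 : codon_end])
            within = offset
            ref_base = revcomp(rec.base_a)
            alt_base = revcomp(rec.base_b)
        rec.codon_position = within + 1
        if len(codon) != 3:
            continue  # truncated terminal codon: no amino-acid call
        assert codon[within] == ref_base
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_a = translate_codon(codon)
        aa_b = translate_codon(alt_codon)
        if "X" in (aa_a, aa_b):
            rec.aa_change = None  # undetermined: ambiguous base in the codon
        else:
            rec.aa_change = "silent" if aa_a == aa_b else f"{aa_a}/{aa_b}"
    return list(diffs)


# ---------------------------------------------------------------------------
# Panel-specific polymorphisms
# ---------------------------------------------------------------------------

def specific_polymorphisms(
    target_diffs: Sequence[DifferenceRecord],
    target: CircularSequence,
    panel: Sequence[CircularSequence],
) -> list[DifferenceRecord]:
    """Differences whose target allele is absent from every panel genome.

    A record is *shared* (hence dropped) when some panel genome carries the
    target's allele at the homologous locus, i.e. when the target-vs-panel
    comparison shows no difference there.
    """
    if not panel:
        return list(target_diffs)
    # loci at which target and panel genome differ, per panel genome
    panel_loci: list[set] = []
    for p in panel:
        diffs_p = pairwise_differences(target, p)
        loci = set()
        for r in diffs_p:
            if r.kind == "substitution":
                loci.add(("sub", r.position))
            else:
                loci.add(("indel", r.position))
        panel_loci.append(loci)
    retained = []
    for rec in target_diffs:
        key = (
            ("sub", rec.position)
            if rec.kind == "substitution"
            else ("indel", rec.position)
        )
        if all(key in loci for loci in panel_loci):
            retained.append(rec)
    return retained


# ---------------------------------------------------------------------------
# Regional rate ratio
# ---------------------------------------------------------------------------

def region_rate_ratio(
    diffs: Sequence[DifferenceRecord],
    features: Sequence,
    region_name: str,
    genome_length: int,
) -> Optional[float]:
    """(differences per nt inside the region) / (per nt outside).

    Returns None (undefined) when there are no out-of-region differences.
    """
    regions = [f for f in features if f.name == region_name or f.type == region_name]
    if not regions:
        raise ValueError(f"region {region_name!r} not in annotation")
    length_in = sum(f.end - f.start + 1 for f in regions)
    length_out = genome_length - length_in
    inside = sum(
        any(f.start <= r.position <= f.end for f in regions) for r in diffs
    )
    outside = len(diffs) - inside
    if outside == 0 or length_out == 0:
        return None
    return (inside / length_in) / (outside / length_out)


# ---------------------------------------------------------------------------
# Tabular output (S4/S5-style layout)
# ---------------------------------------------------------------------------

def differences_to_tsv(diffs: Sequence[DifferenceRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "Position": r.position,
                "Feature": r.feature or "",
                "Strand": r.strand or "",
                "Position_codon": r.codon_position or "NA",
                "Base_A": r.base_a,
                "Base_B": r.base_b,
                "Sequence_A": r.context_a,
                "AA_change": r.aa_change or "NA",
                "Type": {"substitution": r.ts_tv, "insertion": "ins", "deletion": "del"}[
                    r.kind
                ],
            }
            for r in diffs
        ]
    ).to_csv(path, sep="\t", index=False)
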