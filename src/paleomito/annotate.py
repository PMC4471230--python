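"""Annotation transfer between aligned mitogenomes and CDS validation.

Features (CDS / tRNA / rRNA / D-loop) are lifted from an annotated reference
onto a target genome through the end-free global alignment of the two
sequences; a boundary falling in a target gap snaps to the nearest aligned
target position (start snaps right, end snaps left), so a feature is never
extended into unaligned territory.  Coding sequences are validated under the
vertebrate mitochondrial code, admitting the mammalian start set
(ATG/ATA/ATT/GTG) and polyadenylation-completed incomplete stops (T / TA).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .mitocompare import (
    MITO_START_CODONS,
    MITO_STOP_CODONS,
    global_alignment,
)
from .seq import CircularSequence, revcomp


@dataclass
class Feature:
    name: str
    type: str  # CDS | tRNA | rRNA | D-loop
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    intergenic_nt: Optional[int] = None  # signed; negative means overlap
    length_changed: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def compute_intergenic(features: Sequence[Feature]) -> list[Feature]:
    """Fill ``intergenic_nt`` (distance to the previous feature, by start)."""
    feats = sorted(features, key=lambda f: (f.start, f.end))
    prev_end = None
    for f in feats:
        f.intergenic_nt = None if prev_end is None else f.start - prev_end - 1
        prev_end = max(prev_end or 0, f.end)
    return feats


@dataclass
class LiftResult:
    features: list[Feature]
    deleted: list[Feature] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)


def lift_annotations(
    target: CircularSequence, annotated_ref: CircularSequence
) -> LiftResult:
    """Map every reference feature's boundaries onto ``target``.

    Features entirely deleted in the target are reported in ``deleted``;
    features whose length changed (indel inside) carry ``length_changed``.
    """
    row_ref, row_tgt = global_alignment(annotated_ref.seq, target.seq)
    n_ref = len(annotated_ref)
    # ref position (1-based) -> target position (1-based) or 0 when gapped
    ref2tgt = [0] * (n_ref + 1)
    pr = pt = 0
    for x, y in zip(row_ref, row_tgt):
        if y != "-":
            pt += 1
        if x != "-":
            pr += 1
            ref2tgt[pr] = pt if y != "-" else 0
    lifted: list[Feature] = []
    deleted: list[Feature] = []
    for f in annotated_ref.features:
        start = _snap(ref2tgt, f.start, direction=+1, n=n_ref)
        end = _snap(ref2tgt, f.end, direction=-1, n=n_ref)
        if start is None or end is None or start > end:
            deleted.append(f)
            continue
        nf = Feature(f.name, f.type, start, end, f.strand)
        nf.length_changed = nf.length != f.length
        lifted.append(nf)
    return LiftResult(compute_intergenic(lifted), deleted)


def _snap(ref2tgt: list[int], pos: int, direction: int, n: int) -> Optional[int]:
    p = pos
    while 1 <= p <= n:
        if ref2tgt[p]:
            return ref2tgt[p]
        p += direction
    return None


# ---------------------------------------------------------------------------
# CDS validation
# ---------------------------------------------------------------------------

@dataclass
class CdsValidation:
    feature: str
    passed: bool
    reasons: list[str]
    incomplete_stop: bool = False


def validate_cds(feature: Feature, genome: CircularSequence) -> CdsValidation:
    """Start / stop / internal-stop checks under the vertebrate mito code."""
    if feature.type != "CDS":
        raise ValueError("validate_cds requires a CDS feature")
    if feature.end > len(genome):
        raise ValueError("feature out of genome bounds")
    seq = genome.seq[feature.start - 1 : feature.end]
    if feature.strand == "-":
        seq = revcomp(seq)
    reasons: list[str] = []
    incomplete = False
    if len(seq) < 6:
        return CdsValidation(feature.name, False, ["too short"])
    if seq[:3] not in MITO_START_CODONS:
        reasons.append(f"inadmissible start codon {seq[:3]}")
    n_codons, rem = divmod(len(seq), 3)
    if rem == 0:
        if seq[-3:] not in MITO_STOP_CODONS:
            reasons.append(f"no terminal stop codon ({seq[-3:]})")
        internal = range(1, n_codons - 1)
    else:
        tail = seq[n_codons * 3 :]
        if tail in ("T", "TA"):
            incomplete = True  # completed by polyadenylation; flagged, not failed
        else:
            reasons.append(f"incomplete terminal codon {tail!r} is not T/TA")
        internal = range(1, n_codons)
    for k in internal:
        codon = seq[3 * k : 3 * k + 3]
        if codon in MITO_STOP_CODONS:
            reasons.append(f"internal stop codon {codon} at codon {k + 1}")
            break
    return CdsValidation(feature.name, not reasons, reasons, incomplete)


def genome_content_summary(features: Sequence[Feature]) -> dict[str, int]:
    """Feature counts by type (order-invariant)."""
    return dict(Counter(f.type for f in features))


# ---------------------------------------------------------------------------
# Feature-table I/O (S3-style TSV) and GFF3 export
# ---------------------------------------------------------------------------

def features_to_tsv(features: Sequence[Feature], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "name": f.name,
                "type": f.type,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "intergenic_nt": f.intergenic_nt if f.intergenic_nt is not None else "",
                "length_changed": int(f.length_changed),
            }
            for f in features
        ]
    ).to_csv(path, sep="\t", index=False)


def features_from_tsv(path) -> list[Feature]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    feats = []
    for _, row in df.iterrows():
        feats.append(
            Feature(
                str(row["name"]),
                str(row["type"]),
                int(row["start"]),
                int(row["end"]),
                str(row.get("strand", "+")),
            )
        )
    return feats


def features_to_gff3(features: Sequence[Feature], seqid: str, path) -> None:
    type_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "D_loop"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{seqid}\tpaleomito\t{type_map.get(f.type, f.type)}\t{f.start}\t"
                f"{f.end}\t.\t{f.strand}\t.\tID={f.name};Name={f.name}\n"
            )
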