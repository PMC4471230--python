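"""Competitive species assignment, in-silico PCR and coverage arithmetic.

The competitive screen maps a read set against several candidate reference
mitogenomes under the strictest conditions (perfect match, minimum read
length 30 nt by default) and assigns the set to the genome collecting the
most reads; large overlaps between genomes are expected, since reads landing
in locally identical windows map to several references at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .mapping import EditDistanceSchedule, ReferenceIndex, map_read
from .seq import CircularSequence, Read, revcomp

AMBIGUITY_RUNNERUP_FRACTION = 0.5


@dataclass
class CompetitiveReport:
    counts: dict[str, int]
    overlap: dict[tuple[str, str], int]
    assigned: str  # winning genome id, or "ambiguous"
    ambiguous: bool
    threshold: int

    def summary(self) -> str:
        lines = [f"competitive screen (perfect match, length >= {self.threshold} nt)"]
        for gid, c in sorted(self.counts.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {gid}: {c} reads")
        lines.append(f"  assigned: {self.assigned}")
        return "\n".join(lines)


def competitive_counts(
    reads: Sequence[Read],
    genomes: Sequence[CircularSequence],
    min_len: int = 30,
) -> CompetitiveReport:
    """Perfect-match read counts per genome, overlap matrix and a label.

    The label is the genome with the maximal count, flagged ambiguous when
    the runner-up exceeds half the maximum (or nothing mapped at all).
    """
    if len(genomes) < 2:
        raise ValueError("competitive screening needs at least 2 genomes")
    index = ReferenceIndex(genomes)
    sched = EditDistanceSchedule.perfect()
    hits: dict[str, set[str]] = {g.id: set() for g in genomes}
    for read in reads:
        if len(read) < min_len:
            continue
        for rec in map_read(read, index, sched):
            hits[rec.ref_id].add(rec.read_id)
    counts = {gid: len(ids) for gid, ids in hits.items()}
    overlap = {}
    gids = [g.id for g in genomes]
    for i, gi in enumerate(gids):
        for gj in gids[i + 1 :]:
            overlap[(gi, gj)] = len(hits[gi] & hits[gj])
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0
    ambiguous = best == 0 or runner > AMBIGUITY_RUNNERUP_FRACTION * best
    return CompetitiveReport(
        counts=counts,
        overlap=overlap,
        assigned="ambiguous" if ambiguous else best_id,
        ambiguous=ambiguous,
        threshold=min_len,
    )


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers, both written 5'->3'."""

    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if len(self.forward) < 10 or len(self.reverse) < 10:
            raise ValueError("primers must be at least 10 nt")


class NoProductError(ValueError):
    pass


class MultipleProductError(ValueError):
    pass


def _primer_sites(genome: CircularSequence, primer: str, max_mismatch: int) -> list[int]:
    hay = genome.doubled if genome.circular else genome.seq
    n = len(genome)
    L = len(primer)
    sites = []
    limit = n if genome.circular else n - L + 1
    for i in range(max(limit, 0)):
        window = hay[i : i + L]
        if len(window) < L:
            break
        mism = sum(a != b for a, b in zip(window, primer))
        if mism <= max_mismatch:
            sites.append(i)
    return sites


def locate_amplicon(
    genome: CircularSequence,
    primers: PrimerPair,
    max_product: int = 2000,
) -> tuple[tuple[int, int], str]:
    """Locate the unique PCR product and return (1-based region, insert).

    The region spans both primers inclusive; the insert excludes them.
    Raises :class:`NoProductError` / :class:`MultipleProductError`.
    """
    fwd_sites = _primer_sites(genome, primers.forward, primers.max_mismatch)
    rev_sites = _primer_sites(genome, revcomp(primers.reverse), primers.max_mismatch)
    n = len(genome)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            r_adj = r if r >= f else (r + n if genome.circular else None)
            if r_adj is None:
                continue
            end = r_adj + len(primers.reverse)  # exclusive
            length = end - f
            if length <= len(primers.forward) + len(primers.reverse):
                continue
            if length > max_product:
                continue
            products.append((f, end))
    if not products:
        raise NoProductError("no amplification product for this primer pair")
    if len(products) > 1:
        raise MultipleProductError(f"{len(products)} products: primers not specific")
    f, end = products[0]
    region = (f + 1, end)  # 1-based inclusive
    insert = genome.fragment(f + len(primers.forward), end - f - len(primers.forward) - len(primers.reverse))
    return region, insert


# ---------------------------------------------------------------------------
# Clone classification against reference amplicons
# ---------------------------------------------------------------------------

def classify_clone(
    clone: str, amplicons: dict[str, str]
) -> tuple[str, dict[str, int]]:
    """Assign a sequenced clone to the reference amplicon it best matches.

    Ungapped Hamming comparison of equal-length (primer-trimmed) inserts;
    the label with minimal distance wins, ties report "ambiguous".
    """
    if not amplicons:
        raise ValueError("no reference amplicons")
    distances = {}
    for label, seq in amplicons.items():
        if len(seq) != len(clone):
            raise ValueError(
                f"amplicon {label!r} length {len(seq)} != clone length {len(clone)}"
            )
        distances[label] = sum(a != b for a, b in zip(clone, seq))
    best = min(distances.values())
    winners = [lab for lab, d in distances.items() if d == best]
    label = winners[0] if len(winners) == 1 else "ambiguous"
    return label, distances


# ---------------------------------------------------------------------------
# Coverage arithmetic
# ---------------------------------------------------------------------------

def fold_coverage(total_aligned_bases: float, target_len: int, copies: int = 1) -> float:
    """Average depth: aligned bases over (target length x copy number)."""
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return total_aligned_bases / (target_len * copies)


def per_copy_depth(depth: float, copies: int) -> float:
    """Convert a depth over ``copies`` gene copies to a single-copy depth."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return depth / copies


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def primers_from_tsv(path) -> dict[str, PrimerPair]:
    """3-column TSV (name, forward, reverse), one primer pair per row."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {
        str(row.iloc[0]): PrimerPair(str(row.iloc[1]).upper(), str(row.iloc[2]).upper())
        for _, row in df.iterrows()
    }


def report_to_tsv(report: CompetitiveReport, path) -> None:
    import pandas as pd

    rows = []
    for gid, c in report.counts.items():
        row = {"genome": gid, "count": c, "assigned": report.assigned}
        for (gi, gj), ov in report.overlap.items():
            if gid in (gi, gj):
                other = gj if gid == gi else gi
                row[f"overlap_{other}"] = ov
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
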