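"""Ungapped bounded-mismatch read mapping to (circular) reference genomes.

The mapper reproduces the operative semantics of BWA runs with gap opening
disabled (``-o 0``): every placement of a read, on either strand, whose
Hamming distance to the reference window is within a length-dependent bound.
Three bound schedules are supported:

``perfect``
    zero mismatches (the competitive species screen);
``absolute``
    a constant mismatch count (``-n 2``, the first assembly round);
``fraction``
    BWA's fractional rule: the smallest ``k`` such that
    ``P(X > k) < n`` for ``X ~ Poisson(0.02 * read_length)`` (``-n 0.1``,
    later assembly rounds), which grows from 1 mismatch for 20-26 nt reads
    to 4 mismatches for 88-101 nt reads.

Mapping quality is a proxy for BWA's score, reproducing the operative
distinction used downstream (MQ >= 25 means confidently unique): 37 when the
best placement is unique and no other placement is within one mismatch of
it, 25 when unique but a placement exists at best+1, 0 when the best count
is tied.  N in read or reference always counts as a mismatch.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seq import CircularSequence, Read, revcomp, VALID_BASES

MAPQ_UNIQUE = 37
MAPQ_UNIQUE_CLOSE = 25
MAPQ_AMBIGUOUS = 0

#: per-base error rate of BWA's fractional edit-distance rule
FRACTION_BASE_ERROR = 0.02


class ScheduleMode(str, enum.Enum):
    PERFECT = "perfect"
    ABSOLUTE = "absolute"
    FRACTION = "fraction"


@dataclass(frozen=True)
class EditDistanceSchedule:
    """Maximum-mismatch schedule (the BWA ``-n`` semantics, gap open 0)."""

    mode: ScheduleMode
    n: float = 0.0
    gap_open_allowed: bool = False  # always False: ungapped alignment only

    @staticmethod
    def perfect() -> "EditDistanceSchedule":
        return EditDistanceSchedule(ScheduleMode.PERFECT)

    @staticmethod
    def absolute(n: int) -> "EditDistanceSchedule":
        return EditDistanceSchedule(ScheduleMode.ABSOLUTE, n)

    @staticmethod
    def fraction(n: float = 0.1) -> "EditDistanceSchedule":
        return EditDistanceSchedule(ScheduleMode.FRACTION, n)


def max_edit_distance(read_len: int, sched: EditDistanceSchedule) -> int:
    """Maximum mismatches allowed for a read of ``read_len`` nucleotides."""
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if sched.mode is ScheduleMode.PERFECT:
        return 0
    if sched.mode is ScheduleMode.ABSOLUTE:
        return int(sched.n)
    lam = FRACTION_BASE_ERROR * read_len
    # smallest k >= 0 with P(X > k) < n, X ~ Poisson(lam)
    cdf = 0.0
    term = math.exp(-lam)
    k = 0
    while True:
        cdf += term
        if 1.0 - cdf < sched.n:
            return k
        k += 1
        term *= lam / k


@dataclass
class AlignmentRecord:
    """Placement of one read on one reference.

    ``start`` is 0-based on the forward strand; for circular references the
    window may wrap (``start + length > reference length``), in which case
    positions are taken modulo the reference length.
    """

    read_id: str
    ref_id: str
    start: int
    strand: str  # '+' or '-'
    length: int
    mismatches: int
    mapq: int = 0
    duplicate: bool = False

    @property
    def end(self) -> int:
        """Exclusive end on the (unwrapped) forward coordinate."""
        return self.start + self.length


_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
_CODE[ord("N")] = 4  # reference N: mismatches everything, including read N (5)

_READ_CODE = _CODE.copy()
_READ_CODE[ord("N")] = 5


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ReferenceIndex:
    """Pre-encoded references for repeated mapping.

    Hash-free: at mitogenome scale a vectorised sliding Hamming scan over the
    doubled sequence is fast enough and trivially exact.
    """

    def __init__(self, genomes: Sequence[CircularSequence]):
        if not genomes:
            raise ValueError("at least one reference genome required")
        self.genomes = list(genomes)
        self._enc: dict[str, tuple[np.ndarray, int, bool, str]] = {}
        for g in genomes:
            self._enc[g.id] = (_encode(g.doubled, _CODE), len(g), g.circular, g.doubled)

    def ref_ids(self) -> list[str]:
        return [g.id for g in self.genomes]


def _scan_one_strand(
    read_seq: str, enc: np.ndarray, n: int, circular: bool, bound: int
) -> tuple[np.ndarray, np.ndarray]:
    """All start positions (0..n-1) with Hamming distance <= bound."""
    L = len(read_seq)
    r = _encode(read_seq, _READ_CODE)
    mism = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mism += enc[j : j + n] != r[j]
    if not circular:
        # windows may not run past the linear end
        limit = n - L + 1
        if limit <= 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        mism = mism[:limit]
    hits = np.nonzero(mism <= bound)[0]
    return hits, mism[hits]


def _find_perfect(read_seq: str, doubled: str, n: int, circular: bool) -> np.ndarray:
    """Fast path for the perfect schedule via substring search."""
    if "N" in read_seq:
        return np.empty(0, dtype=int)  # N always mismatches
    hay = doubled if circular else doubled[:n]
    hits = []
    i = hay.find(read_seq)
    while i != -1 and i < n:
        hits.append(i)
        i = hay.find(read_seq, i + 1)
    return np.array(hits, dtype=int)


def map_read(
    read: Read,
    index: ReferenceIndex,
    sched: EditDistanceSchedule,
) -> list[AlignmentRecord]:
    """All placements of ``read`` within the schedule bound, both strands.

    Returns an empty list when nothing is within the bound.  Reads longer
    than a reference are rejected for that reference (a circular genome
    cannot be covered more than once by an ungapped read).
    """
    bad = set(read.seq) - VALID_BASES
    if bad:
        raise ValueError(f"read {read.id} contains non-ACGTN symbols: {sorted(bad)}")
    L = len(read.seq)
    if L < 1:
        raise ValueError("empty read")
    bound = max_edit_distance(L, sched)
    records: list[AlignmentRecord] = []
    for ref_id, (enc, n, circular, doubled) in index._enc.items():
        if L > n:
            continue
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            if bound == 0:
                hits = _find_perfect(seq, doubled, n, circular)
                counts = np.zeros(len(hits), dtype=int)
            else:
                hits, counts = _scan_one_strand(seq, enc, n, circular, bound)
            for pos, m in zip(hits, counts):
                records.append(
                    AlignmentRecord(read.id, ref_id, int(pos), strand, L, int(m))
                )
    _assign_mapq(records)
    return records


def _assign_mapq(records: list[AlignmentRecord]) -> None:
    """Mapping-quality proxy over the full placement set of one read."""
    if not records:
        return
    counts = sorted(r.mismatches for r in records)
    best = counts[0]
    best_unique = counts.count(best) == 1
    for r in records:
        if r.mismatches != best or not best_unique:
            r.mapq = MAPQ_AMBIGUOUS
        elif len(counts) > 1 and counts[1] == best + 1:
            r.mapq = MAPQ_UNIQUE_CLOSE
        else:
            r.mapq = MAPQ_UNIQUE


def map_reads(
    reads: Iterable[Read],
    index: ReferenceIndex,
    sched: EditDistanceSchedule,
) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    for read in reads:
        out.extend(map_read(read, index, sched))
    return out


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_reads(
    reads: Iterable[Read],
    adapter: str,
    min_len: int = 20,
    seed_len: int = 8,
) -> list[Read]:
    """Adapter/3'-N trimming with a minimum-length filter.

    Each read is truncated at the first position where a prefix of the
    adapter (at least ``seed_len`` long, or reaching the read's 3' end)
    matches; trailing N runs are then removed and reads shorter than
    ``min_len`` are dropped.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = []
    for read in reads:
        seq = read.seq
        cut = len(seq)
        for p in range(len(seq)):
            overlap = min(len(seq) - p, len(adapter))
            if overlap >= seed_len and seq[p : p + overlap] == adapter[:overlap]:
                cut = p
                break
        seq = seq[:cut].rstrip("N")
        if len(seq) >= min_len:
            qual = read.qual[: len(seq)] if read.qual else None
            kept.append(Read(read.id, seq, qual))
    return kept


# ---------------------------------------------------------------------------
# Duplicate collapsing
# ---------------------------------------------------------------------------

def deduplicate(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Flag PCR/optical duplicates sharing (ref, start, end, strand).

    The first record of each key is kept unflagged; flags are set in place
    and the same list is returned for convenience.
    """
    seen: set[tuple] = set()
    for r in records:
        key = (r.ref_id, r.start, r.end, r.strand)
        if key in seen:
            r.duplicate = True
        else:
            r.duplicate = False
            seen.add(key)
    return list(records)


def unique_records(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    return [r for r in records if not r.duplicate]


# ---------------------------------------------------------------------------
# SAM / TSV output (minimal dialect)
# ---------------------------------------------------------------------------

def write_sam(
    records: Sequence[AlignmentRecord],
    reads: dict[str, Read],
    refs: Sequence[CircularSequence],
    path: str | Path,
) -> None:
    """Minimal SAM: @SQ header, strand/duplicate flags, MAPQ, NM tag."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in refs:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\n")
        for r in records:
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if r.duplicate:
                flag |= 0x400
            read = reads[r.read_id]
            seq = read.seq if r.strand == "+" else revcomp(read.seq)
            fh.write(
                f"{r.read_id}\t{flag}\t{r.ref_id}\t{r.start + 1}\t{r.mapq}\t"
                f"{r.length}M\t*\t0\t0\t{seq}\t*\tNM:i:{r.mismatches}\n"
            )


def records_to_tsv(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "ref_id": r.ref_id,
                "start_1based": r.start + 1,
                "end_1based": r.end,
                "strand": r.strand,
                "mismatches": r.mismatches,
                "mapq": r.mapq,
                "duplicate": int(r.duplicate),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
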