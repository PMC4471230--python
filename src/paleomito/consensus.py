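"""Iterative reference-guided consensus assembly with explicit evidence rules.

The assembly runs in three rounds, mirroring how a degraded-sample
mitogenome is reconstructed against a related reference:

1. reads are mapped to the reference under a constant mismatch bound,
   duplicates collapsed, and a provisional consensus called (uncalled
   positions fall back to the reference base so coordinates stay stable);
2. all reads are remapped to the provisional consensus under the
   length-scaled fractional bound and the consensus re-called;
3. PCR consensus sequences — each counting as a single evidence unit,
   exempt from the mapping-quality filter — are placed (with gaps) on the
   provisional frame and integrated; residual zero-coverage positions are
   reported as gaps, single-evidence and discordant positions as the
   verification list.

A position is called when at least ``min_evidence`` concordant unique
evidences (reads with MQ >= ``min_mapq``, or PCR sequences) support the
majority base.  A column whose minority fraction exceeds
``discordance_threshold`` is flagged unless every minority observation is
explainable as terminal deamination (read-orientation G->A within
``damage_window`` of the read's 3' end, or the mirrored 5' C->T), in which
case the majority stands as ``resolved_damage``.  A still-flagged or
single-evidence column with >= ``min_evidence`` concordant PCR evidences
takes the PCR base (PCR adjudication).  Insertions relative to the frame
are never called from ungapped reads; they enter through PCR evidence only.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .mapping import (
    AlignmentRecord,
    EditDistanceSchedule,
    ReferenceIndex,
    deduplicate,
    map_reads,
    unique_records,
)
from .seq import CircularSequence, Read, complement, revcomp

STATUS_CALLED = "called"
STATUS_ZERO = "zero_coverage"
STATUS_SINGLE = "single_evidence"
STATUS_FLAGGED = "flagged_discordant"
STATUS_DAMAGE = "resolved_damage"

DELETION = "-"


@dataclass(frozen=True)
class ConsensusPolicy:
    min_evidence: int = 2
    min_mapq: int = 25
    discordance_threshold: float = 0.25
    damage_window: int = 10

    def __post_init__(self) -> None:
        if self.min_evidence < 1:
            raise ValueError("min_evidence must be >= 1")
        if not 0.0 <= self.discordance_threshold <= 1.0:
            raise ValueError("discordance_threshold must be in [0, 1]")


@dataclass
class Observation:
    """One evidence unit at one column, in reference-forward orientation.

    ``off5``/``off3`` are offsets from the supporting read's own 5'/3' ends
    (None for PCR evidence).
    """

    base: str  # A/C/G/T/N or '-' (deletion evidence, PCR only)
    source: str  # 'read' | 'pcr'
    strand: str = "+"
    off5: Optional[int] = None
    off3: Optional[int] = None


@dataclass
class PileupColumn:
    position: int  # 0-based on the frame
    observations: list[Observation] = field(default_factory=list)

    def counts(self) -> Counter:
        return Counter(o.base for o in self.observations)

    def read_count(self) -> int:
        return sum(o.source == "read" for o in self.observations)

    def pcr_count(self) -> int:
        return sum(o.source == "pcr" for o in self.observations)


@dataclass
class ConsensusCall:
    position: int  # 0-based
    base: Optional[str]
    status: str
    evidence: dict = field(default_factory=dict)


def build_pileup(
    records: Sequence[AlignmentRecord],
    reads: dict[str, Read],
    policy: ConsensusPolicy,
    frame_length: int,
) -> list[PileupColumn]:
    """One column per frame position from non-duplicate, MQ-passing records.

    ``records`` must already be deduplicated and refer to a single frame;
    circular wrap reduces positions modulo the frame length.
    """
    columns = [PileupColumn(p) for p in range(frame_length)]
    for rec in records:
        if rec.duplicate or rec.mapq < policy.min_mapq:
            continue
        if not (0 <= rec.start < frame_length):
            raise ValueError(f"record start {rec.start} outside frame")
        read = reads[rec.read_id]
        L = rec.length
        oriented = read.seq if rec.strand == "+" else revcomp(read.seq)
        for j in range(L):
            pos = (rec.start + j) % frame_length
            # offsets in the read's own orientation
            if rec.strand == "+":
                off5, off3 = j, L - 1 - j
            else:
                off5, off3 = L - 1 - j, j
            columns[pos].observations.append(
                Observation(oriented[j], "read", rec.strand, off5, off3)
            )
    return columns


def call_column(col: PileupColumn, policy: ConsensusPolicy) -> ConsensusCall:
    """Evidence rules for a single column; see the module docstring."""
    obs = col.observations
    n = len(obs)
    summary = {"n": n, "reads": col.read_count(), "pcr": col.pcr_count()}
    if n == 0:
        return ConsensusCall(col.position, None, STATUS_ZERO, summary)
    counts = col.counts()
    summary["counts"] = dict(counts)
    if n == 1:
        return ConsensusCall(col.position, obs[0].base, STATUS_SINGLE, summary)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        # exact tie: "most frequent base" presumes a strict majority
        call = ConsensusCall(col.position, None, STATUS_FLAGGED, summary)
        return _pcr_adjudicate(col, call, policy, summary)
    base, top = ranked[0]
    minority = 1.0 - top / n
    if minority <= policy.discordance_threshold:
        return ConsensusCall(col.position, base, STATUS_CALLED, summary)
    if _damage_explains_minority(obs, base, policy):
        return ConsensusCall(col.position, base, STATUS_DAMAGE, summary)
    call = ConsensusCall(col.position, base, STATUS_FLAGGED, summary)
    return _pcr_adjudicate(col, call, policy, summary)


def _damage_explains_minority(
    obs: Sequence[Observation], majority: str, policy: ConsensusPolicy
) -> bool:
    for o in obs:
        if o.base == majority:
            continue
        if o.source != "read":
            return False
        # express majority and observation on the read's strand
        if o.strand == "+":
            maj_ro, obs_ro = majority, o.base
        else:
            maj_ro, obs_ro = complement(majority), complement(o.base)
        g_to_a = maj_ro == "G" and obs_ro == "A" and (o.off3 or 0) < policy.damage_window
        c_to_t = maj_ro == "C" and obs_ro == "T" and (o.off5 or 0) < policy.damage_window
        if not (g_to_a or c_to_t):
            return False
    return True


def _pcr_adjudicate(
    col: PileupColumn, call: ConsensusCall, policy: ConsensusPolicy, summary: dict
) -> ConsensusCall:
    """Concordant PCR evidence overrides a flagged or single-evidence column."""
    pcr_bases = [o.base for o in col.observations if o.source == "pcr"]
    if len(pcr_bases) >= policy.min_evidence and len(set(pcr_bases)) == 1:
        summary = dict(summary, pcr_adjudicated=True)
        return ConsensusCall(col.position, pcr_bases[0], STATUS_CALLED, summary)
    return call


# ---------------------------------------------------------------------------
# PCR evidence placement
# ---------------------------------------------------------------------------

@dataclass
class PcrPlacement:
    label: str
    start: int  # 0-based on the frame (may wrap)
    column_obs: list[tuple[int, str]]  # (frame position, base or '-')
    insertions: list[tuple[int, str]]  # (position after which, inserted seq)
    edit_distance: int


def place_pcr_sequence(
    label: str, seq: str, frame: CircularSequence
) -> PcrPlacement:
    """Gapped infix placement of one PCR consensus sequence on the frame.

    Both orientations are tried; the one with the smaller edit distance
    wins.  Matches/mismatches become per-column base evidence, deletions in
    the fragment become '-' evidence, and extra fragment bases are returned
    as insertion evidence keyed to the frame position they follow.
    """
    target = frame.doubled if frame.circular else frame.seq
    best = None
    for oriented in (seq, revcomp(seq)):
        res = edlib.align(oriented, target, task="path", mode="HW")
        if best is None or res["editDistance"] < best[0]["editDistance"]:
            best = (res, oriented)
    res, oriented = best
    start = res["locations"][0][0]
    n = len(frame)
    cigar = res["cigar"]
    column_obs: list[tuple[int, str]] = []
    insertions: list[tuple[int, str]] = []
    qpos, tpos = 0, start
    import re

    for count, op in re.findall(r"(\d+)([=XIDM])", cigar):
        count = int(count)
        if op in ("=", "X", "M"):
            for k in range(count):
                column_obs.append(((tpos + k) % n, oriented[qpos + k]))
            qpos += count
            tpos += count
        elif op == "D":  # bases in the frame absent from the fragment
            for k in range(count):
                column_obs.append(((tpos + k) % n, DELETION))
            tpos += count
        elif op == "I":  # extra fragment bases: insertion after tpos-1
            insertions.append(((tpos - 1) % n, oriented[qpos : qpos + count]))
            qpos += count
    return PcrPlacement(label, start % n, column_obs, insertions, res["editDistance"])


def add_pcr_evidence(
    columns: list[PileupColumn], placements: Sequence[PcrPlacement]
) -> dict[tuple[int, str], int]:
    """Attach PCR observations to the pileup; returns insertion support."""
    ins_support: Counter = Counter()
    for pl in placements:
        for pos, base in pl.column_obs:
            columns[pos].observations.append(Observation(base, "pcr"))
        for pos, seq in pl.insertions:
            ins_support[(pos, seq)] += 1
    return dict(ins_support)


# ---------------------------------------------------------------------------
# Indel-candidate detection
# ---------------------------------------------------------------------------

def indel_candidates(
    records: Sequence[AlignmentRecord],
    frame_length: int,
    margin: int = 6,
    min_flank_depth: int = 3,
    end_cluster: int = 4,
) -> list[tuple[int, int]]:
    """Positions where ungapped mapping suggests an indel in the sample.

    An indel in the template makes reads unable to span it: no alignment
    crosses the point with ``margin`` nt on both sides although both flanks
    are covered, and alignment boundaries cluster on either side.  Returns
    merged 0-based half-open candidate intervals for PCR verification.
    """
    n = frame_length
    depth = np.zeros(2 * n + 1)
    crossing = np.zeros(2 * n + 1)
    right_ends = np.zeros(n, dtype=int)
    left_starts = np.zeros(n, dtype=int)
    for r in records:
        if r.duplicate:
            continue
        s, e = r.start, r.start + r.length
        depth[s] += 1
        depth[min(e, 2 * n)] -= 1
        cs, ce = s + margin, e - margin
        if ce > cs:
            crossing[cs] += 1
            crossing[min(ce, 2 * n)] -= 1
        right_ends[(e - 1) % n] += 1
        left_starts[s % n] += 1
    depth = np.cumsum(depth)[:-1]
    crossing = np.cumsum(crossing)[:-1]
    depth = depth[:n] + depth[n:]
    crossing = crossing[:n] + crossing[n:]
    win = np.ones(margin)
    r_win = np.convolve(np.concatenate([right_ends, right_ends[: 2 * margin]]), win, "same")[:n]
    l_win = np.convolve(np.concatenate([left_starts, left_starts[: 2 * margin]]), win, "same")[:n]
    flags = []
    for p in range(n):
        lo, hi = (p - margin) % n, (p + margin) % n
        flanked = depth[lo] >= min_flank_depth and depth[hi] >= min_flank_depth
        if not flanked:
            continue
        if crossing[p] == 0:
            flags.append(p)
        elif crossing[p] <= 1 and r_win[(p - 2) % n] >= end_cluster and l_win[(p + 2) % n] >= end_cluster:
            flags.append(p)
    return merge_positions(flags, gap=margin, n=n)


def merge_positions(
    positions: Sequence[int], gap: int, n: int
) -> list[tuple[int, int]]:
    """Merge sorted positions closer than ``gap`` into half-open intervals."""
    if not positions:
        return []
    positions = sorted(set(positions))
    out = []
    s = e = positions[0]
    for p in positions[1:]:
        if p - e <= gap:
            e = p
        else:
            out.append((s, e + 1))
            s = e = p
    out.append((s, e + 1))
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyResult:
    consensus: CircularSequence
    calls: list[ConsensusCall]  # final calls, one per frame position
    gap_positions: list[int]  # 1-based, zero coverage after all rounds
    single_positions: list[int]  # 1-based
    no_consensus_positions: list[int]  # 1-based, flagged after all rounds
    insertions: list[tuple[int, str, int]]  # (1-based pos after, seq, support)
    frame: CircularSequence  # the round-2 provisional frame
    round_stats: dict
    records: list[AlignmentRecord] = field(default_factory=list)  # final round reads
    depth: Optional[np.ndarray] = None

    def complete(self) -> bool:
        return not self.gap_positions


ROUND1_SCHEDULE = EditDistanceSchedule.absolute(2)
ROUND2_SCHEDULE = EditDistanceSchedule.fraction(0.1)


def _map_round(
    reads: Sequence[Read],
    frame: CircularSequence,
    sched: EditDistanceSchedule,
    policy: ConsensusPolicy,
) -> tuple[list[AlignmentRecord], dict[str, Read]]:
    index = ReferenceIndex([frame])
    records = deduplicate(map_reads(reads, index, sched))
    return records, {r.id: r for r in reads}


def assemble(
    reads: Sequence[Read],
    ref: CircularSequence,
    pcr_sequences: Sequence[tuple[str, str]] = (),
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> AssemblyResult:
    """Three-round reference-guided assembly; see the module docstring.

    ``pcr_sequences`` are (label, sequence) pairs; they are placed on the
    provisional frame in round 3.  The final consensus contains calls
    wherever the status is called/resolved_damage; residual zero-coverage
    positions become 'N' and are reported in the gap list.
    """
    reads = list(reads)
    # --- round 1: map to the related reference, absolute bound -------------
    records1, read_map = _map_round(reads, ref, ROUND1_SCHEDULE, policy)
    columns1 = build_pileup(unique_records(records1), read_map, policy, len(ref))
    provisional = []
    r1_status = Counter()
    for col in columns1:
        call = call_column(col, policy)
        r1_status[call.status] += 1
        if call.status in (STATUS_CALLED, STATUS_DAMAGE):
            provisional.append(call.base)
        elif call.status == STATUS_SINGLE:
            provisional.append(call.base)  # best available; verified later
        else:
            provisional.append(ref.base(col.position))  # fallback keeps frame stable
    frame = CircularSequence(ref.id + "_provisional", "".join(provisional), ref.circular)

    # --- round 2: remap to the provisional consensus, fractional bound -----
    records2, _ = _map_round(reads, frame, ROUND2_SCHEDULE, policy)
    uniq2 = unique_records(records2)
    columns2 = build_pileup(uniq2, read_map, policy, len(frame))

    # --- round 3: integrate PCR consensus sequences ------------------------
    placements = [place_pcr_sequence(lab, seq, frame) for lab, seq in pcr_sequences]
    ins_support = add_pcr_evidence(columns2, placements)

    calls: list[ConsensusCall] = []
    gaps, singles, flagged = [], [], []
    final = []
    for col in columns2:
        call = call_column(col, policy)
        calls.append(call)
        if call.status == STATUS_ZERO:
            gaps.append(col.position + 1)
            final.append("N")
        elif call.status == STATUS_SINGLE:
            singles.append(col.position + 1)
            final.append(call.base)
        elif call.status == STATUS_FLAGGED:
            flagged.append(col.position + 1)
            final.append(call.base or "N")
        else:
            if call.base != DELETION:
                final.append(call.base)
            else:
                final.append("")  # deleted position
    accepted_ins = [
        (pos + 1, seq, count)
        for (pos, seq), count in sorted(ins_support.items())
        if count >= policy.min_evidence
    ]
    for pos1, seq, _ in sorted(accepted_ins, reverse=True):
        final[pos1 - 1] = final[pos1 - 1] + seq
    consensus = CircularSequence(ref.id.replace("_ref", "") + "_consensus", "".join(final), ref.circular)

    mapq_pass = [r for r in uniq2 if r.mapq >= policy.min_mapq]
    depth = np.zeros(len(frame))
    for r in mapq_pass:
        for j in range(r.length):
            depth[(r.start + j) % len(frame)] += 1
    for pl in placements:
        for pos, base in pl.column_obs:
            depth[pos] += 1
    evidence_bases = sum(r.length for r in mapq_pass) + sum(
        len(pl.column_obs) for pl in placements
    )
    round_stats = {
        "round1": {
            "placements": len(records1),
            "unique_reads": len({r.read_id for r in unique_records(records1)}),
            "status_counts": dict(r1_status),
        },
        "round2": {
            "placements": len(records2),
            "unique_reads": len({r.read_id for r in uniq2}),
        },
        "round3": {
            "pcr_sequences": len(placements),
            "gap_positions": len(gaps),
            "single_evidence_positions": len(singles),
            "no_consensus_positions": len(flagged),
            "accepted_insertions": len(accepted_ins),
        },
        "evidence_bases": int(evidence_bases),
        "status_counts": dict(Counter(c.status for c in calls)),
    }
    return AssemblyResult(
        consensus=consensus,
        calls=calls,
        gap_positions=gaps,
        single_positions=singles,
        no_consensus_positions=flagged,
        insertions=accepted_ins,
        frame=frame,
        round_stats=round_stats,
        records=mapq_pass,
        depth=depth,
    )


def verify_fixed_point(
    reads: Sequence[Read],
    consensus: CircularSequence,
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> tuple[bool, list[tuple[int, str, Optional[str]]]]:
    """Re-align all reads to the consensus and re-call.

    True iff the recalled base agrees with the consensus at every position
    whose recalled status is called/resolved_damage.  Returns the
    discrepancy list as (1-based position, consensus base, recalled base).
    """
    records, read_map = _map_round(list(reads), consensus, ROUND2_SCHEDULE, policy)
    columns = build_pileup(unique_records(records), read_map, policy, len(consensus))
    discrepancies = []
    for col in columns:
        call = call_column(col, policy)
        if call.status in (STATUS_CALLED, STATUS_DAMAGE):
            if call.base != consensus.seq[col.position]:
                discrepancies.append(
                    (col.position + 1, consensus.seq[col.position], call.base)
                )
    return not discrepancies, discrepancies


def coverage_stats(result: AssemblyResult) -> dict:
    """Mean fold coverage and evidence accounting for an assembly."""
    length = len(result.consensus)
    mean = result.round_stats["evidence_bases"] / length if length else 0.0
    return {
        "consensus_length": length,
        "mean_fold_coverage": mean,
        "unique_reads": result.round_stats["round2"]["unique_reads"],
        "pcr_fragments": result.round_stats["round3"]["pcr_sequences"],
        "evidence_bases": result.round_stats["evidence_bases"],
        "depth": result.depth,
    }


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def calls_to_tsv(calls: Sequence[ConsensusCall], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "position": c.position + 1,
                "base": c.base or "",
                "status": c.status,
                "n_evidence": c.evidence.get("n", 0),
                "n_reads": c.evidence.get("reads", 0),
                "n_pcr": c.evidence.get("pcr", 0),
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def intervals_to_bed(positions: Sequence[int], name: str, chrom: str, path) -> None:
    """1-based positions -> merged BED (0-based half-open) intervals."""
    with open(path, "w") as fh:
        for s, e in merge_positions([p - 1 for p in positions], gap=1, n=1 << 30):
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def stats_to_json(result: AssemblyResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.round_stats, fh, indent=2)
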