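"""Synthetic ancient-DNA datasets with ground truth.

The generator emulates the statistical structure a post-mortem DNA library
exhibits: short fragments (20-101 nt, short-favouring length distribution),
terminal deamination damage (C->T at 5' offsets, G->A at 3' offsets, each
Bernoulli(delta * decay**k) at offset k from the end, applied on the read
strand after fragmentation), uniform per-base sequencing error, planted
inter-genome polymorphisms with a strong transitional bias, and
contamination by reads from related genomes.  Every simulated read and every
planted difference is recorded in a truth table so downstream stages are
testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mitocompare import DifferenceRecord, _context, is_transition
from .seq import CircularSequence, Read, revcomp

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = "ACGT"


@dataclass(frozen=True)
class DamageModel:
    """Terminal deamination + sequencing-error model.

    rate at offset k from the relevant end = delta * decay**k.
    """

    delta5: float = 0.3  # C->T probability at the 5'-terminal position
    delta3: float = 0.3  # G->A probability at the 3'-terminal position
    decay: float = 0.5  # per-position geometric decay, in (0, 1)
    seq_error: float = 0.002  # per-base uniform error probability

    def __post_init__(self) -> None:
        for p in (self.delta5, self.delta3, self.seq_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")

    @staticmethod
    def none() -> "DamageModel":
        return DamageModel(0.0, 0.0, 0.5, 0.0)

    def rate5(self, k: int) -> float:
        return self.delta5 * self.decay**k

    def rate3(self, k: int) -> float:
        return self.delta3 * self.decay**k


@dataclass(frozen=True)
class FragmentModel:
    """Fragment-length distribution on [min_len, max_len].

    The default is a discretised truncated geometric favouring short
    fragments (weights proportional to ``geom**(L - min_len)``), matching
    the qualitative shape of ancient-library size distributions; with
    ``geom = 0.966`` the mean length is ~43 nt.
    """

    min_len: int = 20
    max_len: int = 101
    geom: float = 0.966
    length_weights: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.length_weights is not None:
            w = np.asarray(self.length_weights, dtype=float)
            if len(w) != self.max_len - self.min_len + 1:
                raise ValueError("length_weights must cover [min_len, max_len]")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must be nonnegative and sum to 1")

    def weights(self) -> np.ndarray:
        n = self.max_len - self.min_len + 1
        if self.length_weights is not None:
            return np.asarray(self.length_weights, dtype=float)
        w = self.geom ** np.arange(n)
        return w / w.sum()

    def mean_length(self) -> float:
        w = self.weights()
        return float(np.dot(w, np.arange(self.min_len, self.max_len + 1)))


@dataclass
class ReadTruth:
    source: str
    start: int  # 0-based start on the source genome's forward strand
    strand: str
    length: int
    damage_offsets: tuple[int, ...] = ()  # read-strand offsets that were damaged


@dataclass
class TruthSet:
    """Ground truth: one entry per simulated read, plus planted variants."""

    reads: dict[str, ReadTruth] = field(default_factory=dict)
    variants: dict[str, list[DifferenceRecord]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)  # read id -> mixture label


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

#: substitutions only need distinct positions; indels get a wide berth so
#: their gaps cannot slide into a neighbouring event in the alignment
_SUB_SPACING = 2
_INDEL_SPACING = 8


def plant_variants(
    ref: CircularSequence,
    n_transitions: int,
    n_transversions: int,
    indels: Sequence[tuple[str, int]] = (),
    seed: int = 0,
    positions: Optional[dict] = None,
) -> tuple[CircularSequence, list[DifferenceRecord]]:
    """Plant substitutions and indels into a copy of ``ref``.

    Events are placed without collision (minimum spacing keeps every event
    recoverable by exact alignment); ``positions`` optionally pins events to
    chosen loci: ``{"ts": [...], "tv": [...], "indels": [...]}`` with
    0-based positions.  Returns the mutated genome and the truth list,
    sorted by position on the reference frame.
    """
    if n_transitions < 0 or n_transversions < 0:
        raise ValueError("event counts must be >= 0")
    n = len(ref)
    total_indel = sum(length for _, length in indels)
    if n <= total_indel:
        raise ValueError("reference shorter than total planted indel length")
    rng = np.random.default_rng(seed)
    needed = n_transitions + n_transversions + len(indels)
    if needed * _SUB_SPACING >= n:
        raise ValueError(
            f"requested {needed} events exceed available positions on a {n} nt genome"
        )

    taken_subs: list[int] = []
    taken_indels: list[int] = []

    def _ok(p: int) -> bool:
        return all(abs(p - q) >= _SUB_SPACING for q in taken_subs) and all(
            abs(p - q) >= _INDEL_SPACING for q in taken_indels
        )

    def _draw(k: int, pinned: Optional[Sequence[int]], sink: list[int]) -> list[int]:
        if pinned is not None:
            if len(pinned) != k:
                raise ValueError("pinned positions do not match requested count")
            sink.extend(pinned)
            return list(pinned)
        out = []
        attempts = 0
        while len(out) < k:
            attempts += 1
            if attempts > 1000 * max(k, 1):
                raise ValueError("could not place events without collision")
            p = int(rng.integers(_INDEL_SPACING, n - _INDEL_SPACING))
            if _ok(p):
                sink.append(p)
                out.append(p)
        return sorted(out)

    pinned = positions or {}
    # indels first: they demand clearance on both sides
    indel_pos = _draw(len(indels), pinned.get("indels"), taken_indels)
    ts_pos = _draw(n_transitions, pinned.get("ts"), taken_subs)
    tv_pos = _draw(n_transversions, pinned.get("tv"), taken_subs)

    seq = list(ref.seq)
    records: list[DifferenceRecord] = []
    for p in ts_pos:
        alt = _TS_PARTNER[seq[p]]
        records.append(_sub_record(ref, p, seq[p], alt))
        seq[p] = alt
    for p in tv_pos:
        alt = _TV_PARTNERS[seq[p]][int(rng.integers(2))]
        records.append(_sub_record(ref, p, seq[p], alt))
        seq[p] = alt

    # Indels applied right-to-left so earlier coordinates stay valid.
    indel_events = sorted(zip(indel_pos, indels), key=lambda t: -t[0])
    for p, (kind, length) in indel_events:
        if kind in ("ins", "insertion"):
            ins = _unambiguous_insert(ref.seq, p, length, rng)
            seq[p + 1 : p + 1] = list(ins)
            records.append(
                DifferenceRecord(
                    position=p + 1,
                    kind="insertion",
                    base_a="-",
                    base_b=ins,
                    context_a=_context(ref.seq, p),
                )
            )
        elif kind in ("del", "deletion"):
            # shift until the gap cannot slide by one in either direction
            for _ in range(n):
                if (
                    ref.seq[p - 1] != ref.seq[p + length - 1]
                    and ref.seq[p] != ref.seq[(p + length) % n]
                ):
                    break
                p += 1
            deleted = ref.seq[p : p + length]
            del seq[p : p + length]
            records.append(
                DifferenceRecord(
                    position=p + 1,
                    kind="deletion",
                    base_a=deleted,
                    base_b="-",
                    context_a=_context(ref.seq, p),
                )
            )
        else:
            raise ValueError(f"unknown indel kind {kind!r}")

    records.sort(key=lambda r: (r.position, r.kind))
    mutated = CircularSequence(ref.id + "_mut", "".join(seq), ref.circular)
    return mutated, records


def _sub_record(ref: CircularSequence, p: int, base: str, alt: str) -> DifferenceRecord:
    return DifferenceRecord(
        position=p + 1,
        kind="substitution",
        base_a=base,
        base_b=alt,
        context_a=_context(ref.seq, p),
        context_b=alt,
        ts_tv="t" if is_transition(base, alt) else "v",
    )


def _unambiguous_insert(seq: str, p: int, length: int, rng) -> str:
    """Inserted bases whose first/last characters differ from the flanking
    reference bases, so the gap cannot slide in the alignment."""
    left = seq[p]
    right = seq[(p + 1) % len(seq)]
    for _ in range(100):
        ins = "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=length))
        if ins[0] != left and ins[-1] != right:
            return ins
    raise RuntimeError("unreachable")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: CircularSequence,
    n_reads: int,
    frag: FragmentModel = FragmentModel(),
    dmg: DamageModel = DamageModel(),
    seed: int = 0,
    id_prefix: str = "read",
) -> tuple[list[Read], TruthSet]:
    """Simulate ``n_reads`` damaged single-end reads from ``genome``.

    Each read is a contiguous (circularly wrapped) fragment of the genome or
    its reverse complement; damage, then uniform sequencing error, is applied
    on the read strand.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if len(genome) == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    lengths = rng.choice(
        np.arange(frag.min_len, frag.max_len + 1), size=n_reads, p=frag.weights()
    )
    truth = TruthSet()
    reads: list[Read] = []
    n = len(genome)
    for i in range(n_reads):
        L = int(lengths[i])
        if L > n:
            L = n
        start = int(rng.integers(0, n)) if genome.circular else int(
            rng.integers(0, n - L + 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = genome.fragment(start, L)
        if strand == "-":
            fragment = revcomp(fragment)
        seq = list(fragment)
        damaged: list[int] = []
        # 5' C->T, then 3' G->A, each geometric in the offset from its end
        for k in range(L):
            rate = dmg.rate5(k)
            if rate <= 0.0 or rate < 1e-12:
                break
            if seq[k] == "C" and rng.random() < rate:
                seq[k] = "T"
                damaged.append(k)
        for k in range(L):
            rate = dmg.rate3(k)
            if rate <= 0.0 or rate < 1e-12:
                break
            j = L - 1 - k
            if seq[j] == "G" and rng.random() < rate:
                seq[j] = "A"
                damaged.append(j)
        if dmg.seq_error > 0.0:
            errs = np.nonzero(rng.random(L) < dmg.seq_error)[0]
            for j in errs:  # sequencing errors are not recorded as damage
                others = [b for b in _BASES if b != seq[j]]
                seq[j] = others[int(rng.integers(3))]
        rid = f"{id_prefix}_{i:06d}"
        reads.append(Read(rid, "".join(seq)))
        truth.reads[rid] = ReadTruth(genome.id, start, strand, L, tuple(sorted(damaged)))
        truth.labels[rid] = genome.id
    return reads, truth


DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"  # Illumina TruSeq R1


def with_adapter(
    reads: Sequence[Read],
    adapter: str = DEFAULT_ADAPTER,
    read_len: int = 101,
    seed: int = 0,
) -> list[Read]:
    """Pad short fragments to the instrument read length via adapter
    read-through (fragment + adapter + random bases), as a single-end run
    on a short-insert library produces.  Trimming recovers the fragments."""
    rng = np.random.default_rng(seed)
    out = []
    for r in reads:
        if len(r.seq) >= read_len:
            out.append(Read(r.id, r.seq[:read_len]))
            continue
        tail = adapter
        while len(r.seq) + len(tail) < read_len:
            tail += "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=8))
        out.append(Read(r.id, (r.seq + tail)[:read_len]))
    return out


def simulate_pcr_fragments(
    template: CircularSequence,
    frame: CircularSequence,
    regions: Sequence[tuple[int, int]],
    pads: Sequence[int] = (100, 130, 160),
    max_len: int = 700,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Emulate PCR verification of problem regions.

    For each 0-based half-open ``region`` on the assembly ``frame``, one
    amplicon per pad width is produced: the corresponding stretch of the
    *true* template (primers designed on the provisional assembly amplify
    the sample itself, so the product consensus reflects the template, not
    the provisional sequence).  Region-to-template mapping uses a gapped
    infix alignment, as a primer pair tolerant of nearby differences would.
    """
    import edlib

    out: list[tuple[str, str]] = []
    n = len(frame)
    hay = template.doubled if template.circular else template.seq
    for i, (s, e) in enumerate(regions):
        for pad in pads:
            lo, hi = s - pad, e + pad
            if hi - lo > max_len:
                hi = lo + max_len
            probe = frame.fragment(lo % n, hi - lo)
            res = edlib.align(probe, hay, task="locations", mode="HW")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            ts, te = res["locations"][0]
            out.append((f"pcr_{i:02d}_pad{pad}", hay[ts : te + 1]))
    return out


# ---------------------------------------------------------------------------
# Contamination mixing
# ---------------------------------------------------------------------------

def mix_contaminants(
    readsets: Sequence[tuple[Sequence[Read], str]],
    proportions: Sequence[float],
    n_total: int,
    seed: int = 0,
) -> tuple[list[Read], dict[str, str]]:
    """Multinomial mixture of labelled read sets.

    Per-label counts are Multinomial(n_total, proportions).  A label whose
    drawn count equals its pool size contributes the pool unchanged; smaller
    counts subsample without replacement, larger ones resample with
    replacement (resampled copies get fresh ids).
    """
    props = np.asarray(proportions, dtype=float)
    if len(props) != len(readsets):
        raise ValueError("one proportion per read set required")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_total, props)
    out: list[Read] = []
    labels: dict[str, str] = {}
    for (reads, label), count in zip(readsets, counts):
        if count > 0 and len(reads) == 0:
            raise ValueError(f"read set {label!r} is empty but has positive weight")
        if count == len(reads):
            chosen = list(reads)
        elif count < len(reads):
            idx = rng.choice(len(reads), size=count, replace=False)
            chosen = [reads[int(i)] for i in sorted(idx)]
        else:
            idx = rng.choice(len(reads), size=count, replace=True)
            chosen = [
                Read(f"{reads[int(i)].id}_cp{k}", reads[int(i)].seq, reads[int(i)].qual)
                for k, i in enumerate(idx)
            ]
        for r in chosen:
            labels[r.id] = label
        out.extend(chosen)
    return out, labels


# ---------------------------------------------------------------------------
# Truth-table output
# ---------------------------------------------------------------------------

def truth_reads_to_tsv(truth: TruthSet, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "read_id": rid,
                "source": t.source,
                "start": t.start,
                "strand": t.strand,
                "length": t.length,
                "damage_offsets": ",".join(map(str, t.damage_offsets)),
            }
            for rid, t in truth.reads.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def variants_to_tsv(records, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "Position": r.position,
                "Base_ref": r.base_a,
                "Base_alt": r.base_b,
                "Type": {"substitution": r.ts_tv, "insertion": "ins", "deletion": "del"}[
                    r.kind
                ],
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
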