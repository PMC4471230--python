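"""Mapper semantics: bound schedules, oracle equivalence, trimming, dedup."""

import numpy as np
import pytest
from scipy import stats

from oracles import brute_force_map, rc
from conftest import random_genome

from paleomito.mapping import (
    AlignmentRecord,
    EditDistanceSchedule,
    ReferenceIndex,
    deduplicate,
    map_read,
    max_edit_distance,
    trim_reads,
)
from paleomito.seq import CircularSequence, Read


class TestEditDistanceSchedule:
    @pytest.mark.parametrize(
        "length,expected",
        [(20, 1), (23, 1), (26, 1), (27, 2), (55, 2), (56, 3), (88, 4), (101, 4)],
    )
    def test_fraction_rule_anchors(self, length, expected):
        assert max_edit_distance(length, EditDistanceSchedule.fraction(0.1)) == expected

    def test_fraction_rule_matches_poisson_tail(self):
        sched = EditDistanceSchedule.fraction(0.1)
        for length in range(20, 102):
            k = max_edit_distance(length, sched)
            tail = stats.poisson(0.02 * length)
            assert tail.sf(k) < 0.1
            assert k == 0 or tail.sf(k - 1) >= 0.1

    def test_absolute_and_perfect(self):
        for length in (20, 50, 101):
            assert max_edit_distance(length, EditDistanceSchedule.absolute(2)) == 2
            assert max_edit_distance(length, EditDistanceSchedule.perfect()) == 0

    def test_fraction_nondecreasing_in_length(self):
        sched = EditDistanceSchedule.fraction(0.1)
        bounds = [max_edit_distance(x, sched) for x in range(20, 102)]
        assert bounds == sorted(bounds)


def _sample_reads(genome, rng, n, mutate=0):
    reads = []
    for i in range(n):
        L = int(rng.integers(20, 60))
        hi = len(genome) if genome.circular else len(genome) - L + 1
        start = int(rng.integers(0, hi))
        seq = list(genome.fragment(start, L))
        for _ in range(mutate):
            p = int(rng.integers(L))
            seq[p] = "ACGT"[int(rng.integers(4))]
        if rng.random() < 0.5:
            seq = list(rc("".join(seq)))
        reads.append(Read(f"r{i}", "".join(seq)))
    return reads


class TestMapRead:
    @pytest.mark.parametrize(
        "sched",
        [
            EditDistanceSchedule.perfect(),
            EditDistanceSchedule.absolute(2),
            EditDistanceSchedule.fraction(0.1),
        ],
        ids=["perfect", "absolute", "fraction"],
    )
    @pytest.mark.parametrize("circular", [True, False], ids=["circular", "linear"])
    def test_oracle_equivalence(self, sched, circular):
        """Every placement equals the brute-force doubled-sequence scan."""
        genome = random_genome(350, seed=11, circular=circular)
        rng = np.random.default_rng(4)
        index = ReferenceIndex([genome])
        for read in _sample_reads(genome, rng, 20, mutate=2):
            bound = max_edit_distance(len(read), sched)
            expected = brute_force_map(read.seq, genome.seq, bound, circular)
            got = {(r.start, r.strand, r.mismatches) for r in map_read(read, index, sched)}
            assert got == expected

    def test_unique_perfect_hit(self, toy_genome):
        read = Read("u", toy_genome.fragment(50, 30))
        recs = map_read(read, ReferenceIndex([toy_genome]), EditDistanceSchedule.perfect())
        assert len(recs) == 1
        assert (recs[0].start, recs[0].mismatches, recs[0].mapq) == (50, 0, 37)

    def test_no_hit_beyond_bound(self, toy_genome):
        rng = np.random.default_rng(0)
        read = Read("junk", "".join("ACGT"[i] for i in rng.integers(0, 4, 40)))
        recs = map_read(read, ReferenceIndex([toy_genome]), EditDistanceSchedule.absolute(2))
        bound = 2
        assert all(
            len(brute_force_map(read.seq, toy_genome.seq, bound)) == len(recs)
            for _ in [0]
        )

    def test_circular_origin_wrap(self):
        genome = random_genome(100, seed=3)
        read = Read("wrap", genome.fragment(92, 20))  # spans the origin
        recs = map_read(read, ReferenceIndex([genome]), EditDistanceSchedule.perfect())
        got = {(r.start, r.strand, r.mismatches) for r in recs}
        assert got == brute_force_map(read.seq, genome.seq, 0, circular=True)
        assert any(r.start == 92 for r in recs)

    def test_linear_rejects_wrap(self):
        genome = random_genome(100, seed=3, circular=False)
        read = Read("wrap", (genome.seq + genome.seq)[92:112])
        recs = map_read(read, ReferenceIndex([genome]), EditDistanceSchedule.perfect())
        assert all(r.start + r.length <= 100 for r in recs)

    def test_strand_involution(self, toy_genome):
        """Mapping the reverse complement flips strands, keeps intervals."""
        rng = np.random.default_rng(9)
        index = ReferenceIndex([toy_genome])
        sched = EditDistanceSchedule.fraction(0.1)
        for read in _sample_reads(toy_genome, rng, 10, mutate=1):
            fwd = {(r.start, r.strand) for r in map_read(read, index, sched)}
            rev = {
                (r.start, r.strand)
                for r in map_read(Read(read.id, rc(read.seq)), index, sched)
            }
            flip = {"+": "-", "-": "+"}
            assert {(s, flip[st]) for s, st in fwd} == rev

    def test_monotone_in_bound(self, toy_genome):
        """Relaxing the schedule never loses an alignment."""
        rng = np.random.default_rng(12)
        index = ReferenceIndex([toy_genome])
        for read in _sample_reads(toy_genome, rng, 8, mutate=2):
            prev = set()
            for n in range(0, 5):
                sched = EditDistanceSchedule.absolute(n)
                got = {(r.start, r.strand) for r in map_read(read, index, sched)}
                assert prev <= got
                prev = got

    def test_non_acgtn_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="non-ACGTN"):
            map_read(Read("bad", "ACGTRR"), ReferenceIndex([toy_genome]),
                     EditDistanceSchedule.perfect())

    def test_n_counts_as_mismatch(self, toy_genome):
        frag = toy_genome.fragment(10, 30)
        read = Read("n", "N" + frag[1:])
        recs = map_read(read, ReferenceIndex([toy_genome]), EditDistanceSchedule.absolute(2))
        rec = next(r for r in recs if r.start == 10 and r.strand == "+")
        assert rec.mismatches == 1

    def test_mapq_proxy(self):
        # reference with an exact duplicated 30 nt window -> ambiguous hits
        core = random_genome(200, seed=21).seq
        dup = core[:30]
        genome = CircularSequence("dup", core + dup, circular=False)
        index = ReferenceIndex([genome])
        ambiguous = map_read(Read("a", dup), index, EditDistanceSchedule.perfect())
        assert {r.mapq for r in ambiguous} == {0}
        unique = map_read(Read("u", core[50:85]), index, EditDistanceSchedule.perfect())
        assert [r.mapq for r in unique] == [37]
        # unique best with a competitor at best+1 -> mapq 25
        window = core[100:130]
        competitor = window[:-1] + ("A" if window[-1] != "A" else "C")
        genome2 = CircularSequence("near", core + competitor, circular=False)
        recs = map_read(Read("c", window), ReferenceIndex([genome2]),
                        EditDistanceSchedule.absolute(2))
        best = min(recs, key=lambda r: r.mismatches)
        assert best.mismatches == 0 and best.mapq == 25


class TestTrim:
    ADAPTER = "AGATCGGAAGAGC"

    def test_no_adapter_unchanged(self):
        (read,) = trim_reads([Read("r", "ACGT" * 10)], self.ADAPTER, min_len=20)
        assert read.seq == "ACGT" * 10

    def test_adapter_at_35_of_60(self):
        rng = np.random.default_rng(5)
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 35))
        raw = (insert + self.ADAPTER + "TTTTTTTTTTTT")[:60]
        (read,) = trim_reads([Read("r", raw)], self.ADAPTER, min_len=20)
        assert read.seq == insert and len(read) == 35

    def test_short_after_trim_dropped(self):
        insert = "ACGTACGTACGTACGTAC"  # 18 nt < 20
        raw = insert + self.ADAPTER[:7]  # 25 nt read, adapter prefix at 3' end
        kept = trim_reads([Read("r", insert + self.ADAPTER)], self.ADAPTER, min_len=20)
        assert kept == []
        # a sub-seed-length adapter prefix is not trimmed
        (read,) = trim_reads([Read("r", raw)], self.ADAPTER, min_len=20, seed_len=8)
        assert read.seq == raw

    def test_trailing_n_stripped(self):
        (read,) = trim_reads([Read("r", "ACGT" * 8 + "NNNN")], self.ADAPTER, min_len=20)
        assert read.seq == "ACGT" * 8

    def test_quality_truncated_with_sequence(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        raw = insert + self.ADAPTER
        (read,) = trim_reads([Read("r", raw, "I" * len(raw))], self.ADAPTER, min_len=20)
        assert len(read.qual) == len(read.seq) == len(insert)


class TestDeduplicate:
    def _rec(self, start, strand, rid="r", length=30):
        return AlignmentRecord(rid, "g", start, strand, length, 0)

    def test_identical_placements_collapse(self):
        recs = deduplicate([self._rec(5, "+", "a"), self._rec(5, "+", "b")])
        assert [r.duplicate for r in recs] == [False, True]

    def test_opposite_strands_distinct(self):
        recs = deduplicate([self._rec(5, "+"), self._rec(5, "-")])
        assert [r.duplicate for r in recs] == [False, False]

    def test_random_set_matches_pairwise_count(self):
        rng = np.random.default_rng(8)
        recs = [
            self._rec(int(rng.integers(0, 10)), "+-"[int(rng.integers(2))],
                      f"r{i}", int(rng.integers(20, 23)))
            for i in range(50)
        ]
        deduplicate(recs)
        # hash-free oracle: pairwise comparison of placement keys
        distinct = 0
        for i, r in enumerate(recs):
            if not any(
                (r.start, r.end, r.strand) == (q.start, q.end, q.strand)
                for q in recs[:i]
            ):
                distinct += 1
        assert sum(not r.duplicate for r in recs) == distinct
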