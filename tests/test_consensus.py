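"""Evidence rules, damage resolution, three-round assembly, fixed point."""

import numpy as np
import pytest

from conftest import random_genome

from paleomito.consensus import (
    STATUS_CALLED,
    STATUS_DAMAGE,
    STATUS_FLAGGED,
    STATUS_SINGLE,
    STATUS_ZERO,
    AssemblyResult,
    ConsensusPolicy,
    Observation,
    PileupColumn,
    assemble,
    build_pileup,
    call_column,
    coverage_stats,
    indel_candidates,
    merge_positions,
    verify_fixed_point,
)
from paleomito.mapping import AlignmentRecord
from paleomito.seq import CircularSequence, Read, revcomp
from paleomito.simdata import (
    DamageModel,
    FragmentModel,
    plant_variants,
    simulate_pcr_fragments,
    simulate_reads,
)

POLICY = ConsensusPolicy()


def _col(*obs):
    return PileupColumn(0, list(obs))


def _read_obs(base, strand="+", off5=20, off3=20):
    return Observation(base, "read", strand, off5, off3)


class TestCallColumn:
    def test_zero_coverage(self):
        assert call_column(_col(), POLICY).status == STATUS_ZERO

    def test_single_evidence(self):
        call = call_column(_col(_read_obs("A")), POLICY)
        assert (call.status, call.base) == (STATUS_SINGLE, "A")

    def test_two_concordant_called(self):
        call = call_column(_col(_read_obs("G"), _read_obs("G")), POLICY)
        assert (call.status, call.base) == (STATUS_CALLED, "G")

    def test_exact_tie_is_no_consensus(self):
        call = call_column(_col(_read_obs("A"), _read_obs("G")), POLICY)
        assert call.status == STATUS_FLAGGED and call.base is None

    def test_minority_within_threshold_called(self):
        obs = [_read_obs("C")] * 7 + [_read_obs("A")]  # 12.5% minority
        call = call_column(_col(*obs), POLICY)
        assert (call.status, call.base) == (STATUS_CALLED, "C")

    def test_terminal_g_to_a_resolved_as_damage(self):
        """6 G + 3 A where every A sits <= 2 nt from its read's 3' end."""
        obs = [_read_obs("G")] * 6 + [
            _read_obs("A", off5=40, off3=k) for k in (0, 1, 2)
        ]
        call = call_column(_col(*obs), POLICY)
        assert (call.status, call.base) == (STATUS_DAMAGE, "G")

    def test_mid_read_discordance_flagged(self):
        """6 C + 3 T with the T's mid-read: 33% minority, no damage excuse."""
        obs = [_read_obs("C")] * 6 + [_read_obs("T", off5=30, off3=30)] * 3
        assert call_column(_col(*obs), POLICY).status == STATUS_FLAGGED

    def test_five_prime_c_to_t_mirror(self):
        obs = [_read_obs("C")] * 6 + [_read_obs("T", off5=1, off3=40)] * 3
        call = call_column(_col(*obs), POLICY)
        assert (call.status, call.base) == (STATUS_DAMAGE, "C")

    def test_reverse_strand_damage_is_complement_aware(self):
        """A minus-strand read's 5' C->T appears as ref-frame G->A."""
        obs = [_read_obs("G")] * 6 + [
            _read_obs("A", strand="-", off5=1, off3=40) for _ in range(3)
        ]
        call = call_column(_col(*obs), POLICY)
        assert (call.status, call.base) == (STATUS_DAMAGE, "G")

    def test_pcr_minority_never_damage(self):
        """PCR evidence cannot be explained away as deamination: the column
        is adjudicated on the PCR base, not damage-resolved to the read
        majority."""
        obs = [_read_obs("G")] * 6 + [Observation("A", "pcr")] * 3
        call = call_column(_col(*obs), POLICY)
        assert call.status != STATUS_DAMAGE
        assert (call.status, call.base) == (STATUS_CALLED, "A")
        # a single discordant PCR evidence is an ordinary sub-threshold
        # minority: the read majority stands
        call1 = call_column(_col(*([_read_obs("G")] * 6), Observation("A", "pcr")), POLICY)
        assert (call1.status, call1.base) == (STATUS_CALLED, "G")

    def test_pcr_adjudication_overrides_flag(self):
        """A flagged column with two concordant PCR evidences takes the
        PCR base (the 3-of-176 situation in a gap-filling campaign)."""
        obs = [_read_obs("T", off5=25, off3=25)] + [Observation("C", "pcr")] * 2
        call = call_column(_col(*obs), POLICY)
        assert (call.status, call.base) == (STATUS_CALLED, "C")
        assert call.evidence.get("pcr_adjudicated")

    def test_monotone_concordant_evidence(self):
        """Adding a concordant evidence never changes the base and never
        downgrades a called-class status."""
        rng = np.random.default_rng(1)
        called_class = {STATUS_CALLED, STATUS_DAMAGE}
        for _ in range(200):
            n_maj = int(rng.integers(2, 8))
            n_min = int(rng.integers(0, n_maj))
            obs = [_read_obs("A")] * n_maj + [
                _read_obs("CGT"[int(rng.integers(3))],
                          off5=int(rng.integers(50)), off3=int(rng.integers(50)))
                for _ in range(n_min)
            ]
            before = call_column(_col(*obs), POLICY)
            after = call_column(_col(*obs, _read_obs("A")), POLICY)
            if before.status in called_class:
                assert after.status in called_class
                assert after.base == before.base


class TestBuildPileup:
    def _records_and_reads(self, genome, n=40, seed=2):
        rng = np.random.default_rng(seed)
        records, reads = [], {}
        for i in range(n):
            L = int(rng.integers(20, 40))
            start = int(rng.integers(0, len(genome)))
            strand = "+-"[int(rng.integers(2))]
            frag = genome.fragment(start, L)
            seq = frag if strand == "+" else revcomp(frag)
            rid = f"p{i}"
            reads[rid] = Read(rid, seq)
            records.append(AlignmentRecord(rid, genome.id, start, strand, L, 0, mapq=37))
        return records, reads

    def test_counts_match_naive_tally(self, toy_genome):
        records, reads = self._records_and_reads(toy_genome)
        columns = build_pileup(records, reads, POLICY, len(toy_genome))
        # naive per-position re-count
        tally = {p: 0 for p in range(len(toy_genome))}
        for r in records:
            for j in range(r.length):
                tally[(r.start + j) % len(toy_genome)] += 1
        for col in columns:
            assert len(col.observations) == tally[col.position]
            for o in col.observations:
                assert o.base == toy_genome.seq[col.position]  # error-free reads

    def test_mapq_and_duplicate_filtering(self, toy_genome):
        records, reads = self._records_and_reads(toy_genome, n=10)
        records[0].mapq = 0
        records[1].duplicate = True
        columns = build_pileup(records, reads, POLICY, len(toy_genome))
        total = sum(len(c.observations) for c in columns)
        assert total == sum(r.length for r in records[2:])

    def test_single_perfect_read_span(self, toy_genome):
        rid = "one"
        reads = {rid: Read(rid, toy_genome.fragment(10, 30))}
        rec = AlignmentRecord(rid, toy_genome.id, 10, "+", 30, 0, mapq=37)
        columns = build_pileup([rec], reads, POLICY, len(toy_genome))
        for p, col in enumerate(columns):
            assert len(col.observations) == (1 if 10 <= p < 40 else 0)


class TestAssemble:
    def test_clean_high_coverage_recovers_planted_genome(self):
        ref = random_genome(1500, seed=70, gid="ref")
        mutant, _ = plant_variants(ref, 10, 2, [], seed=8)
        reads, _ = simulate_reads(mutant, 1000, dmg=DamageModel.none(), seed=9)
        result = assemble(reads, ref, (), POLICY)
        assert result.consensus.seq == mutant.seq
        assert result.gap_positions == []
        ok, disc = verify_fixed_point(reads, result.consensus, POLICY)
        assert ok and disc == []

    def test_damage_never_reaches_consensus(self):
        """delta = 0.3 terminal damage at ~13x coverage: the consensus
        equals the planted genome at every called position."""
        ref = random_genome(1500, seed=71, gid="ref")
        mutant, _ = plant_variants(ref, 10, 2, [], seed=8)
        dmg = DamageModel(0.3, 0.3, 0.5, 0.0)
        reads, _ = simulate_reads(mutant, 450, dmg=dmg, seed=10)
        result = assemble(reads, ref, (), POLICY)
        for call in result.calls:
            if call.status in (STATUS_CALLED, STATUS_DAMAGE):
                assert call.base == mutant.seq[call.position]

    def test_zero_reads_all_zero_coverage(self):
        ref = random_genome(300, seed=72)
        result = assemble([], ref, (), POLICY)
        assert result.round_stats["status_counts"] == {STATUS_ZERO: 300}
        assert set(result.consensus.seq) == {"N"}
        assert len(result.gap_positions) == 300

    def test_coverage_hole_reported_then_closed_by_pcr(self):
        """A 40 nt hole is the gap list; a spanning PCR product plus one
        overlapping read provide the two evidences that close it."""
        ref = random_genome(1200, seed=73, gid="ref")
        hole = (500, 540)
        reads, truth = simulate_reads(ref, 900, dmg=DamageModel.none(), seed=11)
        kept = [
            r for r in reads
            if truth.reads[r.id].start + truth.reads[r.id].length <= hole[0]
            or truth.reads[r.id].start >= hole[1]
        ]
        bare = assemble(kept, ref, (), POLICY)
        assert set(range(hole[0] + 1, hole[1] + 1)) <= set(bare.gap_positions)
        spanning_read = Read("span", ref.fragment(hole[0] - 20, 80))
        pcr = [("fill", ref.fragment(hole[0] - 60, 160))]
        closed = assemble(kept + [spanning_read], ref, pcr, POLICY)
        assert not set(range(hole[0] + 1, hole[1] + 1)) & set(closed.gap_positions)

    def test_statuses_partition_positions(self):
        ref = random_genome(1000, seed=74, gid="ref")
        mutant, _ = plant_variants(ref, 6, 1, [], seed=12)
        reads, _ = simulate_reads(mutant, 150, seed=13)  # patchy ~4x coverage
        result = assemble(reads, ref, (), POLICY)
        called = sum(
            c.status in (STATUS_CALLED, STATUS_DAMAGE) for c in result.calls
        )
        assert (
            called
            + len(result.gap_positions)
            + len(result.single_positions)
            + len(result.no_consensus_positions)
            == len(ref)
        )
        sc = result.round_stats["round3"]
        assert sc["gap_positions"] == len(result.gap_positions)
        assert sc["single_evidence_positions"] == len(result.single_positions)

    def test_indel_recovery_via_pcr_round(self):
        """Planted 1 bp insertion and 2 bp deletion are absent from the
        ungapped rounds but restored by the PCR verification round."""
        ref = random_genome(2000, seed=75, gid="ref")
        mutant, truth = plant_variants(ref, 12, 2, [("ins", 1), ("del", 2)], seed=14)
        reads, _ = simulate_reads(mutant, 700, dmg=DamageModel(), seed=15)
        first = assemble(reads, ref, (), POLICY)
        problem = [p - 1 for p in first.gap_positions + first.single_positions
                   + first.no_consensus_positions]
        regions = merge_positions(problem, gap=150, n=len(first.frame))
        regions += indel_candidates(first.records, len(first.frame))
        pcr = simulate_pcr_fragments(mutant, first.frame, regions, seed=16)
        result = assemble(reads, ref, pcr, POLICY)
        assert result.consensus.seq == mutant.seq
        ok, _ = verify_fixed_point(reads, result.consensus, POLICY)
        assert ok


class TestVerifyFixedPoint:
    def test_corrupted_base_detected(self):
        ref = random_genome(1000, seed=76, gid="ref")
        reads, _ = simulate_reads(ref, 700, dmg=DamageModel.none(), seed=17)
        corrupted = list(ref.seq)
        corrupted[400] = "A" if corrupted[400] != "A" else "C"
        bad = CircularSequence("bad", "".join(corrupted))
        ok, disc = verify_fixed_point(reads, bad, POLICY)
        assert not ok
        assert [d[0] for d in disc] == [401]

    def test_empty_read_set_vacuously_true(self):
        ref = random_genome(200, seed=77)
        ok, disc = verify_fixed_point([], ref, POLICY)
        assert ok and disc == []


class TestCoverageStats:
    def test_mean_fold_arithmetic(self):
        ref = random_genome(1000, seed=78, gid="ref")
        reads, _ = simulate_reads(ref, 300, dmg=DamageModel.none(), seed=18)
        result = assemble(reads, ref, (), POLICY)
        stats = coverage_stats(result)
        assert stats["mean_fold_coverage"] == pytest.approx(
            stats["evidence_bases"] / len(result.consensus)
        )
        assert stats["depth"].sum() == stats["evidence_bases"]

    def test_single_read_depth(self):
        ref = random_genome(1000, seed=79, gid="ref")
        read = Read("r", ref.fragment(100, 100))
        result = assemble([read], ref, (), POLICY)
        assert coverage_stats(result)["mean_fold_coverage"] == pytest.approx(0.1)
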