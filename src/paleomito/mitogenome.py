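"""Synthetic bovine-like mitogenome panel with a study-profile variant plan.

This builds the full cast of genomes the analysis is exercised on, all
derived from one seeded random reference so every downstream number has a
recoverable ground truth:

* an annotated 16,319 bp circular "modern reference" with the standard
  mammalian complement (13 CDS, 22 tRNA, 2 rRNA, one control region);
* an "ancient" template differing from the reference by a fixed profile of
  events — 105 transitions and 6 transversions (73 substitutions inside
  protein-coding genes at codon positions 16/3/54, of which 11 change the
  amino acid; 24 in the control region; 14 in RNA genes), a 1 bp insertion
  in the control region and a 2 bp deletion at the end of a serine tRNA —
  so the assembled genome is 16,318 bp and 25 of its differences fall in
  the control region;
* a panel of modern conspecific genomes that carry 20 of the ancient
  alleles (19 substitutions and the short tRNA-Ser allele), leaving 93
  ancient-specific polymorphisms, plus a few private substitutions each;
* outgroup genomes derived from an ancestral sequence that retains the
  ancient allele at the modern-derived sites, so the ancient genome is
  basal to the modern clade in phylogenetic reconstruction.

Substitution placement keeps a minimum spacing so every event is
recoverable by exact global alignment, and coding changes are chosen from
codon families of the vertebrate mitochondrial code so that planted silent
and missense counts are silent and missense by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import Feature, compute_intergenic
from .mitocompare import DifferenceRecord, translate_codon
from .seq import CircularSequence, revcomp
from .simdata import _TS_PARTNER, _TV_PARTNERS, _sub_record, _context

REF_LENGTH = 16319
DLOOP_LENGTH = 909  # 910 in the ancient genome after the 1 bp insertion

# study-profile event counts
PROFILE = {
    "pos3_silent_ts": 54,
    "pos1_silent_ts": 8,
    "pos1_missense_ts": 8,
    "pos2_missense_ts": 3,
    "dloop_ts": 20,
    "dloop_tv": 4,
    "rna_ts": 12,
    "rna_tv": 2,
    "shared_subs": 19,  # ancient alleles also present in some modern genome
    "modern_derived": 60,  # sites where the modern lineage, not the ancient, changed
    "stem_sites": 300,  # synapomorphies of (ancient + moderns) vs outgroups
    "n_moderns": 5,
    "private_per_modern": 5,
}

_SPACING = 8

_CDS_LENGTHS = {
    "ND1": 957, "ND2": 1044, "COX1": 1545, "COX2": 684, "ATP8": 201,
    "ATP6": 681, "COX3": 783, "ND3": 345, "ND4L": 297, "ND4": 1377,
    "ND5": 1821, "ND6": 528, "CYTB": 1140,
}

# gene order loosely follows the mammalian arrangement; ND6 on the minus strand
_LAYOUT = [
    ("tRNA-Phe", "tRNA", "+"), ("rRNA-12S", "rRNA", "+"), ("tRNA-Val", "tRNA", "+"),
    ("rRNA-16S", "rRNA", "+"), ("tRNA-Leu1", "tRNA", "+"), ("ND1", "CDS", "+"),
    ("tRNA-Ile", "tRNA", "+"), ("tRNA-Gln", "tRNA", "-"), ("tRNA-Met", "tRNA", "+"),
    ("ND2", "CDS", "+"), ("tRNA-Trp", "tRNA", "+"), ("tRNA-Ala", "tRNA", "-"),
    ("tRNA-Asn", "tRNA", "-"), ("tRNA-Cys", "tRNA", "-"), ("tRNA-Tyr", "tRNA", "-"),
    ("COX1", "CDS", "+"), ("tRNA-Ser2", "tRNA", "-"), ("tRNA-Asp", "tRNA", "+"),
    ("COX2", "CDS", "+"), ("tRNA-Lys", "tRNA", "+"), ("ATP8", "CDS", "+"),
    ("ATP6", "CDS", "+"), ("COX3", "CDS", "+"), ("tRNA-Gly", "tRNA", "+"),
    ("ND3", "CDS", "+"), ("tRNA-Arg", "tRNA", "+"), ("ND4L", "CDS", "+"),
    ("ND4", "CDS", "+"), ("tRNA-His", "tRNA", "+"), ("tRNA-Ser1", "tRNA", "+"),
    ("tRNA-Leu2", "tRNA", "+"), ("ND5", "CDS", "+"), ("ND6", "CDS", "-"),
    ("tRNA-Glu", "tRNA", "-"), ("CYTB", "CDS", "+"), ("tRNA-Thr", "tRNA", "+"),
    ("tRNA-Pro", "tRNA", "-"), ("D-loop", "D-loop", "+"),
]

_RRNA_LENGTHS = {"rRNA-12S": 954, "rRNA-16S": 1566}

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "AGA", "AGG")
]


def build_reference(seed: int = 17) -> CircularSequence:
    """Annotated random reference genome with the layout above."""
    rng = np.random.default_rng(seed)
    trna_names = [n for n, t, _ in _LAYOUT if t == "tRNA"]
    trna_budget = (
        REF_LENGTH
        - sum(_CDS_LENGTHS.values())
        - sum(_RRNA_LENGTHS.values())
        - DLOOP_LENGTH
    )
    base_len, extra = divmod(trna_budget, len(trna_names))
    trna_len = {
        name: base_len + (1 if i < extra else 0) for i, name in enumerate(trna_names)
    }
    parts: list[str] = []
    features: list[Feature] = []
    pos = 1
    for name, ftype, strand in _LAYOUT:
        if ftype == "CDS":
            n_codons = _CDS_LENGTHS[name] // 3
            codons = ["ATG"] + [
                _NONSTOP_CODONS[int(i)]
                for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
            ] + ["TAA"]
            seq = "".join(codons)
            if strand == "-":
                seq = revcomp(seq)
        else:
            length = (
                trna_len[name]
                if ftype == "tRNA"
                else _RRNA_LENGTHS.get(name, DLOOP_LENGTH)
            )
            seq = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=length))
        features.append(Feature(name, ftype, pos, pos + len(seq) - 1, strand))
        parts.append(seq)
        pos += len(seq)
    genome = CircularSequence("bison_ref", "".join(parts), circular=True)
    assert len(genome) == REF_LENGTH
    genome.features = compute_intergenic(features)
    return genome


# ---------------------------------------------------------------------------
# Variant plan
# ---------------------------------------------------------------------------

@dataclass
class VariantPlan:
    """Exact planted events, all 0-based on the reference frame."""

    subs: list[tuple[int, str, str]]  # (pos, ref base, alt base)
    insertion: tuple[int, str]  # inserted after pos
    deletion: tuple[int, int]  # (start, length)
    shared_sub_idx: list[int]  # indices into subs shared with moderns
    modern_derived_idx: list[int]  # indices where the modern lineage changed
    records: list[DifferenceRecord] = field(default_factory=list)


def _feature(genome: CircularSequence, name: str) -> Feature:
    return next(f for f in genome.features if f.name == name)


def _spaced_choice(rng, candidates, k, used):
    out = []
    pool = list(candidates)
    rng.shuffle(pool)
    for p in pool:
        if len(out) == k:
            break
        if all(abs(p - q) >= _SPACING for q in used):
            used.append(p)
            out.append(p)
    if len(out) < k:
        raise RuntimeError("could not place all planted events with spacing")
    return sorted(out)


def plan_variants(ref: CircularSequence, seed: int = 17) -> VariantPlan:
    rng = np.random.default_rng(seed + 1)
    used: list[int] = []
    subs: list[tuple[int, str, str]] = []

    # coding changes: codon picks from plus-strand CDS interiors
    plus_cds = [f for f in ref.features if f.type == "CDS" and f.strand == "+"]
    codon_sites: dict[str, list[tuple[int, str]]] = {"CT_leu": [], "GT": [], "GC": [], "any": []}
    for f in plus_cds:
        n_codons = (f.end - f.start + 1) // 3
        for ci in range(1, n_codons - 1):  # internal codons only
            start0 = f.start - 1 + 3 * ci
            codon = ref.seq[start0 : start0 + 3]
            codon_sites["any"].append((start0, codon))
            if codon in ("CTA", "CTG", "TTA", "TTG"):
                codon_sites["CT_leu"].append((start0, codon))
            if codon[:2] == "GT":
                codon_sites["GT"].append((start0, codon))
            if codon[:2] == "GC":
                codon_sites["GC"].append((start0, codon))

    def pick_codons(pool_key, k, base_offset):
        pool = [s for s, _ in codon_sites[pool_key]]
        chosen = _spaced_choice(rng, pool, k, used)
        return [c + base_offset for c in chosen]

    for p in pick_codons("any", PROFILE["pos3_silent_ts"], 2):
        subs.append((p, ref.seq[p], _TS_PARTNER[ref.seq[p]]))
    for p in pick_codons("CT_leu", PROFILE["pos1_silent_ts"], 0):
        subs.append((p, ref.seq[p], _TS_PARTNER[ref.seq[p]]))  # CTx <-> TTx, silent Leu
    for p in pick_codons("GT", PROFILE["pos1_missense_ts"], 0):
        subs.append((p, "G", "A"))  # GTx -> ATx: Val -> Ile/Met
    for p in pick_codons("GC", PROFILE["pos2_missense_ts"], 1):
        subs.append((p, "C", "T"))  # GCx -> GTx: Ala -> Val

    # control-region changes (keep a margin from the feature edges and
    # leave room for the insertion)
    dloop = _feature(ref, "D-loop")
    d_range = range(dloop.start + 3, dloop.end - 4)
    for p in _spaced_choice(rng, d_range, PROFILE["dloop_ts"], used):
        subs.append((p, ref.seq[p], _TS_PARTNER[ref.seq[p]]))
    for p in _spaced_choice(rng, d_range, PROFILE["dloop_tv"], used):
        subs.append((p, ref.seq[p], _TV_PARTNERS[ref.seq[p]][int(rng.integers(2))]))

    # RNA-gene changes
    rna_pos = []
    for f in ref.features:
        if f.type in ("tRNA", "rRNA") and f.name != "tRNA-Ser1":
            rna_pos.extend(range(f.start + 2, f.end - 3))
    for p in _spaced_choice(rng, rna_pos, PROFILE["rna_ts"], used):
        subs.append((p, ref.seq[p], _TS_PARTNER[ref.seq[p]]))
    for p in _spaced_choice(rng, rna_pos, PROFILE["rna_tv"], used):
        subs.append((p, ref.seq[p], _TV_PARTNERS[ref.seq[p]][int(rng.integers(2))]))

    # 1 bp insertion in the control region, flanks kept distinct
    ins_pos = None
    for p in _spaced_choice(rng, d_range, 30, list(used)):
        choices = [b for b in "ACGT" if b != ref.seq[p] and b != ref.seq[p + 1]]
        if choices and all(abs(p - q) >= _SPACING for q in used):
            ins_pos = p
            ins_base = choices[int(rng.integers(len(choices)))]
            used.append(p)
            break
    assert ins_pos is not None

    # 2 bp deletion at the end of the serine tRNA, placed where the gap
    # cannot slide in an alignment
    ser = _feature(ref, "tRNA-Ser1")
    del_start = None
    for p in range(ser.end - 3, ser.start + 2, -1):
        p0 = p - 1  # 0-based start of the 2 nt run
        # the gap may not slide: no 1 nt shift reproduces the deleted string
        slide_left = ref.seq[p0 - 1] == ref.seq[p0 + 1]
        slide_right = ref.seq[p0] == ref.seq[p0 + 2]
        if not slide_left and not slide_right:
            if all(abs(p0 - q) >= _SPACING for q in used):
                del_start = p0
                used.append(p0)
                break
    assert del_start is not None

    subs.sort()
    n_subs = len(subs)
    idx = list(rng.permutation(n_subs))
    shared = sorted(idx[: PROFILE["shared_subs"]])
    modern_derived = sorted(idx[PROFILE["shared_subs"] : PROFILE["shared_subs"] + PROFILE["modern_derived"]])

    records = [
        _sub_record(ref, p, a, b) for p, a, b in subs
    ]
    records.append(
        DifferenceRecord(
            position=ins_pos + 1,
            kind="insertion",
            base_a="-",
            base_b=ins_base,
            context_a=_context(ref.seq, ins_pos),
        )
    )
    records.append(
        DifferenceRecord(
            position=del_start + 1,
            kind="deletion",
            base_a=ref.seq[del_start : del_start + 2],
            base_b="-",
            context_a=_context(ref.seq, del_start),
        )
    )
    records.sort(key=lambda r: (r.position, r.kind))
    return VariantPlan(
        subs=subs,
        insertion=(ins_pos, ins_base),
        deletion=(del_start, 2),
        shared_sub_idx=shared,
        modern_derived_idx=modern_derived,
        records=records,
    )


def apply_plan(ref: CircularSequence, plan: VariantPlan) -> CircularSequence:
    """The ancient template: reference plus every planted event."""
    seq = list(ref.seq)
    for p, a, b in plan.subs:
        assert seq[p] == a
        seq[p] = b
    ins_pos, ins_base = plan.insertion
    del_start, del_len = plan.deletion
    # apply the higher-coordinate indel first so indices stay valid
    for event in sorted(
        [("ins", ins_pos), ("del", del_start)], key=lambda e: -e[1]
    ):
        if event[0] == "ins":
            seq[ins_pos + 1 : ins_pos + 1] = [ins_base]
        else:
            del seq[del_start : del_start + del_len]
    genome = CircularSequence("ancient_template", "".join(seq), circular=True)
    assert len(genome) == REF_LENGTH - del_len + 1
    return genome


# ---------------------------------------------------------------------------
# Panel and outgroup genomes
# ---------------------------------------------------------------------------

def _mutate(seq: str, positions, rng, tv_fraction: float = 0.1) -> str:
    out = list(seq)
    for p in positions:
        if rng.random() < tv_fraction:
            out[p] = _TV_PARTNERS[out[p]][int(rng.integers(2))]
        else:
            out[p] = _TS_PARTNER[out[p]]
    return "".join(out)


def _fresh_positions(rng, n_total, k, forbidden: set) -> list[int]:
    out: list[int] = []
    while len(out) < k:
        p = int(rng.integers(0, n_total))
        if p in forbidden or p in out:
            continue
        out.append(p)
    return sorted(out)


@dataclass
class StudyGenomes:
    ref: CircularSequence
    plan: VariantPlan
    ancient: CircularSequence
    moderns: list[CircularSequence]
    outgroups: dict[str, CircularSequence]
    contaminant: CircularSequence  # highly divergent screen control (human-like)


def build_study_genomes(seed: int = 17) -> StudyGenomes:
    ref = build_reference(seed)
    plan = plan_variants(ref, seed)
    ancient = apply_plan(ref, plan)
    rng = np.random.default_rng(seed + 2)
    n = len(ref)
    target_positions = {p for p, _, _ in plan.subs}
    target_positions |= {plan.insertion[0], plan.deletion[0], plan.deletion[0] + 1}
    forbidden = set()
    for p in target_positions:
        forbidden.update(range(p - 3, p + 4))

    # modern conspecifics: a few private substitutions plus their assigned
    # share of the ancient alleles
    moderns = []
    n_mod = PROFILE["n_moderns"]
    shared_assignment: dict[int, list[int]] = {i: [] for i in range(n_mod)}
    for k, sub_idx in enumerate(plan.shared_sub_idx):
        shared_assignment[k % n_mod].append(sub_idx)
    deletion_carrier = 2 % n_mod  # the short tRNA-Ser allele exists in moderns too
    for i in range(n_mod):
        seq = list(ref.seq)
        for sub_idx in shared_assignment[i]:
            p, a, b = plan.subs[sub_idx]
            seq[p] = b
        priv = _fresh_positions(rng, n, PROFILE["private_per_modern"], forbidden)
        seq = list(_mutate("".join(seq), priv, rng, tv_fraction=0.0))
        if i == deletion_carrier:
            d, dl = plan.deletion
            del seq[d : d + dl]
        moderns.append(CircularSequence(f"modern_bison_{i + 1}", "".join(seq)))

    # ancestral sequence: carries the ancient allele at modern-derived sites
    # and the stem changes common to ancient + moderns
    anc_seq = list(ref.seq)
    for sub_idx in plan.modern_derived_idx:
        p, a, b = plan.subs[sub_idx]
        anc_seq[p] = b
    stem = _fresh_positions(rng, n, PROFILE["stem_sites"], forbidden)
    anc = _mutate("".join(anc_seq), stem, rng)

    def outgroup(name: str, base: str, rate: float) -> CircularSequence:
        k = int(rate * n)
        pos = _fresh_positions(rng, n, k, forbidden)
        return CircularSequence(name, _mutate(base, pos, rng))

    bonasus = outgroup("bonasus_like", anc, 0.030)
    bos_anc = _mutate(anc, _fresh_positions(rng, n, int(0.040 * n), forbidden), rng)
    taurus = outgroup("taurus_like", bos_anc, 0.007)
    primigenius = outgroup("primigenius_like", bos_anc, 0.007)
    contaminant = outgroup("human_like", anc, 0.220)
    return StudyGenomes(
        ref=ref,
        plan=plan,
        ancient=ancient,
        moderns=moderns,
        outgroups={
            "bonasus_like": bonasus,
            "taurus_like": taurus,
            "primigenius_like": primigenius,
        },
        contaminant=contaminant,
    )
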