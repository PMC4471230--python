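"""Misincorporation profiling: the 12 substitution frequencies by distance
from each read end.

Mismatches between uniquely placed reads and the consensus they align to are
tallied by substitution type (reference-base -> read-base, on the read's
strand orientation) and by offset from the 5' and 3' read ends; frequencies
are normalised per occurrence of the source reference base at that offset.
Post-mortem deamination shows up as C->T inflation at 5' offsets and G->A
inflation at 3' offsets, decaying into the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .mapping import AlignmentRecord
from .seq import CircularSequence, Read, complement

SUBSTITUTIONS = [
    f"{a}>{b}" for a, b in product("ACGT", repeat=2) if a != b
]  # the 12 ordered base pairs

ENDS = ("5p", "3p")


@dataclass
class DamageProfile:
    """freq[sub][end][offset] plus the underlying counts.

    ``numerator[s][e][k]`` counts mismatches of type ``s`` at offset ``k``
    from end ``e``; ``denominator`` counts aligned source bases there.  A
    frequency with zero denominator is NaN (undefined-marked).
    """

    K: int
    numerator: dict[str, dict[str, np.ndarray]]
    denominator: dict[str, dict[str, np.ndarray]]  # keyed by source base
    total_mismatches: int = 0
    total_aligned: int = 0

    def freq(self, sub: str, end: str, offset: int) -> float:
        num = self.numerator[sub][end][offset]
        den = self.denominator[sub[0]][end][offset]
        return float(num) / den if den > 0 else float("nan")

    def identity_percent(self) -> float:
        """Global read-vs-consensus identity, in percent."""
        return identity_percent(self.total_mismatches, self.total_aligned)


def identity_percent(mismatches: int, aligned_bases: int) -> float:
    """100 * (1 - mismatches / aligned bases)."""
    if aligned_bases <= 0:
        raise ValueError("aligned_bases must be positive")
    return 100.0 * (1.0 - mismatches / aligned_bases)


def damage_profile(
    records: Sequence[AlignmentRecord],
    reads: dict[str, Read],
    consensus: CircularSequence,
    K: int = 10,
) -> DamageProfile:
    """Profile mismatches of deduplicated, ungapped records vs ``consensus``.

    Reverse-strand placements are complemented and flipped so everything is
    expressed in the read's own orientation.  Only the K terminal offsets per
    end are profiled; a read shorter than 2K contributes each position to its
    nearer end only (tie -> 5').
    """
    refs = {r.ref_id for r in records}
    if len(refs) > 1:
        raise ValueError(f"records span multiple references: {sorted(refs)}")
    num = {s: {e: np.zeros(K, dtype=np.int64) for e in ENDS} for s in SUBSTITUTIONS}
    den = {b: {e: np.zeros(K, dtype=np.int64) for e in ENDS} for b in "ACGTN"}
    total_mm = 0
    total_bases = 0
    n = len(consensus)
    for rec in records:
        if rec.duplicate:
            continue
        read = reads[rec.read_id]
        L = rec.length
        short = L < 2 * K
        for q in range(L):  # q: offset from the read's own 5' end
            off5 = q
            off3 = L - 1 - q
            if rec.strand == "+":
                pos = (rec.start + q) % n
                ref_base = consensus.seq[pos]
                read_base = read.seq[q]
            else:
                pos = (rec.start + (L - 1 - q)) % n
                ref_base = complement(consensus.seq[pos])
                read_base = read.seq[q]
            total_bases += 1
            mismatch = ref_base != read_base or ref_base == "N" or read_base == "N"
            if mismatch:
                total_mm += 1
            if short:
                # nearer end only; tie -> 5'
                ends = [("5p", off5)] if off5 <= off3 else [("3p", off3)]
            else:
                ends = []
                if off5 < K:
                    ends.append(("5p", off5))
                if off3 < K:
                    ends.append(("3p", off3))
            for end, off in ends:
                if off >= K:
                    continue
                den[ref_base][end][off] += 1
                if mismatch and ref_base in "ACGT" and read_base in "ACGT":
                    num[f"{ref_base}>{read_base}"][end][off] += 1
    return DamageProfile(K, num, den, total_mm, total_bases)


def profile_to_tsv(profile: DamageProfile, path) -> None:
    import pandas as pd

    rows = []
    for sub in SUBSTITUTIONS:
        for end in ENDS:
            for k in range(profile.K):
                n_ = int(profile.numerator[sub][end][k])
                d = int(profile.denominator[sub[0]][end][k])
                rows.append(
                    {
                        "substitution": sub,
                        "end": end,
                        "offset": k,
                        "numerator": n_,
                        "denominator": d,
                        "frequency": n_ / d if d else float("nan"),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_profile(profile: DamageProfile, path) -> None:
    """Two-panel misincorporation plot (5' left, 3' right); optional output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    offsets = np.arange(profile.K)
    for end, ax in zip(ENDS, axes):
        for sub in SUBSTITUTIONS:
            freqs = [profile.freq(sub, end, k) for k in offsets]
            lw = 2.0 if sub in ("C>T", "G>A") else 0.8
            ax.plot(offsets, freqs, label=sub, linewidth=lw)
        ax.set_xlabel(f"offset from {end} end")
        ax.set_title(end)
    axes[0].set_ylabel("mismatch frequency")
    axes[1].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
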