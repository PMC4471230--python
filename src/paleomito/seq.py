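"""Core sequence containers and FASTA/FASTQ input/output.

Coordinates are 0-based half-open internally; report layers convert to
1-based inclusive (GenBank convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC ACGTN only)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class CircularSequence:
    """A nucleotide genome, optionally circular, with optional annotation.

    ``features`` holds :class:`paleomito.annotate.Feature` objects; the
    container itself does not interpret them.
    """

    id: str
    seq: str
    circular: bool = True
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def doubled(self) -> str:
        """Genome concatenated with itself (origin-spanning window support)."""
        return self.seq + self.seq

    def base(self, pos: int) -> str:
        return self.seq[pos % len(self.seq)]

    def fragment(self, start: int, length: int) -> str:
        """Contiguous substring of length ``length`` starting at ``start``.

        Wraps across the origin when the genome is circular; raises
        ``ValueError`` on a linear genome if the window would run off the end.
        """
        n = len(self.seq)
        if length > n:
            raise ValueError(f"fragment length {length} exceeds genome length {n}")
        start %= n
        end = start + length
        if end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise ValueError("fragment runs off the end of a linear sequence")
        return self.seq[start:] + self.seq[: end - n]


@dataclass
class Read:
    """A sequencing read (optionally with a Phred+33 quality string)."""

    id: str
    seq: str
    qual: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[CircularSequence]:
    return [
        CircularSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[CircularSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(Read(rec.id, str(rec.seq), qual))
    return reads


def write_fastq(reads: Sequence[Read], path: str | Path, default_phred: int = 37) -> None:
    """Write Sanger FASTQ; missing qualities become constant ``default_phred``."""
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else chr(default_phred + 33) * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
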