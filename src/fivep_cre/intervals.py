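"""Genomic coordinate model shared by every pipeline stage.

All coordinates inside the package are 0-based half-open; conversions to
1-based conventions (GTF, SAM text) happen only at parse/serialize
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval, optionally stranded.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """End-to-start gap in bp; 0 for adjacent or overlapping intervals."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def opposite(strand: str) -> str:
    if strand == PLUS:
        return MINUS
    if strand == MINUS:
        return PLUS
    return UNSTRANDED
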