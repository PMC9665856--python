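"""CTSS extraction: collapse read-1 alignments to per-cell cDNA 5'-end counts.

A CTSS is a single-bp, strand-specific genomic position of a cDNA 5' end.
Template switching at the mRNA cap typically adds non-templated guanosines
("unencoded G") to the cDNA 5' end, so the fraction of molecules carrying a
5' G that the genome does not encode is a cap signature used downstream to
separate genuine TSS from artifacts. PCR duplicates are collapsed to
molecules on (barcode, UMI, site, strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .intervals import MINUS, PLUS
from .io import AlignmentRead, Genome, REF_CONSUMING


class InvalidAlignmentError(ValueError):
    """Alignment consumes no reference bases."""


@dataclass
class CtssRecord:
    """All molecules whose cDNA 5' end maps to one (chrom, position, strand).

    ``cells`` maps cell barcode to (umi_count, unencoded_g_umi_count), where
    the unencoded-G status of a molecule is the majority vote over its reads
    (ties count as unencoded-G).
    """

    chrom: str
    pos: int
    strand: str
    cells: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def total_umi(self) -> int:
        return sum(u for u, _ in self.cells.values())

    @property
    def total_unencoded_g_umi(self) -> int:
        return sum(g for _, g in self.cells.values())

    @property
    def unencoded_g_fraction(self) -> float:
        total = self.total_umi
        return self.total_unencoded_g_umi / total if total else 0.0


def five_prime_site(read: AlignmentRead) -> Tuple[str, int, str]:
    """Genomic position of the first templated base of the cDNA 5' end.

    Soft-clipped (non-genomic) bases are excluded: for a + strand read this is
    the leftmost aligned reference base, for a - strand read the rightmost.
    """
    ref_len = read.reference_length
    if ref_len == 0:
        raise InvalidAlignmentError("alignment consumes no reference bases")
    if read.strand == PLUS:
        return read.chrom, read.pos, PLUS
    return read.chrom, read.pos + ref_len - 1, MINUS


def _five_prime_walk(read: AlignmentRead) -> Iterator[Tuple[str, str, Optional[int]]]:
    """Yield (op, base-in-read-orientation, ref position) from the 5' end.

    For - strand reads the stored sequence is reference-oriented, so bases are
    complemented and the walk runs from the right end of the CIGAR.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if read.strand == PLUS:
        q, r = 0, read.pos
        for op, n in read.cigar:
            for _ in range(n):
                if op in ("S", "I"):
                    yield op, read.seq[q], None
                    q += 1
                elif op in ("M", "=", "X"):
                    yield "M", read.seq[q], r
                    q += 1
                    r += 1
                elif op in ("D", "N"):
                    r += 1
                # H/P consume nothing
    else:
        q, r = len(read.seq) - 1, read.reference_end - 1
        for op, n in reversed(read.cigar):
            for _ in range(n):
                if op in ("S", "I"):
                    yield op, comp.get(read.seq[q], "N"), None
                    q -= 1
                elif op in ("M", "=", "X"):
                    yield "M", comp.get(read.seq[q], "N"), r
                    q -= 1
                    r -= 1
                elif op in ("D", "N"):
                    r -= 1


def detect_unencoded_g(read: AlignmentRead, genome: Genome, max_g: int = 3) -> int:
    """Count unencoded guanosines at the read's 5' terminus (0..max_g).

    Scanning inward from the 5'-most base: a soft-clipped (or inserted) base
    qualifies iff it is G; an aligned base qualifies iff the read base is G
    and the reference base is not G. The scan stops at the first
    non-qualifying base, so a templated G terminates counting. Reference
    positions beyond the contig read as N (non-G).
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    count = 0
    for op, base, refpos in _five_prime_walk(read):
        if count >= max_g:
            break
        if op in ("S", "I"):
            if base == "G":
                count += 1
            else:
                break
        else:
            ref = genome.base(read.chrom, refpos)
            if read.strand == MINUS:
                ref = comp.get(ref, "N")
            if base == "G" and ref != "G":
                count += 1
            else:
                break
    return count


def aggregate_ctss(
    reads: Iterable[AlignmentRead], genome: Genome, max_g: int = 3
) -> List[CtssRecord]:
    """Aggregate reads into per-site, per-cell molecule counts.

    Reads sharing (barcode, UMI, site, strand) collapse to one molecule whose
    unencoded-G flag is the majority vote of its reads (tie -> flagged).
    Reads without a barcode or UMI are skipped.
    """
    # site -> (barcode, umi) -> [n_reads, n_g_reads]
    sites: Dict[Tuple[str, int, str], Dict[Tuple[str, str], List[int]]] = {}
    for read in reads:
        if not read.barcode or not read.umi:
            continue
        site = five_prime_site(read)
        g = detect_unencoded_g(read, genome) >= 1
        mol = sites.setdefault(site, {}).setdefault((read.barcode, read.umi), [0, 0])
        mol[0] += 1
        mol[1] += int(g)

    records = []
    for (chrom, pos, strand), mols in sorted(sites.items()):
        cells: Dict[str, List[int]] = {}
        for (barcode, _umi), (n_reads, n_g) in mols.items():
            entry = cells.setdefault(barcode, [0, 0])
            entry[0] += 1
            entry[1] += int(2 * n_g >= n_reads)  # majority vote, tie -> True
        records.append(
            CtssRecord(chrom, pos, strand, {bc: (u, g) for bc, (u, g) in cells.items()})
        )
    return records


class CtssIndex:
    """Sorted per-(chrom, strand) position/count arrays for window queries."""

    def __init__(self, records: Iterable[CtssRecord]):
        grouped: Dict[Tuple[str, str], List[Tuple[int, int, int]]] = {}
        for rec in records:
            grouped.setdefault((rec.chrom, rec.strand), []).append(
                (rec.pos, rec.total_umi, rec.total_unencoded_g_umi)
            )
        self._data: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, rows in grouped.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            umi = np.array([r[1] for r in rows], dtype=np.int64)
            gumi = np.array([r[2] for r in rows], dtype=np.int64)
            self._data[key] = (pos, umi, gumi)

    def has(self, chrom: str, strand: str) -> bool:
        return (chrom, strand) in self._data

    def window(
        self, chrom: str, strand: str, start: int, end: int
    ) -> Tuple[int, int]:
        """(UMI, unencoded-G UMI) summed over positions in [start, end)."""
        data = self._data.get((chrom, strand))
        if data is None:
            return 0, 0
        pos, umi, gumi = data
        i, j = np.searchsorted(pos, [start, end])
        return int(umi[i:j].sum()), int(gumi[i:j].sum())

    def umi_in(self, chrom: str, strand: str, start: int, end: int) -> int:
        return self.window(chrom, strand, start, end)[0]


def write_ctss_bed(records: Iterable[CtssRecord], path: str) -> None:
    """Site-level CTSS summary as 6-column BED.

    Name encodes "total_umi;unencoded_g_umi"; score is total UMI.
    """
    with open(path, "w") as out:
        for rec in records:
            out.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\t"
                f"{rec.total_umi};{rec.total_unencoded_g_umi}\t"
                f"{rec.total_umi}\t{rec.strand}\n"
            )


def write_ctss_cells(records: Iterable[CtssRecord], path: str) -> None:
    """Per-cell CTSS detail (TSV) — the lossless interchange for later stages."""
    with open(path, "w") as out:
        out.write("chrom\tpos\tstrand\tbarcode\tumi_count\tunencoded_g_umi_count\n")
        for rec in records:
            for barcode in sorted(rec.cells):
                u, g = rec.cells[barcode]
                out.write(f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{barcode}\t{u}\t{g}\n")


def read_ctss_cells(path: str) -> List[CtssRecord]:
    records: Dict[Tuple[str, int, str], CtssRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not a CTSS per-cell table")
        for line in fh:
            chrom, pos_s, strand, barcode, u, g = line.rstrip("\n").split("\t")
            key = (chrom, int(pos_s), strand)
            rec = records.setdefault(key, CtssRecord(*key))
            rec.cells[barcode] = (int(u), int(g))
    return [records[k] for k in sorted(records)]
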