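"""Readers and writers for the external formats the pipeline consumes.

Alignments come in through :func:`read_alignments` (pysam), the reference
genome through :class:`Genome` (pyfaidx), gene annotation through
:func:`read_gene_annotation` (gffutils) and chromatin-accessibility signal
through :class:`SignalTrack`. All parsed objects use the package-wide
0-based half-open convention; GTF's 1-based inclusive coordinates are
converted at the parse boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pyfaidx
import pysam

from .intervals import MINUS, PLUS, GenomicInterval

QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")

_PYSAM_OPS = "MIDNSHP=X"


class MissingIndexError(RuntimeError):
    """A coordinate-sorted BAM was supplied without its index."""


class TagConfigurationError(ValueError):
    """No read in the file carried the configured barcode/UMI tags."""


class ParseError(ValueError):
    """A text input file violated its format."""


@dataclass
class AlignmentRead:
    """One aligned sequencing read, reduced to the fields the pipeline uses.

    ``cigar`` is a run-length list of (operation char, length); ``pos`` is the
    0-based leftmost aligned reference position.
    """

    chrom: str
    pos: int
    cigar: List[Tuple[str, int]]
    strand: str
    seq: str
    mapq: int
    barcode: Optional[str]
    umi: Optional[str]
    is_read1: bool = True

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in QUERY_CONSUMING)
        if self.seq and qlen != len(self.seq):
            raise ValueError(
                f"cigar consumes {qlen} query bases but sequence has {len(self.seq)}"
            )

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_length


def _from_pysam(seg: pysam.AlignedSegment, cb_tag: str, umi_tag: str) -> AlignmentRead:
    cigar = [(_PYSAM_OPS[op], n) for op, n in (seg.cigartuples or [])]
    barcode = seg.get_tag(cb_tag) if seg.has_tag(cb_tag) else None
    umi = seg.get_tag(umi_tag) if seg.has_tag(umi_tag) else None
    return AlignmentRead(
        chrom=seg.reference_name,
        pos=seg.reference_start,
        cigar=cigar,
        strand=MINUS if seg.is_reverse else PLUS,
        seq=seg.query_sequence or "",
        mapq=seg.mapping_quality,
        barcode=barcode,
        umi=umi,
        is_read1=seg.is_read1 or not seg.is_paired,
    )


def read_alignments(
    path: str,
    min_mapq: int = 10,
    cb_tag: str = "CB",
    umi_tag: str = "UB",
    tally: Optional[Dict[str, int]] = None,
) -> Iterator[AlignmentRead]:
    """Stream primary read-1 alignments with barcode and UMI tags.

    Yields reads in file (coordinate) order. Reads failing the mapq cut,
    secondary/supplementary/unmapped records, read 2, and reads missing the
    barcode or UMI tag are dropped; drop reasons are tallied into ``tally``
    when given. Unpaired reads count as read 1 (single-end 5' libraries).

    Raises :class:`MissingIndexError` for an unindexed BAM and
    :class:`TagConfigurationError` if reads were seen but none carried the
    configured tags.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mode = "rb" if path.endswith((".bam", ".cram")) else "r"
    counters = tally if tally is not None else {}
    for key in ("records", "not_primary_read1", "low_mapq", "untagged", "yielded"):
        counters.setdefault(key, 0)
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if mode == "rb" and not fh.has_index():
            raise MissingIndexError(
                f"{path}: coordinate-sorted BAM requires a .bai/.csi index"
            )
        n_tagged = 0
        for seg in fh.fetch(until_eof=True):
            counters["records"] += 1
            if (
                seg.is_unmapped
                or seg.is_secondary
                or seg.is_supplementary
                or (seg.is_paired and not seg.is_read1)
            ):
                counters["not_primary_read1"] += 1
                continue
            if seg.has_tag(cb_tag) and seg.has_tag(umi_tag):
                n_tagged += 1
            else:
                counters["untagged"] += 1
                continue
            if seg.mapping_quality < min_mapq:
                counters["low_mapq"] += 1
                continue
            counters["yielded"] += 1
            yield _from_pysam(seg, cb_tag, umi_tag)
        if counters["records"] > 0 and n_tagged == 0:
            raise TagConfigurationError(
                f"{path}: no read carried both tags {cb_tag!r} and {umi_tag!r}; "
                "set --cb-tag/--umi-tag to the dialect your aligner emits"
            )


class Genome:
    """Random-access reference sequence, padded with N beyond contig edges."""

    def __init__(self, fasta_path: str):
        self._fa = pyfaidx.Fasta(fasta_path, sequence_always_upper=True)

    @property
    def contigs(self) -> Dict[str, int]:
        return {name: len(rec) for name, rec in self._fa.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Bases of [start, end); positions outside the contig read as N."""
        if chrom not in self._fa:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            return ""
        clen = len(self._fa[chrom])
        lo, hi = max(0, start), min(clen, end)
        core = str(self._fa[chrom][lo:hi]) if hi > lo else ""
        return "N" * (lo - start) + core + "N" * (end - hi)

    def base(self, chrom: str, pos: int) -> str:
        return self.sequence(chrom, pos, pos + 1)


@dataclass
class GeneModel:
    """One annotated gene: its transcript TSS positions and merged exons."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: List[int] = field(default_factory=list)
    exons: List[GenomicInterval] = field(default_factory=list)


def _merge_intervals(ivs: List[GenomicInterval]) -> List[GenomicInterval]:
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def _prevalidate_gtf(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ParseError(f"{path}:{lineno}: expected >=8 tab-separated columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid 1-based span {start}-{end}")


def read_gene_annotation(path: str) -> List[GeneModel]:
    """Parse a GTF into gene models.

    TSS is the transcript start for + strand genes and the transcript end for
    - strand genes, converted to a 0-based position; exon intervals are merged
    per gene.
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=False,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes: Dict[str, GeneModel] = {}
    for tx in db.features_of_type("transcript"):
        gid = tx.attributes.get("gene_id", [tx.id])[0]
        gname = tx.attributes.get("gene_name", [gid])[0]
        model = genes.setdefault(
            gid, GeneModel(gene_id=gid, gene_name=gname, chrom=tx.seqid, strand=tx.strand)
        )
        # GTF is 1-based inclusive: 5' end is start-1 on +, end-1 on -.
        tss = tx.start - 1 if tx.strand == PLUS else tx.end - 1
        if tss not in model.tss:
            model.tss.append(tss)
        for exon in db.children(tx, featuretype="exon"):
            model.exons.append(
                GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
            )
    for model in genes.values():
        model.tss.sort()
        model.exons = _merge_intervals(model.exons)
    return sorted(genes.values(), key=lambda g: (g.chrom, min(g.tss) if g.tss else 0))


class SignalTrack:
    """Piecewise-constant non-negative coverage, queryable at any position.

    Overlapping input intervals are resolved by taking the maximum value;
    positions outside every interval read as 0.
    """

    def __init__(self, segments: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._segs = segments

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[Tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}-{end}")
            if end > start:
                by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        segments = {}
        for chrom, ivs in by_chrom.items():
            bounds = np.unique(
                np.concatenate([[s for s, _, _ in ivs], [e for _, e, _ in ivs]])
            )
            vals = np.zeros(len(bounds) - 1)
            for s, e, v in ivs:
                i, j = np.searchsorted(bounds, [s, e])
                vals[i:j] = np.maximum(vals[i:j], v)
            keep = vals > 0
            segments[chrom] = (bounds[:-1][keep], bounds[1:][keep], vals[keep])
        return cls(segments)

    @classmethod
    def from_bedgraph(cls, path: str) -> "SignalTrack":
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                cols = line.split()
                if len(cols) < 4:
                    raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
                ivs.append((cols[0], int(cols[1]), int(cols[2]), float(cols[3])))
        return cls.from_intervals(ivs)

    @classmethod
    def from_bed(cls, path: str) -> "SignalTrack":
        """Peak BED: value 1 inside peaks, 0 outside."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                cols = line.split()
                ivs.append((cols[0], int(cols[1]), int(cols[2]), 1.0))
        return cls.from_intervals(ivs)

    @classmethod
    def load(cls, path: str) -> "SignalTrack":
        """Dispatch on extension: .bedgraph/.bdg -> coverage, else peak BED."""
        if path.lower().endswith((".bedgraph", ".bdg")):
            return cls.from_bedgraph(path)
        return cls.from_bed(path)

    def value_at(self, chrom: str, pos: int) -> float:
        seg = self._segs.get(chrom)
        if seg is None:
            return 0.0
        starts, ends, vals = seg
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(vals[i])
        return 0.0

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end); uncovered bases contribute 0."""
        if end <= start:
            return 0.0
        seg = self._segs.get(chrom)
        if seg is None:
            return 0.0
        starts, ends, vals = seg
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        total = 0.0
        for i in range(lo, hi):
            total += vals[i] * (min(end, ends[i]) - max(start, starts[i]))
        return total / (end - start)


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write BED6 (BED3 when neither names nor scores are given)."""
    with open(path, "w") as out:
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                out.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_bed(path: str) -> List[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out
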