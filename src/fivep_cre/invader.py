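"""Strand-invasion artifact removal.

During template switching the TS oligo can anneal to a complementary
internal sequence instead of the cap, creating a spurious cDNA 5' end whose
immediately upstream genomic sequence resembles the oligo's 3' terminus. A
CTSS is flagged as a strand invader when the genomic bases directly 5' of
the site (in transcript orientation) are within a small Levenshtein edit
distance of the TSO 3'-end suffix. Whole sites are removed: invasion is a
property of the genomic context, not of individual cells' molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import edlib

from .ctss import CtssRecord
from .intervals import MINUS, revcomp
from .io import Genome

DEFAULT_TSO_SUFFIX = "TATAGGG"


@dataclass(frozen=True)
class StrandInvaderParams:
    tso_suffix: str = DEFAULT_TSO_SUFFIX
    max_edit_distance: int = 2

    def __post_init__(self) -> None:
        if not self.tso_suffix or set(self.tso_suffix) - set("ACGTN"):
            raise ValueError("tso_suffix must be non-empty uppercase ACGTN")
        if not 0 <= self.max_edit_distance < len(self.tso_suffix):
            raise ValueError("require 0 <= max_edit_distance < len(tso_suffix)")


def upstream_sequence(
    site: Tuple[str, int, str], genome: Genome, length: int
) -> str:
    """The ``length`` genomic bases immediately 5' of a CTSS, transcript-oriented.

    For a - strand site this is the reverse complement of the downstream
    genomic bases; positions beyond the contig read as N.
    """
    chrom, pos, strand = site
    if length < 1:
        raise ValueError("length must be >= 1")
    if strand == MINUS:
        return revcomp(genome.sequence(chrom, pos + 1, pos + 1 + length))
    return genome.sequence(chrom, pos - length, pos)


def edit_distance(a: str, b: str) -> int:
    """Global Levenshtein distance; N never matches (not even another N)."""
    # edlib compares characters literally, so N==N would match; remap the two
    # sides' Ns to distinct sentinels to enforce "N matches nothing".
    return edlib.align(a.replace("N", "#"), b.replace("N", "%"), mode="NW")[
        "editDistance"
    ]


def is_strand_invader(
    site: Tuple[str, int, str], genome: Genome, params: StrandInvaderParams
) -> bool:
    up = upstream_sequence(site, genome, len(params.tso_suffix))
    return edit_distance(up, params.tso_suffix) <= params.max_edit_distance


def filter_ctss(
    ctss: Iterable[CtssRecord],
    genome: Genome,
    params: StrandInvaderParams = StrandInvaderParams(),
    tally: Dict[str, float] | None = None,
) -> Tuple[List[CtssRecord], float]:
    """Drop CTSS at strand-invader sites.

    Returns the retained records and the removed fraction of UMIs (0 when the
    input is empty). Per-call tallies land in ``tally`` when given.
    """
    retained: List[CtssRecord] = []
    kept_umi = removed_umi = 0
    removed_sites = 0
    for rec in ctss:
        if is_strand_invader((rec.chrom, rec.pos, rec.strand), genome, params):
            removed_umi += rec.total_umi
            removed_sites += 1
        else:
            kept_umi += rec.total_umi
            retained.append(rec)
    total = kept_umi + removed_umi
    frac = removed_umi / total if total else 0.0
    if tally is not None:
        tally.update(
            {
                "input_umi": total,
                "removed_umi": removed_umi,
                "removed_sites": removed_sites,
                "removed_fraction": frac,
            }
        )
    return retained, frac
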