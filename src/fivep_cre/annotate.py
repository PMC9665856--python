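"""tCRE annotation: merge TSS clusters into regulatory elements.

A transcribed cis-regulatory element (tCRE) is an unstranded DNA element —
promoter-like (proximal to an annotated gene TSS) or enhancer-like (distal)
— built by single-linkage merging of nearby filtered TSS clusters from both
strands. Distal tCREs are further stitched into loci, and loci with
disproportionately high aggregate activity (above an elbow point of the
ranked-activity curve, as in super-enhancer calling) are flagged
hyperactive. Directionality summarizes the strand balance of transcription
within a tCRE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .cluster import TssCluster
from .ctss import CtssIndex
from .intervals import MINUS, PLUS, GenomicInterval
from .io import GeneModel

PROXIMAL = "proximal"
DISTAL = "distal"


@dataclass
class Tcre:
    """One unstranded tCRE: the union span of its member TSS clusters."""

    chrom: str
    start: int
    end: int
    members: List[TssCluster] = field(default_factory=list)
    cre_class: str = DISTAL

    @property
    def total_umi(self) -> int:
        return sum(c.total_umi for c in self.members)

    @property
    def dominant_strand(self) -> str:
        plus = sum(c.total_umi for c in self.members if c.strand == PLUS)
        minus = sum(c.total_umi for c in self.members if c.strand == MINUS)
        return MINUS if minus > plus else PLUS

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def tcre_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end};{self.cre_class}"


@dataclass
class StitchedLocus:
    chrom: str
    start: int
    end: int
    member_ids: List[str]
    total_umi: int
    rank: int = 0  # ascending UMI rank among loci
    hyperactive: bool = False


def _single_linkage(
    items: Sequence[Tuple[str, int, int]], max_gap: int
) -> List[List[int]]:
    """Chain intervals (chrom, start, end) whose end-to-start gap <= max_gap.

    Input need not be sorted; chains are built on the canonical coordinate
    order so the result is input-order independent. Returns groups of input
    indices.
    """
    order = sorted(range(len(items)), key=lambda i: (items[i][0], items[i][1], items[i][2]))
    groups: List[List[int]] = []
    cur: List[int] = []
    cur_chrom, cur_end = None, -1
    for i in order:
        chrom, start, end = items[i]
        gap = max(0, start - cur_end)
        if cur and chrom == cur_chrom and gap <= max_gap:
            cur.append(i)
            cur_end = max(cur_end, end)
        else:
            if cur:
                groups.append(cur)
            cur = [i]
            cur_chrom, cur_end = chrom, end
    if cur:
        groups.append(cur)
    return groups


def merge_clusters(clusters: Sequence[TssCluster], merge_distance: int = 500) -> List[Tcre]:
    """Single-linkage merge of filtered clusters (both strands) into tCREs."""
    items = [(c.chrom, c.start, c.end) for c in clusters]
    tcres = []
    for group in _single_linkage(items, merge_distance):
        members = [clusters[i] for i in group]
        tcres.append(
            Tcre(
                chrom=members[0].chrom,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                members=members,
            )
        )
    tcres.sort(key=lambda t: (t.chrom, t.start, t.end))
    return tcres


def classify_proximity(
    tcre: Tcre,
    gene_models: Sequence[GeneModel],
    proximal_distance: int = 500,
    _tss_by_chrom: Optional[Dict[str, np.ndarray]] = None,
) -> str:
    """Proximal iff any annotated gene TSS lies within ``proximal_distance``
    bp of the tCRE span (distance 0 inside the span); else distal."""
    if _tss_by_chrom is None:
        _tss_by_chrom = annotated_tss_by_chrom(gene_models)
    tss = _tss_by_chrom.get(tcre.chrom)
    if tss is None or len(tss) == 0:
        return DISTAL
    # distance from a point p to [start, end): 0 if inside
    i = np.searchsorted(tss, tcre.start)
    # nearest TSS is around the insertion points of start and end-1
    cand = tss[max(0, i - 1) : np.searchsorted(tss, tcre.end) + 1]
    if len(cand) == 0:
        return DISTAL
    dist = np.where(
        (cand >= tcre.start) & (cand < tcre.end),
        0,
        np.minimum(np.abs(cand - tcre.start), np.abs(cand - (tcre.end - 1))),
    )
    return PROXIMAL if int(dist.min()) <= proximal_distance else DISTAL


def annotated_tss_by_chrom(gene_models: Sequence[GeneModel]) -> Dict[str, np.ndarray]:
    by_chrom: Dict[str, List[int]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).extend(g.tss)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}


def annotate_tcres(
    clusters: Sequence[TssCluster],
    gene_models: Sequence[GeneModel],
    merge_distance: int = 500,
    proximal_distance: int = 500,
    warn=None,
) -> List[Tcre]:
    """Merge clusters and classify each tCRE as proximal or distal."""
    tcres = merge_clusters(clusters, merge_distance)
    tss_map = annotated_tss_by_chrom(gene_models)
    if not any(len(v) for v in tss_map.values()) and warn is not None:
        warn("no annotated gene TSS: all tCREs classified distal")
    for t in tcres:
        t.cre_class = classify_proximity(t, gene_models, proximal_distance, tss_map)
    return tcres


def stitch_distal(
    distal_tcres: Sequence[Tcre], stitch_distance: int = 12500
) -> List[StitchedLocus]:
    """Single-linkage stitching of distal tCREs into loci."""
    if any(t.cre_class != DISTAL for t in distal_tcres):
        raise ValueError("stitch_distal expects distal tCREs only")
    items = [(t.chrom, t.start, t.end) for t in distal_tcres]
    loci = []
    for group in _single_linkage(items, stitch_distance):
        members = [distal_tcres[i] for i in group]
        loci.append(
            StitchedLocus(
                chrom=members[0].chrom,
                start=min(t.start for t in members),
                end=max(t.end for t in members),
                member_ids=[t.tcre_id for t in members],
                total_umi=sum(t.total_umi for t in members),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end))
    return loci


def elbow_cutoff(loci_totals: Sequence[float]) -> float:
    """Activity threshold above which stitched loci are called hyperactive.

    Totals are ranked ascending and both rank and total are scaled to [0,1];
    the cutoff is the total at the first rank where the discrete slope of the
    scaled curve exceeds 1 (the elbow of the hockey-stick curve used for
    super-enhancer calling). Raises on fewer than 3 loci.
    """
    totals = np.sort(np.asarray(loci_totals, dtype=float))
    n = len(totals)
    if n < 3:
        raise ValueError("elbow cutoff needs >= 3 loci")
    span = totals[-1] - totals[0]
    if span == 0:
        return float(totals[-1])  # flat curve: nothing exceeds the cutoff
    x = np.arange(n) / (n - 1)
    y = (totals - totals[0]) / span
    slopes = np.diff(y) / np.diff(x)
    above = np.nonzero(slopes > 1.0)[0]
    if len(above) == 0:
        return float(totals[-1])
    return float(totals[above[0]])


def flag_hyperactive(loci: List[StitchedLocus], warn=None) -> Optional[float]:
    """Rank loci by total UMI and flag those above the elbow cutoff.

    Returns the cutoff, or None when there are too few loci to define one
    (then nothing is flagged).
    """
    order = np.argsort([l.total_umi for l in loci], kind="stable")
    for rank, i in enumerate(order):
        loci[int(i)].rank = rank
    try:
        cutoff = elbow_cutoff([l.total_umi for l in loci])
    except ValueError:
        if warn is not None:
            warn("fewer than 3 stitched loci: no hyperactive calls")
        return None
    for l in loci:
        l.hyperactive = l.total_umi > cutoff
    return cutoff


def directionality(tcre: Tcre, index: CtssIndex) -> Optional[float]:
    """Strand balance (plus - minus)/(plus + minus) of CTSS UMIs in the tCRE.

    None when the tCRE span carries no UMIs (undefined).
    """
    plus = index.umi_in(tcre.chrom, PLUS, tcre.start, tcre.end)
    minus = index.umi_in(tcre.chrom, MINUS, tcre.start, tcre.end)
    if plus + minus == 0:
        return None
    return (plus - minus) / (plus + minus)


def write_tcre_bed(tcres: Sequence[Tcre], path: str) -> None:
    with open(path, "w") as out:
        for t in tcres:
            out.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.tcre_id}\t{t.total_umi}\t"
                f"{t.dominant_strand}\n"
            )


def write_loci_bed(loci: Sequence[StitchedLocus], path: str) -> None:
    with open(path, "w") as out:
        for l in loci:
            flag = "hyperactive" if l.hyperactive else "normal"
            out.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{flag};rank={l.rank}\t{l.total_umi}\t.\n"
            )


def write_directionality(
    tcres: Sequence[Tcre], index: CtssIndex, path: str
) -> None:
    with open(path, "w") as out:
        out.write("tcre_id\ttotal_umi\tdirectionality\n")
        for t in tcres:
            d = directionality(t, index)
            out.write(f"{t.tcre_id}\t{t.total_umi}\t{'NA' if d is None else f'{d:.6f}'}\n")
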