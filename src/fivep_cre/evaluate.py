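"""Compare pipeline output against a simulated bundle's ground truth."""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotate import Tcre
from .cluster import TssCluster
from .simulate import EXON_PAINTING, PROMOTER, STRAND_INVADER


def truth_invader_fraction(molecules: pd.DataFrame) -> float:
    return float((molecules["origin"] == STRAND_INVADER).mean())


def cluster_majority_origin(
    clusters: Sequence[TssCluster], molecules: pd.DataFrame
) -> List[str]:
    """Majority truth origin of the molecules inside each cluster's span."""
    grouped = molecules.groupby(["chrom", "strand", "pos"])["origin"]
    counts = grouped.value_counts().unstack(fill_value=0)
    out = []
    for c in clusters:
        try:
            sub = counts.loc[(c.chrom, c.strand)]
        except KeyError:
            out.append("none")
            continue
        window = sub.loc[(sub.index >= c.start) & (sub.index < c.end)].sum()
        out.append(window.idxmax() if window.sum() else "none")
    return out


def promoter_recovery(
    kept_clusters: Sequence[TssCluster],
    promoters: pd.DataFrame,
    window: int = 100,
) -> float:
    """Fraction of planted promoters with a kept same-strand cluster within
    +/- ``window`` bp of the TSS."""
    hit = 0
    for row in promoters.itertuples(index=False):
        for c in kept_clusters:
            if (
                c.chrom == row.chrom
                and c.strand == row.strand
                and c.start <= row.tss + window
                and c.end > row.tss - window
            ):
                hit += 1
                break
    return hit / len(promoters) if len(promoters) else 0.0


def painting_removal(
    clusters: Sequence[TssCluster],
    kept: Sequence[bool],
    molecules: pd.DataFrame,
) -> Tuple[float, int]:
    """(fraction of exon-painting-majority clusters removed, their number).

    ``clusters`` are the post-filter candidates entering classification and
    ``kept`` the classifier's keep-mask over them.
    """
    origins = cluster_majority_origin(clusters, molecules)
    painting = [(o == EXON_PAINTING) for o in origins]
    n = sum(painting)
    if n == 0:
        return 1.0, 0
    removed = sum(1 for p, k in zip(painting, kept) if p and not k)
    return removed / n, n


def truth_umi_in_tcres(
    molecules: pd.DataFrame,
    tcres: Sequence[Tcre],
    retained_sites: Set[Tuple[str, int, str]],
) -> int:
    """Truth molecules at invader-filter-retained sites inside kept tCREs."""
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for t in tcres:
        spans.setdefault(t.chrom, []).append((t.start, t.end))
    for chrom in spans:
        spans[chrom].sort()
    total = 0
    for row in molecules.itertuples(index=False):
        if (row.chrom, row.pos, row.strand) not in retained_sites:
            continue
        ivs = spans.get(row.chrom)
        if not ivs:
            continue
        starts = [s for s, _ in ivs]
        k = int(np.searchsorted(starts, row.pos, side="right")) - 1
        if k >= 0 and row.pos < ivs[k][1]:
            total += 1
    return total
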