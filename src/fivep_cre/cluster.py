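"""TSS clustering by the Paraclu parametric density recursion.

Paraclu groups single-bp CTSS into a laminar hierarchy of intervals, each
stable over a range of density (UMI/bp) thresholds. For the sites of one
chromosome+strand the recursion finds the weakest "break" — the minimum over
proper prefix densities sum(counts of s_1..s_k)/(pos_{k+1}-pos_1) and proper
suffix densities sum(counts of s_k..s_n)/(pos_n-pos_{k-1}) — emits the whole
interval as a cluster whose max_density is that break density (and whose
min_density is the floor inherited from its parent), then recurses on the
two halves split at the break with the break density as the new floor.
Cluster stability is max_density/min_density; clusters stable over a wide
density range survive the post-filter.

Ties among equally weak breaks are resolved deterministically: prefix breaks
before suffix breaks, smaller k first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .ctss import CtssRecord


@dataclass
class TssCluster:
    """One strand-specific TSS cluster from the Paraclu hierarchy."""

    chrom: str
    strand: str
    start: int  # 0-based inclusive: first member site
    end: int  # 0-based exclusive: last member site + 1
    positions: np.ndarray
    counts: np.ndarray
    min_density: float
    max_density: float

    @property
    def total_umi(self) -> int:
        return int(self.counts.sum())

    @property
    def summit(self) -> int:
        return find_summit(self)

    @property
    def stability(self) -> float:
        if self.min_density == 0:
            return math.inf
        return self.max_density / self.min_density

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end},{self.strand}"

    def __len__(self) -> int:
        return self.end - self.start


def find_summit(cluster: TssCluster) -> int:
    """Member position with the maximal UMI count; ties break leftmost."""
    if len(cluster.positions) == 0:
        raise ValueError("empty cluster has no summit")
    return int(cluster.positions[int(np.argmax(cluster.counts))])


def paraclu(
    sites: Sequence[Tuple[int, int]],
    min_density_floor: float = 0.0,
    chrom: str = ".",
    strand: str = ".",
) -> List[TssCluster]:
    """Full Paraclu hierarchy for the sorted sites of one chrom+strand.

    Returns every cluster in the laminar hierarchy (pre-order). Single-site
    clusters get max_density = +inf.
    """
    if not sites:
        return []
    pos = np.asarray([p for p, _ in sites], dtype=np.int64)
    cnt = np.asarray([c for _, c in sites], dtype=np.float64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("site positions must be strictly increasing")
    if np.any(cnt <= 0):
        raise ValueError("site counts must be positive")
    csum = np.concatenate([[0.0], np.cumsum(cnt)])  # csum[k] = counts of first k

    out: List[TssCluster] = []
    stack: List[Tuple[int, int, float]] = [(0, len(pos), min_density_floor)]
    while stack:
        i, j, floor = stack.pop()
        n = j - i
        if n == 1:
            out.append(
                TssCluster(
                    chrom, strand, int(pos[i]), int(pos[i]) + 1,
                    pos[i:j], cnt[i:j], floor, math.inf,
                )
            )
            continue
        # proper prefixes s_i..s_k (local k = i..j-2 inclusive)
        pre = (csum[i + 1 : j] - csum[i]) / (pos[i + 1 : j] - pos[i])
        # proper suffixes s_k..s_j-1 (local k = i+1..j-1)
        suf = (csum[j] - csum[i + 1 : j]) / (pos[j - 1] - pos[i : j - 1])
        kp = int(np.argmin(pre))
        ks = int(np.argmin(suf))
        if pre[kp] <= suf[ks]:
            break_density = float(pre[kp])
            split = i + kp + 1  # halves: [i, split), [split, j)
        else:
            break_density = float(suf[ks])
            split = i + ks + 1
        out.append(
            TssCluster(
                chrom, strand, int(pos[i]), int(pos[j - 1]) + 1,
                pos[i:j], cnt[i:j], floor, break_density,
            )
        )
        # push right then left so output is pre-order, left first
        stack.append((split, j, break_density))
        stack.append((i, split, break_density))
    return out


def post_filter(
    clusters: Iterable[TssCluster],
    stability_min: float = 2.0,
    min_umi: int = 5,
    max_length: int = 500,
    min_density_floor: float = 0.0,
) -> List[TssCluster]:
    """Stability/size/count filters plus outermost-survivor resolution.

    A cluster qualifies when stability >= stability_min, total UMI >= min_umi
    and length <= max_length; within each nested chain of qualifying clusters
    only the outermost is kept.
    """
    qualifying = [
        c
        for c in clusters
        if c.stability >= stability_min
        and c.total_umi >= min_umi
        and len(c) <= max_length
        and c.max_density >= min_density_floor
    ]
    qualifying.sort(key=lambda c: (c.chrom, c.strand, c.start, -c.end))
    kept: List[TssCluster] = []
    last: Dict[Tuple[str, str], TssCluster] = {}
    for c in qualifying:
        prev = last.get((c.chrom, c.strand))
        if prev is not None and c.start >= prev.start and c.end <= prev.end:
            continue  # nested inside an already-kept survivor (laminar family)
        kept.append(c)
        last[(c.chrom, c.strand)] = c
    return kept


def cluster_ctss(
    records: Iterable[CtssRecord],
    stability_min: float = 2.0,
    min_umi: int = 5,
    max_length: int = 500,
    min_density_floor: float = 0.0,
) -> List[TssCluster]:
    """Cluster CTSS records strand-separately and apply the post-filter."""
    grouped: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for rec in records:
        grouped.setdefault((rec.chrom, rec.strand), []).append((rec.pos, rec.total_umi))
    final: List[TssCluster] = []
    for (chrom, strand), sites in sorted(grouped.items()):
        sites.sort()
        hierarchy = paraclu(sites, min_density_floor, chrom=chrom, strand=strand)
        final.extend(
            post_filter(hierarchy, stability_min, min_umi, max_length, min_density_floor)
        )
    final.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return final


def write_clusters_bed(clusters: Sequence[TssCluster], path: str) -> None:
    with open(path, "w") as out:
        for c in clusters:
            out.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t{c.total_umi}\t{c.strand}\n"
            )


def write_cluster_table(clusters: Sequence[TssCluster], path: str) -> None:
    """Detail table: summit, density bounds, member count."""
    with open(path, "w") as out:
        out.write(
            "name\tchrom\tstart\tend\tstrand\ttotal_umi\tsummit\t"
            "n_sites\tmin_density\tmax_density\n"
        )
        for c in clusters:
            out.write(
                f"{c.name}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t"
                f"{c.total_umi}\t{c.summit}\t{len(c.positions)}\t"
                f"{c.min_density:.6g}\t{c.max_density:.6g}\n"
            )
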