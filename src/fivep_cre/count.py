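"""tCRE-by-cell UMI count matrix.

The count of a (tCRE, cell) pair sums the cell's deduplicated molecules over
all CTSS positions, on either strand, falling inside the tCRE span. Output
follows the de-facto single-cell triple-file layout: MatrixMarket integer
coordinate matrix + features TSV + barcodes TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.io
import scipy.sparse

from .annotate import Tcre
from .ctss import CtssRecord


@dataclass
class CountMatrix:
    """Sparse tCRE-by-cell UMI counts as coordinate triplets."""

    feature_ids: List[str]
    barcodes: List[str]
    triplets: List[Tuple[int, int, int]]  # (feature index, cell index, count > 0)

    def validate(self) -> None:
        nf, nc = len(self.feature_ids), len(self.barcodes)
        seen = set()
        for fi, ci, v in self.triplets:
            if not (0 <= fi < nf and 0 <= ci < nc):
                raise ValueError(f"triplet ({fi},{ci}) out of range")
            if v <= 0 or int(v) != v:
                raise ValueError("counts must be positive integers")
            if (fi, ci) in seen:
                raise ValueError(f"duplicate triplet ({fi},{ci})")
            seen.add((fi, ci))

    @property
    def total(self) -> int:
        return sum(v for _, _, v in self.triplets)

    def to_sparse(self) -> scipy.sparse.coo_matrix:
        rows = [t[0] for t in self.triplets]
        cols = [t[1] for t in self.triplets]
        vals = [t[2] for t in self.triplets]
        return scipy.sparse.coo_matrix(
            (vals, (rows, cols)),
            shape=(len(self.feature_ids), len(self.barcodes)),
            dtype=np.int64,
        )


def count_matrix(
    ctss: Iterable[CtssRecord],
    tcres: Sequence[Tcre],
    barcode_whitelist: Optional[Sequence[str]] = None,
) -> CountMatrix:
    """Build the tCRE-by-cell matrix from filtered CTSS.

    tCREs must be non-overlapping (guaranteed by the merge stage). When a
    whitelist is given, its barcodes define the cell axis — including cells
    with zero counts — and other barcodes are dropped; otherwise the cell
    axis is the sorted set of observed barcodes.
    """
    ids = [t.tcre_id for t in tcres]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tCRE ids")
    order = sorted(range(len(tcres)), key=lambda i: (tcres[i].chrom, tcres[i].start))
    for a, b in zip(order, order[1:]):
        if (
            tcres[a].chrom == tcres[b].chrom
            and tcres[b].start < tcres[a].end
        ):
            raise ValueError("tCREs must be non-overlapping")
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {t.chrom for t in tcres}:
        idx = [i for i in order if tcres[i].chrom == chrom]
        by_chrom[chrom] = (
            np.array([tcres[i].start for i in idx], dtype=np.int64),
            np.array([tcres[i].end for i in idx], dtype=np.int64),
            np.array(idx, dtype=np.int64),
        )

    counts: Dict[Tuple[int, str], int] = {}
    observed = set()
    for rec in ctss:
        seg = by_chrom.get(rec.chrom)
        if seg is None:
            continue
        starts, ends, idx = seg
        k = int(np.searchsorted(starts, rec.pos, side="right")) - 1
        if k < 0 or rec.pos >= ends[k]:
            continue
        fi = int(idx[k])
        for barcode, (umi, _g) in rec.cells.items():
            observed.add(barcode)
            key = (fi, barcode)
            counts[key] = counts.get(key, 0) + umi

    if barcode_whitelist is not None:
        barcodes = list(barcode_whitelist)
    else:
        barcodes = sorted(observed)
    cell_index = {bc: i for i, bc in enumerate(barcodes)}
    triplets = sorted(
        (fi, cell_index[bc], v)
        for (fi, bc), v in counts.items()
        if bc in cell_index
    )
    mat = CountMatrix(ids, barcodes, triplets)
    mat.validate()
    return mat


def write_matrix_dir(mat: CountMatrix, out_dir: str) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), mat.to_sparse(), field="integer"
    )
    with open(os.path.join(out_dir, "features.tsv"), "w") as out:
        out.write("".join(f"{fid}\n" for fid in mat.feature_ids))
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as out:
        out.write("".join(f"{bc}\n" for bc in mat.barcodes))


def read_matrix_dir(path: str) -> CountMatrix:
    m = scipy.io.mmread(os.path.join(path, "matrix.mtx")).tocoo()
    with open(os.path.join(path, "features.tsv")) as fh:
        features = [line.rstrip("\n") for line in fh if line.strip()]
    with open(os.path.join(path, "barcodes.tsv")) as fh:
        barcodes = [line.rstrip("\n") for line in fh if line.strip()]
    triplets = sorted(
        (int(r), int(c), int(v)) for r, c, v in zip(m.row, m.col, m.data)
    )
    mat = CountMatrix(features, barcodes, triplets)
    mat.validate()
    return mat
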