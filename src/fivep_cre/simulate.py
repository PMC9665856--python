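"""Synthetic sc-end5-seq bundles with known per-molecule ground truth.

The generator emulates the statistical structure the pipeline assumes:

* genuine promoters — sharp CTSS peaks (discretized normal spread around
  each gene TSS), high unencoded-G probability, high ATAC signal;
* exon-painting artifacts — 5'-end signal scattered uniformly over the
  exons of expressed genes, so artifact counts are proportional to
  transcript abundance (the failure mode that defeats count-based
  classifiers), with low unencoded-G probability and no ATAC signal;
* strand invaders — molecules planted at dedicated intergenic sites whose
  upstream genomic sequence is set to the TSO 3' suffix exactly.

Each emitted read traces to exactly one truth-table row. Promoter
neighbourhoods are rejection-sampled so that no upstream 7-mer within the
CTSS spread zone lies within the invader edit-distance threshold of the TSO
suffix; planted invader labels are therefore exact, which the pipeline's
removed-fraction check relies on. Reads are written directly as consistent
alignments (plain-text SAM with CB/UB tags) against the emitted genome;
no read-mapping step is simulated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .intervals import MINUS, PLUS, revcomp
from .invader import edit_distance

PROMOTER = "promoter"
EXON_PAINTING = "exon_painting"
STRAND_INVADER = "strand_invader"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    genome_length: int = 500_000  # total over contigs
    n_contigs: int = 2
    n_genes: int = 40
    n_cells: int = 60
    expression_sigma: float = 1.0  # log-normal sd of per-gene expression
    promoter_sd: float = 15.0  # bp spread of genuine CTSS around the TSS
    exon_painting_rate: float = 0.15  # per transcript UMI
    unencoded_g_prob_genuine: float = 0.7
    unencoded_g_prob_artifact: float = 0.1
    strand_invader_fraction: float = 0.03
    n_invader_sites: int = 30
    umis_per_cell_mean: float = 400.0
    umis_per_cell_dispersion: float = 10.0  # negative-binomial size
    read_length: int = 50
    duplicate_rate: float = 0.1  # chance a molecule is observed as two reads
    tso_suffix: str = "TATAGGG"
    invader_max_edit: int = 2
    atac_half_width: int = 200
    atac_value: float = 10.0

    def validate(self) -> None:
        for name in (
            "exon_painting_rate",
            "unencoded_g_prob_genuine",
            "unencoded_g_prob_artifact",
            "strand_invader_fraction",
            "duplicate_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_contigs < 1 or self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_contigs, n_genes and n_cells must be positive")
        if self.genome_length // self.n_contigs < 20_000:
            raise ValueError("contigs too short for the gene layout")
        if self.promoter_sd <= 0 or self.read_length < 20:
            raise ValueError("invalid promoter_sd or read_length")


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: List[Tuple[int, int]]  # 0-based half-open, genomic order


@dataclass
class Bundle:
    """Paths and in-memory ground truth of one simulated dataset."""

    out_dir: str
    genome_fasta: str
    gtf: str
    alignments: str  # coordinate-sorted SAM with CB/UB tags
    atac_bedgraph: str
    truth_molecules_tsv: str
    truth_promoters_tsv: str
    molecules: pd.DataFrame  # chrom pos strand barcode umi origin unencoded_g gene_id
    promoters: pd.DataFrame  # gene_id chrom tss strand atac_high
    barcodes: List[str] = field(default_factory=list)
    config: Optional[SimulationConfig] = None


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _encode_umi(value: int, length: int = 10) -> str:
    out = []
    for _ in range(length):
        out.append("ACGT"[value & 3])
        value >>= 2
    return "".join(out)


def _lay_out_genes(cfg: SimulationConfig, rng: np.random.Generator) -> List[SimGene]:
    contig_len = cfg.genome_length // cfg.n_contigs
    per_contig = [cfg.n_genes // cfg.n_contigs] * cfg.n_contigs
    for i in range(cfg.n_genes % cfg.n_contigs):
        per_contig[i] += 1
    exon_lengths = (400, 600, 800)
    intron_length = 500
    genes = []
    gid = 0
    for ci in range(cfg.n_contigs):
        chrom = f"chr{ci + 1}"
        n = per_contig[ci]
        if n == 0:
            continue
        slot = contig_len // n
        span = sum(exon_lengths) + intron_length * (len(exon_lengths) - 1)
        if slot < span + 8000:
            raise ValueError("gene slots too small; increase genome_length")
        for k in range(n):
            gid += 1
            strand = PLUS if rng.random() < 0.5 else MINUS
            jitter = int(rng.integers(-500, 501))
            left = k * slot + 4000 + jitter  # leftmost genomic base of the gene
            exons = []
            pos = left
            for el in exon_lengths:
                exons.append((pos, pos + el))
                pos += el + intron_length
            tss = left if strand == PLUS else exons[-1][1] - 1
            genes.append(SimGene(f"G{gid:04d}", chrom, strand, tss, exons))
    return genes


def _sanitize_promoter_zone(
    seq: np.ndarray, gene: SimGene, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    """Resample bases until no upstream 7-mer near the TSS looks like the TSO."""
    L = len(cfg.tso_suffix)
    zone = range(gene.tss - 60, gene.tss + 61)
    for _ in range(200):
        bad = None
        for p in zone:
            if gene.strand == PLUS:
                window = _decode(seq[p - L : p])
            else:
                window = revcomp(_decode(seq[p + 1 : p + 1 + L]))
            if edit_distance(window, cfg.tso_suffix) <= cfg.invader_max_edit:
                bad = p
                break
        if bad is None:
            return
        if gene.strand == PLUS:
            seq[bad - L : bad] = _random_seq(rng, L)
        else:
            seq[bad + 1 : bad + 1 + L] = _random_seq(rng, L)
    raise RuntimeError("could not sanitize promoter zone")


def simulate_bundle(cfg: SimulationConfig, out_dir: str) -> Bundle:
    """Generate a complete test bundle; byte-identical for a fixed seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(out_dir, exist_ok=True)
    contig_len = cfg.genome_length // cfg.n_contigs
    contigs = {f"chr{i + 1}": _random_seq(rng, contig_len) for i in range(cfg.n_contigs)}

    genes = _lay_out_genes(cfg, rng)
    for g in genes:
        _sanitize_promoter_zone(contigs[g.chrom], g, cfg, rng)

    # intergenic strand-invader sites: upstream sequence set to the TSO suffix
    invader_sites: List[Tuple[str, int, str]] = []
    L = len(cfg.tso_suffix)
    slots: List[Tuple[str, int]] = []
    per_contig: Dict[str, int] = {}
    for g in genes:
        per_contig[g.chrom] = per_contig.get(g.chrom, 0) + 1
    for chrom, n in per_contig.items():
        slot = contig_len // n
        for k in range(n):
            slots.append((chrom, k * slot + 1200))
    for chrom, pos in slots[: cfg.n_invader_sites]:
        strand = PLUS if rng.random() < 0.5 else MINUS
        seq = contigs[chrom]
        if strand == PLUS:
            seq[pos - L : pos] = [("ACGT").index(b) for b in cfg.tso_suffix]
        else:
            seq[pos + 1 : pos + 1 + L] = [("ACGT").index(b) for b in revcomp(cfg.tso_suffix)]
        invader_sites.append((chrom, pos, strand))

    # per-gene expression weights (log-normal)
    weights = rng.lognormal(mean=0.0, sigma=cfg.expression_sigma, size=len(genes))
    weights = weights / weights.sum()

    barcodes = sorted(
        {_decode(_random_seq(rng, 16)) for _ in range(cfg.n_cells * 3)}
    )[: cfg.n_cells]
    if len(barcodes) < cfg.n_cells:
        raise RuntimeError("barcode collision storm; raise n_cells head-room")

    p_nb = cfg.umis_per_cell_dispersion / (
        cfg.umis_per_cell_dispersion + cfg.umis_per_cell_mean
    )
    mol_rows = []
    for barcode in barcodes:
        n_umis = int(rng.negative_binomial(cfg.umis_per_cell_dispersion, p_nb))
        n_umis = max(n_umis, 1)
        umi_codes = rng.choice(4**10, size=n_umis, replace=False)
        for code in umi_codes:
            umi = _encode_umi(int(code))
            u = rng.random()
            if u < cfg.strand_invader_fraction and invader_sites:
                chrom, pos, strand = invader_sites[int(rng.integers(len(invader_sites)))]
                origin, gene_id = STRAND_INVADER, "."
                g_prob = cfg.unencoded_g_prob_artifact
            else:
                gi = int(rng.choice(len(genes), p=weights))
                gene = genes[gi]
                gene_id = gene.gene_id
                chrom, strand = gene.chrom, gene.strand
                if rng.random() < cfg.exon_painting_rate:
                    origin = EXON_PAINTING
                    exon_bases = np.concatenate(
                        [np.arange(s, e) for s, e in gene.exons]
                    )
                    pos = int(exon_bases[int(rng.integers(len(exon_bases)))])
                    g_prob = cfg.unencoded_g_prob_artifact
                else:
                    origin = PROMOTER
                    offset = int(np.clip(np.rint(rng.normal(0.0, cfg.promoter_sd)), -60, 60))
                    pos = gene.tss + offset
                    g_prob = cfg.unencoded_g_prob_genuine
            unenc_g = bool(rng.random() < g_prob)
            n_reads = 2 if rng.random() < cfg.duplicate_rate else 1
            mol_rows.append(
                (chrom, pos, strand, barcode, umi, origin, int(unenc_g), gene_id, n_reads)
            )

    molecules = pd.DataFrame(
        mol_rows,
        columns=[
            "chrom", "pos", "strand", "barcode", "umi",
            "origin", "unencoded_g", "gene_id", "n_reads",
        ],
    )
    promoters = pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand, 1) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand", "atac_high"],
    )

    paths = _write_bundle(cfg, out_dir, contigs, genes, molecules, promoters)
    return Bundle(
        out_dir=out_dir,
        molecules=molecules,
        promoters=promoters,
        barcodes=barcodes,
        config=cfg,
        **paths,
    )


def _write_bundle(
    cfg: SimulationConfig,
    out_dir: str,
    contigs: Dict[str, np.ndarray],
    genes: List[SimGene],
    molecules: pd.DataFrame,
    promoters: pd.DataFrame,
) -> Dict[str, str]:
    genome_fasta = os.path.join(out_dir, "genome.fa")
    with open(genome_fasta, "w") as out:
        for chrom in sorted(contigs):
            out.write(f">{chrom}\n")
            s = _decode(contigs[chrom])
            for i in range(0, len(s), 80):
                out.write(s[i : i + 80] + "\n")
    for ext in (".fai",):  # stale index would shadow a regenerated genome
        if os.path.exists(genome_fasta + ext):
            os.remove(genome_fasta + ext)

    gtf = os.path.join(out_dir, "genes.gtf")
    with open(gtf, "w") as out:
        for g in genes:
            gstart = min(s for s, _ in g.exons) + 1  # GTF is 1-based inclusive
            gend = max(e for _, e in g.exons)
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_name "{g.gene_id}";'
            out.write(
                f"{g.chrom}\tsim\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            out.write(
                f"{g.chrom}\tsim\ttranscript\t{gstart}\t{gend}\t.\t{g.strand}\t.\t{tattrs}\n"
            )
            for s, e in g.exons:
                out.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                )

    atac = os.path.join(out_dir, "atac.bedgraph")
    ivs = sorted(
        (g.chrom, g.tss - cfg.atac_half_width, g.tss + cfg.atac_half_width + 1)
        for g in genes
    )
    with open(atac, "w") as out:
        for chrom, s, e in ivs:
            out.write(f"{chrom}\t{s}\t{e}\t{cfg.atac_value:g}\n")

    sam = os.path.join(out_dir, "alignments.sam")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": len(contigs[chrom])} for chrom in sorted(contigs)
        ],
    }
    rl = cfg.read_length
    records = []
    for row in molecules.itertuples(index=False):
        seq_arr = contigs[row.chrom]
        if row.strand == PLUS:
            ref = _decode(seq_arr[row.pos : row.pos + rl])
            seq = ("G" + ref) if row.unencoded_g else ref
            cigar = f"1S{rl}M" if row.unencoded_g else f"{rl}M"
            left, flag = row.pos, 0
        else:
            ref = _decode(seq_arr[row.pos - rl + 1 : row.pos + 1])
            seq = (ref + "C") if row.unencoded_g else ref
            cigar = f"{rl}M1S" if row.unencoded_g else f"{rl}M"
            left, flag = row.pos - rl + 1, 16
        for ri in range(row.n_reads):
            qname = f"m:{row.barcode}:{row.umi}:{ri}"
            records.append((row.chrom, left, qname, flag, cigar, seq, row.barcode, row.umi))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with pysam.AlignmentFile(sam, "w", header=header) as out:
        tid = {chrom: i for i, chrom in enumerate(sorted(contigs))}
        for chrom, left, qname, flag, cigar, seq, barcode, umi in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = tid[chrom]
            a.reference_start = left
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq
            a.set_tag("CB", barcode)
            a.set_tag("UB", umi)
            out.write(a)

    truth_mol = os.path.join(out_dir, "truth_molecules.tsv")
    molecules.to_csv(truth_mol, sep="\t", index=False)
    truth_prom = os.path.join(out_dir, "truth_promoters.tsv")
    promoters.to_csv(truth_prom, sep="\t", index=False)
    return {
        "genome_fasta": genome_fasta,
        "gtf": gtf,
        "alignments": sam,
        "atac_bedgraph": atac,
        "truth_molecules_tsv": truth_mol,
        "truth_promoters_tsv": truth_prom,
    }
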