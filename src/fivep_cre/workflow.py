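"""Pre-configured end-to-end workflow chaining the seven pipeline stages.

Stage order: bam-to-ctss -> remove-strand-invader -> cluster -> filter ->
annotate -> count -> directionality. Multiple libraries are processed
through CTSS extraction and invader filtering independently, then pooled
before clustering so all libraries share one cluster/tCRE universe; when
more than one library is pooled, cell barcodes are suffixed "-<k>" with the
1-based library index. Every run writes a manifest (parameters, input
checksums, per-stage tallies, output checksums); a fixed configuration
yields a byte-identical manifest apart from nothing — reruns are
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .annotate import (
    DISTAL,
    annotate_tcres,
    flag_hyperactive,
    stitch_distal,
    write_directionality,
    write_loci_bed,
    write_tcre_bed,
)
from .classify import (
    LogisticModel,
    benchmark_predictors,
    classify_clusters,
    compute_features,
    label_by_atac,
)
from .cluster import cluster_ctss, write_cluster_table, write_clusters_bed
from .count import count_matrix, write_matrix_dir
from .ctss import (
    CtssIndex,
    CtssRecord,
    aggregate_ctss,
    write_ctss_bed,
    write_ctss_cells,
)
from .invader import StrandInvaderParams, filter_ctss
from .io import Genome, SignalTrack, read_alignments, read_gene_annotation

logger = logging.getLogger("fivep_cre")


class WorkflowError(RuntimeError):
    """A stage failed; the failing stage is named in the message."""


@dataclass
class RunConfig:
    """All inputs and per-stage parameters of one workflow run."""

    bams: List[str]
    genome: str
    gtf: str
    out_dir: str
    atac: Optional[str] = None  # training signal (bedGraph or peak BED)
    model: Optional[str] = None  # pre-trained model instead of training
    whitelist: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"
    # bam_to_ctss
    min_mapq: int = 10
    max_g: int = 3
    cb_tag: str = "CB"
    umi_tag: str = "UB"
    # remove_strand_invader
    tso_suffix: str = "TATAGGG"
    max_edit_distance: int = 2
    # cluster
    stability_min: float = 2.0
    min_cluster_umi: int = 5
    max_cluster_length: int = 500
    min_density_floor: float = 0.0
    # filter
    cutoff: float = 0.5
    background_half_width: int = 2000
    pos_quantile: float = 0.75
    neg_value: float = 0.0
    min_per_class: int = 50
    allow_l2: bool = True
    # annotate
    merge_distance: int = 500
    proximal_distance: int = 500
    stitch_distance: int = 12500

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("bams"), str):
            raw["bams"] = [raw["bams"]]
        return cls(**raw)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass
class WorkflowResult:
    """In-memory view of a finished run, alongside the files on disk."""

    config: RunConfig
    manifest: Dict
    pooled_ctss: List[CtssRecord]
    clusters: List  # post-filter candidates entering classification
    features: List
    probabilities: np.ndarray
    keep_mask: np.ndarray
    kept_clusters: List
    tcres: List
    loci: List
    matrix: object
    model: LogisticModel


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_workflow(config: RunConfig) -> WorkflowResult:
    """Execute the full pipeline; raises :class:`WorkflowError` naming the
    failing stage and leaves a FAILED_<stage> marker next to partial outputs."""
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: Dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }
    for path in [*config.bams, config.genome, config.gtf, config.atac, config.model]:
        if path:
            manifest["inputs"][os.path.basename(path)] = _md5(path)

    stage = "init"
    try:
        genome = Genome(config.genome)
        gene_models = read_gene_annotation(config.gtf)

        # ---- bam_to_ctss + remove_strand_invader, per library, then pool
        stage = "bam_to_ctss"
        per_lib_ctss: List[List[CtssRecord]] = []
        lib_tallies = []
        for lib_i, bam in enumerate(config.bams):
            tally: Dict[str, int] = {}
            reads = read_alignments(
                bam, config.min_mapq, config.cb_tag, config.umi_tag, tally
            )
            records = aggregate_ctss(reads, genome, config.max_g)
            per_lib_ctss.append(records)
            tally["molecules"] = sum(r.total_umi for r in records)
            lib_tallies.append({"library": os.path.basename(bam), **tally})
            logger.info("library %s: %s", bam, tally)
        manifest["stages"]["bam_to_ctss"] = lib_tallies

        stage = "remove_strand_invader"
        params = StrandInvaderParams(config.tso_suffix, config.max_edit_distance)
        pooled: Dict = {}
        invader_tallies = []
        multi = len(per_lib_ctss) > 1
        for lib_i, records in enumerate(per_lib_ctss):
            tally: Dict[str, float] = {}
            retained, frac = filter_ctss(records, genome, params, tally)
            invader_tallies.append(
                {"library": os.path.basename(config.bams[lib_i]), **tally}
            )
            for rec in retained:
                key = (rec.chrom, rec.pos, rec.strand)
                dst = pooled.setdefault(key, CtssRecord(*key))
                for bc, (u, g) in rec.cells.items():
                    name = f"{bc}-{lib_i + 1}" if multi else bc
                    pu, pg = dst.cells.get(name, (0, 0))
                    dst.cells[name] = (pu + u, pg + g)
        pooled_ctss = [pooled[k] for k in sorted(pooled)]
        manifest["stages"]["remove_strand_invader"] = invader_tallies
        write_ctss_bed(pooled_ctss, os.path.join(config.out_dir, "ctss.bed"))
        write_ctss_cells(pooled_ctss, os.path.join(config.out_dir, "ctss_cells.tsv"))

        # ---- cluster
        stage = "cluster"
        clusters = cluster_ctss(
            pooled_ctss,
            config.stability_min,
            config.min_cluster_umi,
            config.max_cluster_length,
            config.min_density_floor,
        )
        write_clusters_bed(clusters, os.path.join(config.out_dir, "clusters.bed"))
        write_cluster_table(clusters, os.path.join(config.out_dir, "clusters.tsv"))
        manifest["stages"]["cluster"] = {
            "n_clusters": len(clusters),
            "cluster_umi": int(sum(c.total_umi for c in clusters)),
        }

        # ---- filter (train or load model, classify, cut)
        stage = "filter"
        index = CtssIndex(pooled_ctss)
        filter_info: Dict = {}
        if config.model:
            model = LogisticModel.load(config.model)
            filter_info["model"] = "pre-trained"
        else:
            if not config.atac:
                raise ValueError("either a pre-trained model or a training signal "
                                 "(atac) is required")
            atac = SignalTrack.load(config.atac)
            labels = label_by_atac(
                clusters, atac, config.pos_quantile, config.neg_value,
                config.min_per_class,
            )
            training = [
                (compute_features(c, index, config.background_half_width),
                 1 if l.label == "positive" else 0)
                for c, l in zip(clusters, labels)
                if l.label != "excluded"
            ]
            feats = [f for f, _ in training]
            ys = [y for _, y in training]
            aucs, model = benchmark_predictors(feats, ys, config.min_per_class)
            filter_info["model"] = "trained"
            filter_info["auc"] = {k: round(v, 6) for k, v in aucs.items()}
            filter_info["n_pos"] = int(sum(ys))
            filter_info["n_neg"] = int(len(ys) - sum(ys))
            model.metadata["training_data"] = os.path.basename(config.atac)
            model.save(os.path.join(config.out_dir, "model.txt"))
        features, probs, keep = classify_clusters(
            clusters, index, model, config.cutoff, config.background_half_width
        )
        kept_clusters = [c for c, k in zip(clusters, keep) if k]
        filter_info.update(
            n_input=len(clusters), n_kept=len(kept_clusters),
            kept_umi=int(sum(c.total_umi for c in kept_clusters)),
        )
        manifest["stages"]["filter"] = filter_info
        with open(os.path.join(config.out_dir, "cluster_features.tsv"), "w") as out:
            out.write(
                "name\tcluster_count\tsummit_count\tflanking_count\t"
                "unencoded_g_pct\tcorrected_expression\tprobability\tkept\n"
            )
            for c, f, p, k in zip(clusters, features, probs, keep):
                out.write(
                    f"{c.name}\t{f.cluster_count}\t{f.summit_count}\t"
                    f"{f.flanking_count}\t{f.unencoded_g_pct:.6f}\t"
                    f"{f.corrected_expression:.4f}\t{p:.6g}\t{int(k)}\n"
                )
        write_clusters_bed(
            kept_clusters, os.path.join(config.out_dir, "clusters_filtered.bed")
        )

        # ---- annotate
        stage = "annotate"
        tcres = annotate_tcres(
            kept_clusters, gene_models, config.merge_distance,
            config.proximal_distance, warn=logger.warning,
        )
        distal = [t for t in tcres if t.cre_class == DISTAL]
        loci = stitch_distal(distal, config.stitch_distance)
        cutoff_val = flag_hyperactive(loci, warn=logger.warning)
        write_tcre_bed(tcres, os.path.join(config.out_dir, "tcre.bed"))
        write_loci_bed(loci, os.path.join(config.out_dir, "stitched_loci.bed"))
        manifest["stages"]["annotate"] = {
            "n_tcres": len(tcres),
            "n_proximal": sum(1 for t in tcres if t.cre_class != DISTAL),
            "n_distal": len(distal),
            "n_loci": len(loci),
            "n_hyperactive": sum(1 for l in loci if l.hyperactive),
            "elbow_cutoff": cutoff_val,
        }

        # ---- count
        stage = "count"
        whitelist = None
        if config.whitelist:
            with open(config.whitelist) as fh:
                whitelist = [line.strip() for line in fh if line.strip()]
        matrix = count_matrix(pooled_ctss, tcres, whitelist)
        write_matrix_dir(matrix, os.path.join(config.out_dir, "matrix"))
        manifest["stages"]["count"] = {
            "n_features": len(matrix.feature_ids),
            "n_cells": len(matrix.barcodes),
            "total_umi": matrix.total,
        }

        # ---- directionality
        stage = "directionality"
        write_directionality(
            tcres, index, os.path.join(config.out_dir, "directionality.tsv")
        )
        manifest["stages"]["directionality"] = {"n_tcres": len(tcres)}
    except Exception as exc:
        marker = os.path.join(config.out_dir, f"FAILED_{stage}")
        with open(marker, "w") as out:
            out.write(f"{type(exc).__name__}: {exc}\n")
        _write_manifest(manifest, config.out_dir, failed_stage=stage)
        raise WorkflowError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {
        name: _md5(os.path.join(config.out_dir, name))
        for name in sorted(os.listdir(config.out_dir))
        if os.path.isfile(os.path.join(config.out_dir, name))
        and name != "manifest.json"
    }
    for name in sorted(os.listdir(os.path.join(config.out_dir, "matrix"))):
        manifest["outputs"][f"matrix/{name}"] = _md5(
            os.path.join(config.out_dir, "matrix", name)
        )
    _write_manifest(manifest, config.out_dir)
    return WorkflowResult(
        config=config,
        manifest=manifest,
        pooled_ctss=pooled_ctss,
        clusters=clusters,
        features=features,
        probabilities=probs,
        keep_mask=keep,
        kept_clusters=kept_clusters,
        tcres=tcres,
        loci=loci,
        matrix=matrix,
        model=model,
    )


def _write_manifest(manifest: Dict, out_dir: str, failed_stage: Optional[str] = None) -> None:
    if failed_stage:
        manifest = {**manifest, "failed_stage": failed_stage}
    with open(os.path.join(out_dir, "manifest.json"), "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
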