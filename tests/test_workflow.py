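import hashlib
import json
import os
from pathlib import Path

import pytest
from click.testing import CliRunner

from fivep_cre import RunConfig, run_workflow
from fivep_cre.cli import main as cli_main
from fivep_cre.workflow import WorkflowError


def md5(path):
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


STAGE_FILES = [
    "ctss.bed", "ctss_cells.tsv", "clusters.bed", "clusters.tsv", "model.txt",
    "cluster_features.tsv", "clusters_filtered.bed", "tcre.bed",
    "stitched_loci.bed", "directionality.tsv", "manifest.json",
    "matrix/matrix.mtx", "matrix/features.tsv", "matrix/barcodes.tsv",
]


class TestEndToEnd:
    def test_all_stage_outputs_and_manifest_present(self, workflow_result):
        out = workflow_result.config.out_dir
        for name in STAGE_FILES:
            assert os.path.exists(os.path.join(out, name)), name
        stages = workflow_result.manifest["stages"]
        assert list(stages) == [
            "bam_to_ctss", "remove_strand_invader", "cluster", "filter",
            "annotate", "count", "directionality",
        ]
        assert workflow_result.manifest["inputs"]

    def test_rerun_reproduces_output_checksums(self, bundle, workflow_result, tmp_path):
        cfg = RunConfig(
            bams=[bundle.alignments], genome=bundle.genome_fasta, gtf=bundle.gtf,
            atac=bundle.atac_bedgraph, out_dir=str(tmp_path / "rerun"),
            min_per_class=20,
        )
        rerun = run_workflow(cfg)
        assert rerun.manifest["outputs"] == workflow_result.manifest["outputs"]

    def test_umi_conservation_across_stage_boundaries(self, workflow_result):
        st = workflow_result.manifest["stages"]
        lib = st["bam_to_ctss"][0]
        inv = st["remove_strand_invader"][0]
        assert inv["input_umi"] == lib["molecules"]
        retained_umi = sum(r.total_umi for r in workflow_result.pooled_ctss)
        assert retained_umi + inv["removed_umi"] == inv["input_umi"]
        kept_umi = sum(c.total_umi for c in workflow_result.kept_clusters)
        assert st["filter"]["kept_umi"] == kept_umi
        assert sum(t.total_umi for t in workflow_result.tcres) == kept_umi


class TestAggregation:
    def test_two_libraries_pool_after_invader_filtering(self, bundle, tmp_path):
        cfg = RunConfig(
            bams=[bundle.alignments, bundle.alignments],
            genome=bundle.genome_fasta, gtf=bundle.gtf,
            atac=bundle.atac_bedgraph, out_dir=str(tmp_path / "agg"),
            min_per_class=20,
        )
        res = run_workflow(cfg)
        inv = res.manifest["stages"]["remove_strand_invader"]
        assert len(inv) == 2
        per_lib_retained = [t["input_umi"] - t["removed_umi"] for t in inv]
        pooled = sum(r.total_umi for r in res.pooled_ctss)
        assert pooled == sum(per_lib_retained)
        # cells are suffixed with the library index, so both libraries survive
        suffixes = {bc.rsplit("-", 1)[1] for bc in res.matrix.barcodes}
        assert suffixes == {"1", "2"}


class TestPretrainedModel:
    def test_shipped_synthetic_model_runs_without_training_signal(
        self, bundle, tmp_path
    ):
        import importlib.resources as ir

        from fivep_cre.evaluate import promoter_recovery

        model_path = str(ir.files("fivep_cre") / "data" / "pretrained_synthetic.model.txt")
        cfg = RunConfig(
            bams=[bundle.alignments], genome=bundle.genome_fasta, gtf=bundle.gtf,
            model=model_path, out_dir=str(tmp_path / "pre"),
        )
        res = run_workflow(cfg)
        assert res.manifest["stages"]["filter"]["model"] == "pre-trained"
        assert promoter_recovery(res.kept_clusters, bundle.promoters) >= 0.9


class TestFailure:
    def test_failing_stage_is_named_and_marked(self, bundle, tmp_path):
        cfg = RunConfig(
            bams=[bundle.alignments], genome=bundle.genome_fasta, gtf=bundle.gtf,
            atac=None, model=None, out_dir=str(tmp_path / "fail"),
        )
        with pytest.raises(WorkflowError, match="filter"):
            run_workflow(cfg)
        assert (tmp_path / "fail" / "FAILED_filter").exists()

    def test_unknown_config_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("bams: [x.bam]\ngenome: g.fa\ngtf: a.gtf\n"
                        "out_dir: o\nbogus_knob: 7\n")
        with pytest.raises(ValueError, match="bogus_knob"):
            RunConfig.from_yaml(str(path))


class TestWorkflowMatchesManualStages:
    def test_stagewise_cli_outputs_match_workflow(self, bundle, workflow_result, tmp_path):
        """Running the tools one by one reproduces the workflow's files."""
        out = workflow_result.config.out_dir
        runner = CliRunner()
        d = tmp_path / "manual"
        d.mkdir()

        r = runner.invoke(cli_main, [
            "bam-to-ctss", "--bam", bundle.alignments, "--genome",
            bundle.genome_fasta, "--out-prefix", str(d / "s1")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "remove-strand-invader", "--ctss", str(d / "s1.ctss_cells.tsv"),
            "--genome", bundle.genome_fasta, "--out-prefix", str(d / "s2")])
        assert r.exit_code == 0, r.output
        assert md5(d / "s2.ctss.bed") == md5(Path(out) / "ctss.bed")
        assert md5(d / "s2.ctss_cells.tsv") == md5(Path(out) / "ctss_cells.tsv")

        r = runner.invoke(cli_main, [
            "cluster", "--ctss", str(d / "s2.ctss_cells.tsv"),
            "--out-prefix", str(d / "s3")])
        assert r.exit_code == 0, r.output
        assert md5(d / "s3.clusters.bed") == md5(Path(out) / "clusters.bed")

        r = runner.invoke(cli_main, [
            "filter", "--ctss", str(d / "s2.ctss_cells.tsv"),
            "--clusters", str(d / "s3.clusters.tsv"),
            "--model", str(Path(out) / "model.txt"),
            "--out-prefix", str(d / "s4")])
        assert r.exit_code == 0, r.output
        assert md5(d / "s4.clusters_filtered.bed") == md5(
            Path(out) / "clusters_filtered.bed")

        r = runner.invoke(cli_main, [
            "annotate", "--ctss", str(d / "s2.ctss_cells.tsv"),
            "--clusters", str(d / "s4.clusters_filtered.bed"),
            "--gtf", bundle.gtf, "--out-prefix", str(d / "s5")])
        assert r.exit_code == 0, r.output
        assert md5(d / "s5.tcre.bed") == md5(Path(out) / "tcre.bed")
        assert md5(d / "s5.directionality.tsv") == md5(
            Path(out) / "directionality.tsv")

        r = runner.invoke(cli_main, [
            "count", "--ctss", str(d / "s2.ctss_cells.tsv"),
            "--tcre", str(d / "s5.tcre.bed"), "--out-dir", str(d / "mtx")])
        assert r.exit_code == 0, r.output
        for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
            assert md5(d / "mtx" / name) == md5(Path(out) / "matrix" / name)
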