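import sys
from pathlib import Path

import pysam
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from fivep_cre import (
    Genome,
    RunConfig,
    SimulationConfig,
    run_workflow,
    simulate_bundle,
)

BUNDLE_SEED = 0  # the generator's default study conditions


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle shared across the suite."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(SimulationConfig(seed=BUNDLE_SEED), str(out))


@pytest.fixture(scope="session")
def workflow_result(bundle, tmp_path_factory):
    """Full pipeline run on the default bundle.

    min_per_class is set to 20: one 40-gene bundle yields a fluctuating
    number of accessibility-positive clusters, at times below the default
    training minimum of 50.
    """
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        bams=[bundle.alignments],
        genome=bundle.genome_fasta,
        gtf=bundle.gtf,
        atac=bundle.atac_bedgraph,
        out_dir=str(out),
        min_per_class=20,
    )
    return run_workflow(cfg)


@pytest.fixture()
def make_genome(tmp_path):
    """Write contig sequences to FASTA and open them as a Genome."""

    def _make(contigs, name="genome.fa"):
        path = tmp_path / name
        with open(path, "w") as out:
            for chrom, seq in contigs.items():
                out.write(f">{chrom}\n{seq}\n")
        return Genome(str(path))

    return _make


@pytest.fixture()
def write_sam(tmp_path):
    """Write alignment rows to a plain-text SAM file.

    Rows are (qname, flag, chrom, pos0, mapq, cigar, seq, tags-dict).
    """

    def _write(contig_lengths, rows, name="reads.sam"):
        path = tmp_path / name
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in contig_lengths.items()],
        }
        tid = {c: i for i, c in enumerate(contig_lengths)}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for qname, flag, chrom, pos, mapq, cigar, seq, tags in rows:
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.flag = flag
                a.reference_id = tid[chrom]
                a.reference_start = pos
                a.mapping_quality = mapq
                a.cigarstring = cigar
                a.query_sequence = seq
                for key, val in tags.items():
                    a.set_tag(key, val)
                out.write(a)
        return str(path)

    return _write
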