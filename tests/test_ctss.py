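import numpy as np
import pytest

from fivep_cre import aggregate_ctss, detect_unencoded_g, five_prime_site, revcomp
from fivep_cre.ctss import InvalidAlignmentError
from fivep_cre.io import AlignmentRead


def read(pos, cigar, seq, strand="+", chrom="chr1", barcode="BC1", umi="U1"):
    return AlignmentRead(
        chrom=chrom, pos=pos, cigar=cigar, strand=strand, seq=seq,
        mapq=60, barcode=barcode, umi=umi,
    )


class TestFivePrimeSite:
    def test_plus_strand_is_leftmost_aligned_base(self):
        r = read(1000, [("M", 50)], "A" * 50)
        assert five_prime_site(r) == ("chr1", 1000, "+")

    def test_minus_strand_is_rightmost_aligned_base(self):
        r = read(1000, [("M", 50)], "A" * 50, strand="-")
        assert five_prime_site(r) == ("chr1", 1049, "-")

    def test_soft_clips_consume_no_reference(self):
        r = read(1000, [("S", 2), ("M", 48)], "G" * 50)
        assert five_prime_site(r) == ("chr1", 1000, "+")

    def test_reference_free_alignment_rejected(self):
        r = read(1000, [("S", 10)], "A" * 10)
        with pytest.raises(InvalidAlignmentError):
            five_prime_site(r)


class TestUnencodedG:
    # 60-bp reference beginning with a known context at position 10
    REF = "TTTTTTTTTT" + "ACGTACGTAC" + "A" * 40

    @pytest.fixture()
    def genome(self, make_genome):
        return make_genome({"chr1": self.REF})

    def test_soft_clipped_g_counts_one(self, genome):
        # 1 soft-clipped G, first aligned base matches the reference (A at 10)
        r = read(10, [("S", 1), ("M", 20)], "G" + self.REF[10:30])
        assert detect_unencoded_g(r, genome) == 1

    def test_aligned_g_mismatch_counts_one(self, genome):
        # no soft clip; read starts with G over reference A at position 10
        r = read(10, [("M", 20)], "G" + self.REF[11:30])
        assert detect_unencoded_g(r, genome) == 1

    def test_matching_non_g_start_counts_zero(self, genome):
        r = read(10, [("M", 20)], self.REF[10:30])
        assert detect_unencoded_g(r, genome) == 0

    def test_templated_g_stops_the_scan(self, genome):
        # soft-clipped GG then aligned G over reference G (position 12 is G)
        r = read(12, [("S", 2), ("M", 20)], "GG" + self.REF[12:32])
        assert detect_unencoded_g(r, genome) == 2

    def test_scan_capped_at_max_g(self, genome):
        r = read(10, [("S", 5), ("M", 20)], "GGGGG" + self.REF[10:30])
        assert detect_unencoded_g(r, genome, max_g=3) == 3

    def test_minus_strand_mirror_of_soft_clip(self, genome):
        # - strand read whose 5' end is at position 29; SAM stores the
        # reverse complement, so the unencoded G appears as a trailing C
        aligned = self.REF[10:30]
        r = read(10, [("M", 20), ("S", 1)], aligned + "C", strand="-")
        assert detect_unencoded_g(r, genome) == 1

    def test_contig_edge_soft_clip_reads_as_non_g(self, make_genome):
        genome = make_genome({"c": "AAAA"})
        r = read(0, [("S", 1), ("M", 3)], "GAAA", chrom="c")
        # soft-clipped G before the contig start still counts (clip rule
        # depends only on the read base)
        assert detect_unencoded_g(r, genome) == 1


class TestAggregate:
    @pytest.fixture()
    def genome(self, make_genome):
        return make_genome({"chr1": "A" * 200})

    def test_same_molecule_reads_collapse(self, genome):
        reads = [read(100, [("M", 50)], "A" * 50) for _ in range(3)]
        (rec,) = aggregate_ctss(reads, genome)
        assert rec.total_umi == 1

    def test_distinct_umis_count_separately(self, genome):
        reads = [
            read(100, [("M", 50)], "A" * 50, umi="U1"),
            read(100, [("M", 50)], "A" * 50, umi="U2"),
        ]
        (rec,) = aggregate_ctss(reads, genome)
        assert rec.total_umi == 2

    def test_majority_vote_tie_flags_unencoded_g(self, genome):
        reads = [
            read(100, [("S", 1), ("M", 49)], "G" + "A" * 49),  # flagged
            read(100, [("M", 50)], "A" * 50),  # not flagged
        ]
        (rec,) = aggregate_ctss(reads, genome)
        assert rec.total_umi == 1
        assert rec.total_unencoded_g_umi == 1  # 1-1 tie -> True

    def test_planted_unencoded_fraction_recovered(self, genome):
        reads = []
        for i in range(10):
            flagged = i < 4
            cigar = [("S", 1), ("M", 49)] if flagged else [("M", 50)]
            seq = ("G" if flagged else "A") + "A" * 49
            reads.append(read(100, cigar, seq, umi=f"U{i}"))
        (rec,) = aggregate_ctss(reads, genome)
        assert rec.total_unencoded_g_umi / rec.total_umi == pytest.approx(0.40)

    def test_total_equals_distinct_molecule_tuples(self, genome):
        rng = np.random.default_rng(5)
        reads = []
        for _ in range(300):
            pos = int(rng.integers(50, 150))
            bc = f"BC{rng.integers(3)}"
            umi = f"U{rng.integers(40)}"
            reads.append(read(pos, [("M", 50)], "A" * 50, barcode=bc, umi=umi))
        records = aggregate_ctss(reads, genome)
        truth = {(r.pos, r.barcode, r.umi, r.strand) for r in reads}
        assert sum(r.total_umi for r in records) == len(truth)
        for rec in records:
            assert 0.0 <= rec.unencoded_g_fraction <= 1.0


def test_strand_mirror_invariance(make_genome):
    """Reverse-complementing the genome and flipping all reads leaves the
    multiset of per-site (UMI, unencoded-G) tallies unchanged."""
    rng = np.random.default_rng(17)
    L = 300
    seq = "".join(rng.choice(list("ACGT"), size=L))
    fwd = make_genome({"chr1": seq}, name="fwd.fa")
    rev = make_genome({"chr1": revcomp(seq)}, name="rev.fa")

    fwd_reads, rev_reads = [], []
    for i in range(60):
        pos = int(rng.integers(60, 200))
        flagged = rng.random() < 0.5
        aligned = seq[pos : pos + 40]
        umi = f"U{i}"
        if flagged:
            fwd_reads.append(read(pos, [("S", 1), ("M", 40)], "G" + aligned, umi=umi))
        else:
            fwd_reads.append(read(pos, [("M", 40)], aligned, umi=umi))
        # mirrored read: - strand at the mirrored coordinate
        mpos = L - 1 - pos - 39  # leftmost base of the mirrored alignment
        maligned = revcomp(seq)[mpos : mpos + 40]
        if flagged:
            rev_reads.append(
                read(mpos, [("M", 40), ("S", 1)], maligned + "C", strand="-", umi=umi)
            )
        else:
            rev_reads.append(read(mpos, [("M", 40)], maligned, strand="-", umi=umi))

    tally_f = sorted(
        (r.total_umi, r.total_unencoded_g_umi) for r in aggregate_ctss(fwd_reads, fwd)
    )
    tally_r = sorted(
        (r.total_umi, r.total_unencoded_g_umi) for r in aggregate_ctss(rev_reads, rev)
    )
    assert tally_f == tally_r
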