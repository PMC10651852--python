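"""Unit tests for PASS-read extraction, clustering, filtering and
terminal-exon extension."""

from __future__ import annotations

from polyagrammar import sites3p
from polyagrammar.genome import Annotation, Exon, Gene, SequenceStore, Transcript
from polyagrammar.sites3p import PassRead


class FakeAlignment:
    """Duck-typed stand-in for a pysam AlignedSegment."""

    def __init__(self, *, reference_name="chr1", reference_start=10,
                 reference_end=30, cigartuples=((0, 20), (4, 5)),
                 query_sequence="C" * 20 + "AAAAA", is_reverse=False,
                 mapping_quality=60, is_unmapped=False, is_secondary=False,
                 is_supplementary=False, tags=None, query_name="read"):
        self.reference_name = reference_name
        self.reference_start = reference_start
        self.reference_end = reference_end
        self.cigartuples = list(cigartuples)
        self.query_sequence = query_sequence
        self.is_reverse = is_reverse
        self.mapping_quality = mapping_quality
        self.is_unmapped = is_unmapped
        self.is_secondary = is_secondary
        self.is_supplementary = is_supplementary
        self._tags = tags or {}
        self.query_name = query_name

    def has_tag(self, tag):
        return tag in self._tags

    def get_tag(self, tag):
        return self._tags[tag]


def _genome(seq):
    return SequenceStore({"chr1": seq})


def test_extract_pass_plus_strand_nongenomic_tail():
    # alignment ends on a non-A base, next reference base is not A:
    # cleavage at the last aligned base, full tail is untemplated
    seq = "C" * 29 + "G" + "C" * 70
    reads = sites3p.extract_pass_reads([FakeAlignment()], _genome(seq))
    assert len(reads) == 1
    assert reads[0].cleavage_pos == 29
    assert reads[0].strand == "+"
    assert reads[0].n_nongenomic_a == 5


def test_extract_pass_plus_strand_genomic_a_subtraction():
    # reference carries AAA right after the alignment end: 3 of the 5 tail
    # As are genomic, and the cleavage moves to the first A of the run
    seq = "C" * 29 + "G" + "AAA" + "C" * 67
    reads = sites3p.extract_pass_reads([FakeAlignment()], _genome(seq))
    assert len(reads) == 1
    assert reads[0].n_nongenomic_a == 2
    assert reads[0].cleavage_pos == 30


def test_extract_pass_plus_strand_first_a_of_run():
    # last aligned bases are reference As: walk 5' to the first A of the run
    seq = "C" * 26 + "G" + "AAA" + "C" * 70  # As at 27..29
    reads = sites3p.extract_pass_reads([FakeAlignment()], _genome(seq))
    assert len(reads) == 1
    assert reads[0].cleavage_pos == 27
    assert reads[0].n_nongenomic_a == 5


def test_extract_pass_minus_strand():
    # minus-strand read: leading soft clip of Ts, cleavage at reference_start
    aln = FakeAlignment(reference_start=40, reference_end=60,
                        cigartuples=((4, 4), (0, 20)),
                        query_sequence="TTTT" + "C" * 20, is_reverse=True,
                        tags={"RG": "s1"})
    seq = "C" * 39 + "G" * 2 + "C" * 59
    reads = sites3p.extract_pass_reads([aln], _genome(seq),
                                       sample_map={"s1": "lineageA"})
    assert len(reads) == 1
    assert reads[0].strand == "-"
    assert reads[0].cleavage_pos == 40
    assert reads[0].n_nongenomic_a == 4
    assert reads[0].sample_id == "s1"
    assert reads[0].lineage == "lineageA"


def test_extract_pass_rejections():
    seq = "C" * 29 + "G" + "C" * 70
    genome = _genome(seq)
    low_mapq = FakeAlignment(mapping_quality=5)
    secondary = FakeAlignment(is_secondary=True)
    # only one untemplated A (below the >=2 threshold)
    short_tail = FakeAlignment(cigartuples=((0, 20), (4, 1)),
                               query_sequence="C" * 20 + "A")
    no_clip = FakeAlignment(cigartuples=((0, 25),), query_sequence="C" * 25)
    kept = sites3p.extract_pass_reads(
        [low_mapq, secondary, short_tail, no_clip, FakeAlignment()], genome)
    assert len(kept) == 1


def test_read_pass_tsv(tmp_path):
    path = tmp_path / "reads.tsv"
    path.write_text("chrom\tpos\tstrand\tn_nongenomic_a\tsample_id\n"
                    "chr1\t100\t+\t5\ts1\n"
                    "chr1\t101\t+\t1\ts1\n"      # filtered: < 2 tail As
                    "chr2\t50\t-\t3\ts2\n")
    reads = sites3p.read_pass_tsv(path, sample_map={"s1": "brain"})
    assert len(reads) == 2
    assert reads[0] == PassRead("chr1", 100, "+", 5, "s1", "brain")
    assert reads[1].lineage == "s2"  # unmapped samples keep their own label


def test_cluster_sites_greedy_and_conservation():
    reads = ([PassRead("chr1", 100, "+", 3)] * 3
             + [PassRead("chr1", 110, "+", 3)] * 3
             + [PassRead("chr1", 105, "+", 3)])
    sites = sites3p.cluster_sites(reads)
    assert len(sites) == 1
    # count tie between 100 and 110 breaks to the 5'-most on the plus strand
    assert sites[0].pos == 100
    assert sites[0].read_count_total == len(reads)
    assert sites[0].read_positions == {100: 3, 105: 1, 110: 3}

    minus = [PassRead("chr1", p, "-", 3) for p in (100, 100, 110, 110)]
    msites = sites3p.cluster_sites(minus)
    assert len(msites) == 1
    # on the minus strand the 5'-most position is the larger coordinate
    assert msites[0].pos == 110


def test_cluster_sites_window_boundary():
    # 24 nt apart merges; 25 nt apart does not
    near = [PassRead("chr1", 100, "+", 3), PassRead("chr1", 124, "+", 3),
            PassRead("chr1", 100, "+", 3)]
    assert len(sites3p.cluster_sites(near)) == 1
    far = [PassRead("chr1", 100, "+", 3), PassRead("chr1", 125, "+", 3),
           PassRead("chr1", 100, "+", 3)]
    assert len(sites3p.cluster_sites(far)) == 2


def test_filter_sites_thresholds():
    def site(pos, total, by_lineage, gene="g1"):
        s = sites3p.PolyASite("chr1", pos, "+", read_count_total=total,
                              read_count_by_lineage=by_lineage)
        s.gene_id = gene
        return s

    totals = {"g1": {"A": 1000, "B": 500}}
    strong = site(100, 50, {"A": 50})                  # 5% of lineage A
    weak_reads = site(200, 9, {"A": 9})                # < 10 reads
    # exactly 2% in every lineage: the fraction must strictly exceed 0.02
    at_threshold = site(300, 30, {"A": 20, "B": 10})
    rescue = site(400, 11, {"B": 11})                  # 2.2% of lineage B
    kept = sites3p.filter_sites([strong, weak_reads, at_threshold, rescue],
                                totals)
    assert [s.pos for s in kept] == [100, 400]


def test_gene_read_totals():
    s1 = sites3p.PolyASite("chr1", 10, "+", read_count_total=5,
                           read_count_by_lineage={"A": 3, "B": 2})
    s1.gene_id = "g1"
    s2 = sites3p.PolyASite("chr1", 40, "+", read_count_total=4,
                           read_count_by_lineage={"A": 4})
    s2.gene_id = "g1"
    orphan = sites3p.PolyASite("chr1", 90, "+", read_count_total=7,
                               read_count_by_lineage={"A": 7})
    totals = sites3p.gene_read_totals([s1, s2, orphan])
    assert totals == {"g1": {"A": 7, "B": 2}}


def _gene(gene_id, chrom, strand, start, end):
    return Gene(gene_id, chrom, strand,
                [Transcript(f"{gene_id}.t", [Exon(start, end)])])


def test_extend_terminal_exon_caps():
    plus = _gene("g1", "chr1", "+", 100, 500)
    alone = Annotation([plus])
    assert sites3p.extend_terminal_exon(plus, alone, 10000) == (500, 5500)
    # capped by the next same-strand TSS
    nxt = _gene("g2", "chr1", "+", 800, 900)
    assert sites3p.extend_terminal_exon(plus, Annotation([plus, nxt]),
                                        10000) == (500, 800)
    # capped by the chromosome end
    assert sites3p.extend_terminal_exon(plus, alone, 600) == (500, 600)

    minus = _gene("g3", "chr1", "-", 500, 900)
    alone_m = Annotation([minus])
    assert sites3p.extend_terminal_exon(minus, alone_m, 10000) == (0, 500)
    upstream = _gene("g4", "chr1", "-", 100, 301)  # tss at 300
    assert sites3p.extend_terminal_exon(
        minus, Annotation([minus, upstream]), 10000) == (301, 500)


def test_assign_genes_uses_extensions():
    gene = _gene("g1", "chr1", "+", 100, 500)
    ann = Annotation([gene])
    inside = sites3p.PolyASite("chr1", 300, "+")
    downstream = sites3p.PolyASite("chr1", 600, "+")
    sites3p.assign_genes([inside, downstream], ann)
    assert inside.gene_id == "g1" and downstream.gene_id is None
    downstream.gene_id = None
    sites3p.assign_genes([downstream], ann, {"g1": (500, 700)})
    assert downstream.gene_id == "g1"


def test_write_bed_and_frame(tmp_path):
    s = sites3p.PolyASite("chr1", 42, "+", read_count_total=12)
    s.gene_id = "g1"
    s.usage = 0.5
    frame = sites3p.sites_to_frame([s])
    assert frame.loc[0, "pos"] == 42 and frame.loc[0, "read_count"] == 12
    path = tmp_path / "sites.bed"
    sites3p.write_bed([s], path)
    fields = path.read_text().strip().split("\t")
    assert fields[:6] == ["chr1", "42", "43", "g1", "12", "+"]
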