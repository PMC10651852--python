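"""PASS-read extraction and expressed polyA-site calling from 3'-end reads.

A PASS (polyA-site-supporting) read carries ≥2 non-genomic As in its
untemplated tail.  Reads are clustered within 24 nt, the position with the
most reads represents each cluster, and clusters are kept when supported by
≥10 reads that amount to >2% of their gene's reads in at least one
cell/tissue lineage.  Because cleavage frequently happens within genomic
A-runs, a read whose alignment ends in (or immediately before) a reference
A-run is assigned to the first A of that run.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .genome import Annotation, Gene, SequenceStore

logger = logging.getLogger(__name__)

GENOMIC_CLASSES = ("intronic", "upstream_exonic", "terminal_exonic",
                   "extended_terminal_exonic", "intergenic")


@dataclass(frozen=True)
class PassRead:
    """One polyA-site-supporting read reduced to its inferred cleavage event."""

    chrom: str
    cleavage_pos: int
    strand: str
    n_nongenomic_a: int
    sample_id: str = "sample"
    lineage: str = "lineage"


@dataclass
class PolyASite:
    chrom: str
    pos: int
    strand: str
    read_count_total: int = 0
    read_count_by_lineage: dict = field(default_factory=dict)
    gene_id: str | None = None
    genomic_class: str | None = None
    usage: float | None = None
    pas_type: str | None = None
    # genomic position -> member read count, for cleavage-vector labels
    read_positions: dict = field(default_factory=dict)

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


# --------------------------------------------------------------------------
# PASS read extraction
# --------------------------------------------------------------------------

def _first_a_of_run(genome: SequenceStore, chrom: str, pos: int, step: int,
                    base: str) -> int:
    """Walk from ``pos`` against transcription (by ``step``) while the
    reference carries ``base``; return the most 5' position of the run."""
    length = genome.chrom_length(chrom)
    while True:
        nxt = pos + step
        if nxt < 0 or nxt >= length:
            break
        if genome.fetch(chrom, nxt, nxt + 1) != base:
            break
        pos = nxt
    return pos


def _ref_run_length(genome: SequenceStore, chrom: str, start: int, step: int,
                    base: str, limit: int) -> int:
    """Length of the reference ``base`` run starting at ``start`` going in
    direction ``step``, capped at ``limit``."""
    length = genome.chrom_length(chrom)
    n = 0
    pos = start
    while 0 <= pos < length and n < limit:
        if genome.fetch(chrom, pos, pos + 1) != base:
            break
        n += 1
        pos += step
    return n


def extract_pass_reads(alignments, genome: SequenceStore,
                       sample_map: dict[str, str] | None = None,
                       min_mapq: int = 10,
                       min_nongenomic_a: int = 2) -> list[PassRead]:
    """Extract PASS reads from a pysam alignment stream.

    The untemplated tail is taken from the terminal soft clip (3' soft clip
    for plus-strand alignments; leading soft clip, reference Ts, for
    minus-strand ones).  Tail As matching the reference beyond the alignment
    end are genomic and subtracted; reads with ≥``min_nongenomic_a``
    remaining are kept.  "Uniquely mapped" means mapping quality ≥
    ``min_mapq`` and no secondary/supplementary flag.

    ``sample_map`` maps sample/read-group labels to lineages; unmapped
    samples keep their own label as lineage.
    """
    sample_map = sample_map or {}
    reads = []
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        chrom = aln.reference_name
        cigar = aln.cigartuples
        seq = aln.query_sequence
        if not cigar or seq is None:
            logger.debug("read %s rejected: missing tail info", aln.query_name)
            continue
        try:
            if not aln.is_reverse:
                strand = "+"
                if cigar[-1][0] != 4:  # soft clip holds the tail
                    continue
                clip = seq[len(seq) - cigar[-1][1]:]
                tail_a = len(clip) - len(clip.lstrip("A"))
                end = aln.reference_end  # exclusive
                last = end - 1
                k = _ref_run_length(genome, chrom, end, +1, "A", tail_a)
                nongenomic = tail_a - k
                if genome.fetch(chrom, last, last + 1) == "A":
                    pos = _first_a_of_run(genome, chrom, last, -1, "A")
                elif k > 0:
                    pos = end  # alignment abuts a genomic A-run
                else:
                    pos = last
            else:
                strand = "-"
                if cigar[0][0] != 4:
                    continue
                clip = seq[: cigar[0][1]]
                tail_a = len(clip) - len(clip.rstrip("T"))
                start = aln.reference_start
                k = _ref_run_length(genome, chrom, start - 1, -1, "T", tail_a)
                nongenomic = tail_a - k
                if genome.fetch(chrom, start, start + 1) == "T":
                    pos = _first_a_of_run(genome, chrom, start, +1, "T")
                elif k > 0:
                    pos = start - 1
                else:
                    pos = start
        except IndexError:
            logger.debug("read %s rejected: past chromosome end", aln.query_name)
            continue
        if nongenomic < min_nongenomic_a:
            continue
        sample = aln.get_tag("RG") if aln.has_tag("RG") else "sample"
        reads.append(PassRead(chrom, pos, strand, nongenomic, sample,
                              sample_map.get(sample, sample)))
    return reads


def read_pass_tsv(path, sample_map: dict[str, str] | None = None,
                  min_nongenomic_a: int = 2) -> list[PassRead]:
    """Load PASS reads from a TSV with columns chrom, pos, strand,
    n_nongenomic_a, sample_id."""
    sample_map = sample_map or {}
    df = pd.read_csv(path, sep="\t")
    reads = []
    for row in df.itertuples(index=False):
        if row.n_nongenomic_a < min_nongenomic_a:
            continue
        reads.append(PassRead(str(row.chrom), int(row.pos), row.strand,
                              int(row.n_nongenomic_a), str(row.sample_id),
                              sample_map.get(str(row.sample_id), str(row.sample_id))))
    return reads


# --------------------------------------------------------------------------
# Clustering and filtering
# --------------------------------------------------------------------------

def cluster_sites(reads: list[PassRead], window: int = 24) -> list[PolyASite]:
    """Greedy clustering of cleavage positions within ``window`` nt.

    Positions are visited in order of decreasing read count (ties broken to
    the 5'-most position in transcript orientation); each seed absorbs every
    unassigned position within ±``window``.  The seed is the representative
    position and every read joins exactly one cluster.
    """
    groups = defaultdict(list)
    for read in reads:
        groups[(read.chrom, read.strand)].append(read)
    sites = []
    for (chrom, strand), members in sorted(groups.items()):
        counts = Counter(r.cleavage_pos for r in members)
        by_pos = defaultdict(list)
        for r in members:
            by_pos[r.cleavage_pos].append(r)
        five_prime = (lambda p: p) if strand == "+" else (lambda p: -p)
        order = sorted(counts, key=lambda p: (-counts[p], five_prime(p)))
        assigned = set()
        for seed in order:
            if seed in assigned:
                continue
            cluster_pos = [p for p in counts
                           if p not in assigned and abs(p - seed) <= window]
            assigned.update(cluster_pos)
            lineage_counts: Counter = Counter()
            read_positions = {}
            total = 0
            for p in cluster_pos:
                read_positions[p] = counts[p]
                total += counts[p]
                for r in by_pos[p]:
                    lineage_counts[r.lineage] += 1
            sites.append(PolyASite(chrom, seed, strand,
                                   read_count_total=total,
                                   read_count_by_lineage=dict(lineage_counts),
                                   read_positions=read_positions))
    return sites


def assign_genes(sites: list[PolyASite], annotation: Annotation,
                 extensions: dict[str, tuple[int, int]] | None = None) -> None:
    """Attach ``gene_id`` to each site (gene span or extended terminal
    region); leaves intergenic sites unassigned."""
    extensions = extensions or {}
    for site in sites:
        for gene in annotation.genes_on(site.chrom, site.strand):
            lo, hi = gene.start, gene.end
            ext = extensions.get(gene.gene_id)
            if ext is not None:
                lo, hi = min(lo, ext[0]), max(hi, ext[1])
            if lo <= site.pos < hi:
                site.gene_id = gene.gene_id
                break


def gene_read_totals(sites: list[PolyASite]) -> dict[str, dict[str, int]]:
    """Per-gene, per-lineage PASS-read totals over the assigned sites."""
    totals: dict[str, Counter] = defaultdict(Counter)
    for site in sites:
        if site.gene_id is None:
            continue
        for lineage, n in site.read_count_by_lineage.items():
            totals[site.gene_id][lineage] += n
    return {g: dict(c) for g, c in totals.items()}


def filter_sites(sites: list[PolyASite],
                 gene_read_totals: dict[str, dict[str, int]],
                 min_reads: int = 10, min_frac: float = 0.02) -> list[PolyASite]:
    """Keep sites with ≥``min_reads`` total reads whose share of the gene's
    reads exceeds ``min_frac`` in at least one lineage."""
    kept = []
    for site in sites:
        if site.read_count_total < min_reads:
            continue
        totals = gene_read_totals.get(site.gene_id, {})
        if not any(totals.values()):
            logger.info("site %s dropped: gene read total zero in every lineage",
                        site.site_id)
            continue
        passes = False
        for lineage, n in site.read_count_by_lineage.items():
            gene_n = totals.get(lineage, 0)
            if gene_n > 0 and n / gene_n > min_frac:
                passes = True
                break
        if passes:
            kept.append(site)
    return kept


def extend_terminal_exon(gene: Gene, annotation: Annotation,
                         chrom_length: int, max_ext: int = 5000) -> tuple[int, int]:
    """3'-extension interval downstream of the annotated gene end.

    The extension is capped at ``max_ext`` nt, the next same-strand TSS, and
    the chromosome boundary; it is never negative.  Returns a 0-based
    half-open interval (empty when no room).
    """
    next_tss = annotation.next_same_strand_tss(gene)
    if gene.strand == "+":
        limit = chrom_length if next_tss is None else min(next_tss, chrom_length)
        ext = max(0, min(max_ext, limit - gene.end))
        return gene.end, gene.end + ext
    limit = 0 if next_tss is None else max(next_tss + 1, 0)
    ext = max(0, min(max_ext, gene.start - limit))
    return gene.start - ext, gene.start


def sites_to_frame(sites: list[PolyASite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": s.chrom, "pos": s.pos, "strand": s.strand,
        "read_count": s.read_count_total, "gene_id": s.gene_id,
        "genomic_class": s.genomic_class, "usage": s.usage,
        "pas_type": s.pas_type,
    } for s in sites])


def write_bed(sites: list[PolyASite], path) -> None:
    """BED6+ output: extra columns read_count, usage, genomic_class."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            usage = "" if s.usage is None else f"{s.usage:.4f}"
            fh.write("\t".join(map(str, [
                s.chrom, s.pos, s.pos + 1, s.gene_id or ".", s.read_count_total,
                s.strand, s.read_count_total, usage, s.genomic_class or "."]))
                + "\n")
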