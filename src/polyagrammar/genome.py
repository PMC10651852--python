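"""Shared sequence and annotation utilities.

Conventions used throughout the package:

- all coordinates are 0-based, half-open intervals; BED on output
- a cleavage position is the genomic coordinate of the last transcribed base
- a prediction window is the 240-nt *sense* sequence covering offsets
  −120..+119 around its anchor, the anchor sitting at string index 120
- cleavage vectors cover offsets −25..+24 (length 50, anchor at index 25)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

WINDOW_HALF = 120
WINDOW_LENGTH = 240
CLEAVAGE_HALF = 25
CLEAVAGE_LENGTH = 50


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceStore:
    """Uniform access to chromosome sequences from a dict or a FASTA file.

    A dict of ``{chrom: sequence}`` is used directly; a path is opened with
    pyfaidx.  Slices outside chromosome bounds raise ``IndexError``.
    """

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict = None
        elif isinstance(source, dict):
            self._dict = {k: v.upper() for k, v in source.items()}
            self._fasta = None
        else:
            raise TypeError("SequenceStore needs a dict or FASTA path")

    def chrom_length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def chroms(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > self.chrom_length(chrom):
            raise IndexError(
                f"{chrom}:{start}-{end} outside chromosome bounds")
        if self._dict is not None:
            return self._dict[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()


def extract_window(genome: SequenceStore, chrom: str, pos: int, strand: str,
                   half: int = WINDOW_HALF) -> str:
    """240-nt sense-orientation window with the anchor at index ``half``.

    Plus strand: genomic [pos-half, pos+half).  Minus strand: genomic
    [pos-half+1, pos+half+1) reverse-complemented, so that sense offset o
    maps to genomic position pos − o.
    """
    if strand == "+":
        return genome.fetch(chrom, pos - half, pos + half)
    seq = genome.fetch(chrom, pos - half + 1, pos + half + 1)
    return revcomp(seq)


@dataclass(frozen=True)
class Exon:
    start: int
    end: int


@dataclass
class Transcript:
    tx_id: str
    exons: list[Exon]

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list[tuple[int, int]]:
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        """Transcription start position (0-based, strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        """Position of the annotated last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def terminal_exon(self) -> Exon:
        """The 3'-most exon over all isoforms."""
        exons = [t.exons[-1] if self.strand == "+" else t.exons[0]
                 for t in self.transcripts]
        if self.strand == "+":
            return max(exons, key=lambda e: e.end)
        return min(exons, key=lambda e: e.start)


class Annotation:
    """A gene set with strand-aware neighbour lookups."""

    def __init__(self, genes: list[Gene]):
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def genes_on(self, chrom: str, strand: str | None = None) -> list[Gene]:
        return [g for g in self.genes
                if g.chrom == chrom and (strand is None or g.strand == strand)]

    def next_same_strand_tss(self, gene: Gene) -> int | None:
        """TSS of the nearest downstream same-strand gene, or None."""
        best = None
        for other in self.genes_on(gene.chrom, gene.strand):
            if other.gene_id == gene.gene_id:
                continue
            if gene.strand == "+":
                if other.tss >= gene.end:
                    if best is None or other.tss < best:
                        best = other.tss
            else:
                if other.tss < gene.start:
                    if best is None or other.tss > best:
                        best = other.tss
        return best

    def next_antisense_gene_distance(self, gene: Gene) -> int | None:
        """Distance from the gene 3'-end to the nearest downstream gene on the
        opposite strand (its closest edge), or None."""
        best = None
        anchor = gene.three_prime_end
        opp = "-" if gene.strand == "+" else "+"
        for other in self.genes_on(gene.chrom, opp):
            if gene.strand == "+":
                if other.start > anchor:
                    d = other.start - anchor
                    best = d if best is None or d < best else best
            else:
                if other.end <= anchor:
                    d = anchor - (other.end - 1)
                    best = d if best is None or d < best else best
        return best

    # ------------------------------------------------------------------ IO

    def to_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in self.genes:
                attrs = f'gene_id "{gene.gene_id}";'
                fh.write("\t".join([
                    gene.chrom, "polyagrammar", "gene", str(gene.start + 1),
                    str(gene.end), ".", gene.strand, ".", attrs]) + "\n")
                for tx in gene.transcripts:
                    tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.tx_id}";'
                    fh.write("\t".join([
                        gene.chrom, "polyagrammar", "transcript",
                        str(tx.start + 1), str(tx.end), ".", gene.strand, ".",
                        tattrs]) + "\n")
                    for exon in tx.exons:
                        fh.write("\t".join([
                            gene.chrom, "polyagrammar", "exon",
                            str(exon.start + 1), str(exon.end), ".",
                            gene.strand, ".", tattrs]) + "\n")

    @classmethod
    def from_gtf(cls, path: str | Path) -> "Annotation":
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True,
                                disable_infer_genes=True,
                                disable_infer_transcripts=True)
        genes = []
        for grec in db.features_of_type("gene"):
            transcripts = []
            for trec in db.children(grec, featuretype="transcript"):
                exons = [Exon(e.start - 1, e.end)
                         for e in db.children(trec, featuretype="exon")]
                transcripts.append(Transcript(trec.id, exons))
            genes.append(Gene(grec.attributes["gene_id"][0], grec.seqid,
                              grec.strand, transcripts))
        return cls(genes)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start:start + width] + "\n")
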