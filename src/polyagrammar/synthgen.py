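"""Synthetic genomes, polyA-site grammars, PASS reads, and variants.

The generator plants a configurable motif grammar around each cleavage site:
an AAUAAA polyadenylation signal ending ~21 nt upstream, a GU-rich CstF
element ~10 nt downstream, and optional elements (UGUA/CFI upstream of the
PAS, a U-rich stretch between the PAS and the cleavage site, a G-rich
element downstream of CstF, a second CstF motif).  Site strength is a
monotone function of the optional-motif count, per-gene usage fractions
follow 2^strength shares, and read 3'-ends disperse around the true
cleavage position with a discretised Gaussian.  Everything is reproducible
from seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import (Annotation, Exon, Gene, SequenceStore, Transcript,
                     revcomp)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class OptionalMotif:
    name: str
    seq: str
    offset_min: int   # motif start offset relative to the cleavage position
    offset_max: int
    prob: float = 0.5


def _default_optional() -> list[OptionalMotif]:
    return [
        OptionalMotif("UGUA", "TGTA", -60, -35, 0.5),
        OptionalMotif("U_rich", "TTTTTT", -18, -10, 0.5),
        OptionalMotif("CstF2", "TGTGTG", 18, 19, 0.5),
        OptionalMotif("G_rich", "GGGGGG", 32, 50, 0.5),
    ]


@dataclass
class GrammarSpec:
    """Motif grammar around a planted cleavage site.

    ``pas_offset`` is the distance from the cleavage position to the 3' end
    of the PAS hexamer (21 puts AAUAAA at offsets −26..−21).  Dispersion is
    the standard deviation (nt) of simulated read 3'-ends around the site.
    """

    pas_offset: int = 21
    pas_hexamer: str = "AATAAA"
    cstf_seq: str = "TGTGTG"
    cstf_offset: int = 10  # motif start offset downstream of cleavage
    optional_motifs: list[OptionalMotif] = field(default_factory=_default_optional)
    cleavage_dispersion: float = 2.0
    background_gc: float = 0.5
    strength_base: float = -4.0
    strength_per_motif: float = 1.6
    strength_noise_sd: float = 0.3
    a_run_prob: float = 0.3  # fraction of sites whose cleavage base starts an A-run

    def __post_init__(self):
        if self.cleavage_dispersion < 0:
            raise ValueError("cleavage_dispersion must be >= 0")

    def pas_span(self) -> tuple[int, int]:
        """Sense offsets [start, end) occupied by the PAS hexamer."""
        end = -self.pas_offset + 1
        return end - len(self.pas_hexamer), end


@dataclass
class TruthSet:
    genome: SequenceStore
    sequences: dict[str, str]
    annotation: Annotation
    grammar: GrammarSpec
    sites: pd.DataFrame                # planted sites with strengths/usages
    latent_sites: pd.DataFrame | None = None
    reads: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# Genome generation
# --------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(BASES, size=n, p=p))


def generate_genome(n_genes: int = 24, seed: int = 0,
                    n_chroms: int = 2,
                    exon_len: tuple[int, int] = (120, 300),
                    intron_len: tuple[int, int] = (200, 700),
                    n_exons: tuple[int, int] = (2, 4),
                    terminal_exon_len: tuple[int, int] = (700, 1200),
                    intergenic_gap: tuple[int, int] = (500, 900),
                    gc: float = 0.5) -> tuple[dict[str, str], Annotation]:
    """Random multi-exon genes on both strands with intergenic gaps.

    Returns the chromosome sequences (as strings) and the annotation.  The
    terminal exon is drawn longer than internal exons so several polyA sites
    fit; reproducible byte-for-byte from ``seed``.
    """
    if n_genes < 1 or n_chroms < 1:
        raise ValueError("need at least one gene and one chromosome")
    if exon_len[0] < 50 or terminal_exon_len[0] < 400:
        raise ValueError("infeasible exon sizes")
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    gene_no = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        cursor = 0

        def emit(n):
            nonlocal cursor
            parts.append("".join(_random_seq(rng, n, gc)))
            cursor += n

        emit(int(rng.integers(*intergenic_gap)))
        for _ in range(n_on_chrom):
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(n_exons[0], n_exons[1] + 1))
            lengths = [int(rng.integers(*exon_len)) for _ in range(k - 1)]
            term = int(rng.integers(*terminal_exon_len))
            # genomic order: on '+' the terminal exon is last, on '-' first
            exon_sizes = lengths + [term] if strand == "+" else [term] + lengths
            exons = []
            for j, size in enumerate(exon_sizes):
                start = cursor
                emit(size)
                exons.append(Exon(start, cursor))
                if j < len(exon_sizes) - 1:
                    emit(int(rng.integers(*intron_len)))
            gene_no += 1
            gid = f"gene{gene_no:03d}"
            genes.append(Gene(gid, chrom, strand,
                              [Transcript(f"{gid}.t1", exons)]))
            emit(int(rng.integers(*intergenic_gap)))
        sequences[chrom] = "".join(parts)
    return sequences, Annotation(genes)


# --------------------------------------------------------------------------
# Site planting
# --------------------------------------------------------------------------

def _write_motif(seq: list[str], pos: int, strand: str, start_off: int,
                 motif: str) -> None:
    """Write ``motif`` at sense offsets [start_off, start_off+len) around the
    cleavage position ``pos``."""
    if strand == "+":
        g = pos + start_off
        seq[g:g + len(motif)] = list(motif)
    else:
        end_off = start_off + len(motif) - 1
        g = pos - end_off
        seq[g:g + len(motif)] = list(revcomp(motif))


def _plant_one(seq: list[str], pos: int, strand: str, grammar: GrammarSpec,
               rng: np.random.Generator, functional_pas: bool = True) -> int:
    """Write the grammar around one site; returns the optional-motif count."""
    pas = grammar.pas_hexamer if functional_pas else "AATCAA"
    _write_motif(seq, pos, strand, grammar.pas_span()[0], pas)
    _write_motif(seq, pos, strand, grammar.cstf_offset, grammar.cstf_seq)
    # cleavage context: CA dinucleotide, optionally opening an A-run
    if rng.random() < grammar.a_run_prob:
        _write_motif(seq, pos, strand, -1, "CAAA")
    else:
        _write_motif(seq, pos, strand, -1, "CA")
        nxt = str(rng.choice(np.array(list("CGT"))))
        _write_motif(seq, pos, strand, 1, nxt)
    count = 0
    for motif in grammar.optional_motifs:
        if rng.random() < motif.prob:
            start = int(rng.integers(motif.offset_min, motif.offset_max + 1))
            _write_motif(seq, pos, strand, start, motif.seq)
            count += 1
    return count


def plant_polya_sites(sequences: dict[str, str], annotation: Annotation,
                      grammar: GrammarSpec | None = None, seed: int = 0,
                      sites_per_gene: tuple[int, int] = (1, 3),
                      min_spacing: int = 80,
                      exon_margin: int = 80) -> TruthSet:
    """Plant polyA sites with the grammar in every gene's terminal exon.

    Site strength is ``strength_base + strength_per_motif × (optional motif
    count) + N(0, strength_noise_sd)``; per-gene usage fractions are the
    normalised 2^strength shares, so they sum to one.  Sequences are
    modified in place around each site.
    """
    grammar = grammar or GrammarSpec()
    rng = np.random.default_rng(seed)
    seq_lists = {c: list(s) for c, s in sequences.items()}
    rows = []
    for gene in annotation:
        term = gene.terminal_exon()
        chrom_len = len(seq_lists[gene.chrom])
        lo = max(term.start + exon_margin, 150)
        hi = min(term.end - exon_margin, chrom_len - 150)
        if hi - lo < min_spacing:
            continue
        n_sites = int(rng.integers(sites_per_gene[0], sites_per_gene[1] + 1))
        placed: list[int] = []
        for _ in range(n_sites):
            for _attempt in range(50):
                pos = int(rng.integers(lo, hi))
                if all(abs(pos - p) >= min_spacing for p in placed):
                    placed.append(pos)
                    break
        for pos in sorted(placed):
            k = _plant_one(seq_lists[gene.chrom], pos, gene.strand, grammar, rng)
            strength = (grammar.strength_base + grammar.strength_per_motif * k
                        + rng.normal(0, grammar.strength_noise_sd))
            rows.append({"chrom": gene.chrom, "pos": pos,
                         "strand": gene.strand, "gene_id": gene.gene_id,
                         "n_optional": k, "strength": strength})
    sites = pd.DataFrame(rows)
    weights = np.exp2(sites["strength"])
    sites["usage"] = weights / weights.groupby(sites["gene_id"]).transform("sum")
    new_sequences = {c: "".join(s) for c, s in seq_lists.items()}
    return TruthSet(SequenceStore(new_sequences), new_sequences, annotation,
                    grammar, sites)


def plant_latent_sites(truth: TruthSet, n: int = 8, seed: int = 1,
                       min_distance: int = 200) -> None:
    """Plant non-functional site grammars (PAS destroyed to AATCAA) for
    PAS-creating variant simulations; they produce no reads."""
    rng = np.random.default_rng(seed)
    seq_lists = {c: list(s) for c, s in truth.sequences.items()}
    rows = []
    genes = list(truth.annotation)
    rng.shuffle(genes)
    for gene in genes:
        if len(rows) >= n:
            break
        term = gene.terminal_exon()
        gene_sites = truth.sites[truth.sites.gene_id == gene.gene_id]
        for _attempt in range(60):
            pos = int(rng.integers(term.start + 80, term.end - 80))
            if len(gene_sites) and (gene_sites.pos - pos).abs().min() < min_distance:
                continue
            _plant_one(seq_lists[gene.chrom], pos, gene.strand, truth.grammar,
                       rng, functional_pas=False)
            rows.append({"chrom": gene.chrom, "pos": pos,
                         "strand": gene.strand, "gene_id": gene.gene_id})
            break
    truth.latent_sites = pd.DataFrame(rows)
    truth.sequences = {c: "".join(s) for c, s in seq_lists.items()}
    truth.genome = SequenceStore(truth.sequences)


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------

def simulate_pass_reads(truth: TruthSet, depth: float = 600.0,
                        dispersion: float | None = None, seed: int = 0,
                        samples: dict[str, str] | None = None) -> pd.DataFrame:
    """Simulate PASS-read 3'-end positions around every planted site.

    Per site and sample, the read count is Poisson(usage × depth / n_samples)
    and each 3'-end offset is a discretised Gaussian (sd ``dispersion``,
    default the grammar's) truncated to ±25 nt.  Non-genomic tail lengths
    are uniform on 2..10.  ``samples`` maps sample_id to lineage (default
    two samples in two lineages).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    grammar = truth.grammar
    sd = grammar.cleavage_dispersion if dispersion is None else dispersion
    samples = samples or {"s1": "lineageA", "s2": "lineageB"}
    rng = np.random.default_rng(seed)
    rows = []
    for site in truth.sites.itertuples(index=False):
        for sample_id, lineage in samples.items():
            n = rng.poisson(site.usage * depth / len(samples))
            if n == 0:
                continue
            if sd == 0:
                offsets = np.zeros(n, dtype=int)
            else:
                offsets = np.rint(rng.normal(0, sd, size=n)).astype(int)
                while np.any(np.abs(offsets) > 25):
                    bad = np.abs(offsets) > 25
                    offsets[bad] = np.rint(rng.normal(0, sd, size=bad.sum())).astype(int)
            sign = 1 if site.strand == "+" else -1
            for off in offsets:
                rows.append({"chrom": site.chrom,
                             "pos": site.pos + sign * int(off),
                             "strand": site.strand,
                             "n_nongenomic_a": int(rng.integers(2, 11)),
                             "sample_id": sample_id,
                             "lineage": lineage,
                             "true_site": site.pos})
    reads = pd.DataFrame(rows)
    truth.reads = reads
    return reads


def reads_to_sam(truth: TruthSet, reads: pd.DataFrame, path,
                 read_len: int = 30) -> None:
    """Write the simulated reads as a text SAM with soft-clipped tails.

    Tail As that continue into a genomic A-run are aligned through it (the
    aligner would do the same), deliberately exercising the first-A
    reassignment convention downstream.
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": len(s)}
                     for c, s in sorted(truth.sequences.items())],
              "RG": [{"ID": s} for s in sorted(reads["sample_id"].unique())]}
    records = []
    for i, read in enumerate(reads.itertuples(index=False)):
        seq = truth.sequences[read.chrom]
        tail = int(read.n_nongenomic_a)
        if read.strand == "+":
            aln_start = read.pos - read_len + 1
            aln_end = read.pos + 1
            # extend the alignment through any genomic A-run
            ext = 0
            while (aln_end + ext < len(seq) and ext < tail
                   and seq[aln_end + ext] == "A"):
                ext += 1
            aln_end += ext
            clip = tail  # soft-clipped As beyond the (extended) alignment
            bases = seq[aln_start:aln_end] + "A" * clip
            flag = 0
            cigar = f"{aln_end - aln_start}M{clip}S"
            pos0 = aln_start
        else:
            aln_start = read.pos
            aln_end = read.pos + read_len
            ext = 0
            while (aln_start - 1 - ext >= 0 and ext < tail
                   and seq[aln_start - 1 - ext] == "T"):
                ext += 1
            aln_start -= ext
            clip = tail
            bases = "T" * clip + seq[aln_start:aln_end]
            flag = 16
            cigar = f"{clip}S{aln_end - aln_start}M"
            pos0 = aln_start
        records.append((read.chrom, pos0, flag, cigar, bases, read.sample_id, i))
    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for chrom, pos0, flag, cigar, bases, sample, i in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}"
            a.reference_name = chrom
            a.reference_start = pos0
            a.flag = flag
            a.mapping_quality = 50
            a.cigarstring = cigar
            a.query_sequence = bases
            a.set_tag("RG", sample)
            out.write(a)


def reads_to_tsv(reads: pd.DataFrame, path) -> None:
    reads[["chrom", "pos", "strand", "n_nongenomic_a", "sample_id"]].to_csv(
        path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Stand-alone training windows
# --------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Arrays of labelled 240-nt training windows.

    ``strength`` is NaN for random negatives; non-functional grammars
    (PAS destroyed) carry the log2-odds a zero-read site would receive
    against a typically-expressed gene, making strength models sensitive to
    PAS loss.  ``motif_count`` is −1 where no grammar was planted.
    """

    x: np.ndarray              # (N, 4, 240) one-hot
    label_class: np.ndarray    # 1 = functional site grammar
    cleavage: np.ndarray       # (N, 50) target vectors
    strength: np.ndarray
    motif_count: np.ndarray
    functional: np.ndarray     # bool


def generate_training_windows(n_positive: int, n_negative: int,
                              grammar: GrammarSpec | None = None,
                              seed: int = 0, max_shift: int = 25,
                              nonfunctional_frac: float = 0.0,
                              nonfunctional_mode: str = "pas",
                              cstf_spacing_range: tuple[int, int] | None = None,
                              dispersion_per_nt: float = 0.15,
                              reference_depth: float = 600.0) -> WindowSet:
    """Random-background windows with the site grammar planted at the centre.

    Each positive draws a shift in −``max_shift``..+``max_shift``; the
    window's anchor sits at that offset from the planted cleavage position
    and the cleavage target is the discretised Gaussian read profile
    (sd = grammar dispersion) re-centred accordingly.  A
    ``nonfunctional_frac`` share of planted grammars is rendered
    non-functional (class 0, strongly negative strength):
    ``nonfunctional_mode="pas"`` corrupts one random PAS base, while
    ``"element"`` corrupts either the PAS or erases the CstF element (50/50),
    so classifiers must learn the PAS∧CstF conjunction rather than either
    element alone.  Negatives are uniform random windows with the constant
    0.02 background vector.

    ``cstf_spacing_range`` draws each site's CstF start offset uniformly
    from [lo, hi] and widens the cleavage dispersion by ``dispersion_per_nt``
    per nt beyond ``lo`` — tighter PAS↔CstF grammars cleave more precisely —
    so models can learn the distance→heterogeneity relationship.  ``None``
    keeps the grammar's fixed offset and dispersion.
    """
    from .trainset import BACKGROUND, usage_logodds

    if nonfunctional_mode not in ("pas", "element"):
        raise ValueError("nonfunctional_mode must be 'pas' or 'element'")
    grammar = grammar or GrammarSpec()
    rng = np.random.default_rng(seed)
    eye = np.eye(4, dtype=np.float32)
    index = {b: i for i, b in enumerate("ACGT")}
    buf_len = 240 + 2 * max_shift
    site_idx = max_shift + 120
    sd = grammar.cleavage_dispersion
    offs = np.arange(-25, 25)
    # Eq.-4 label of an unexpressed site against a gene whose top two sites
    # carry half / quarter of the reference depth
    dead_strength = usage_logodds(0.0, reference_depth / 2,
                                  reference_depth / 4).o_i

    n = n_positive + n_negative
    x = np.empty((n, 4, 240), dtype=np.float32)
    label = np.zeros(n)
    cleavage = np.full((n, 50), BACKGROUND, dtype=np.float64)
    strength = np.full(n, np.nan)
    motif_count = np.full(n, -1, dtype=int)
    functional = np.zeros(n, dtype=bool)

    pas_lo = site_idx + grammar.pas_span()[0]
    for i in range(n_positive):
        is_functional = rng.random() >= nonfunctional_frac
        buf = _random_seq(rng, buf_len, grammar.background_gc)
        site_grammar, sd = grammar, grammar.cleavage_dispersion
        if cstf_spacing_range is not None:
            spacing = int(rng.integers(cstf_spacing_range[0],
                                       cstf_spacing_range[1] + 1))
            site_grammar = replace(grammar, cstf_offset=spacing)
            sd = (grammar.cleavage_dispersion
                  + dispersion_per_nt * (spacing - cstf_spacing_range[0]))
        k = _plant_one(buf, site_idx, "+", site_grammar, rng,
                       functional_pas=True)
        if not is_functional:
            if nonfunctional_mode == "element" and rng.random() < 0.5:
                # erase the CstF element: downstream grammar alone must not
                # be taken as evidence of a site
                c0 = site_idx + site_grammar.cstf_offset
                buf[c0:c0 + len(grammar.cstf_seq)] = _random_seq(
                    rng, len(grammar.cstf_seq), grammar.background_gc)
            else:
                # corrupt one random PAS base so models learn PAS loss from
                # arbitrary single-nucleotide disruptions
                j = pas_lo + int(rng.integers(len(grammar.pas_hexamer)))
                buf[j] = str(rng.choice([b for b in "ACGT" if b != buf[j]]))
        shift = int(rng.integers(-max_shift, max_shift + 1))
        window = buf[max_shift + shift: max_shift + shift + 240]
        x[i] = eye[[index[b] for b in window]].T
        motif_count[i] = k
        functional[i] = is_functional
        label[i] = 1.0 if is_functional else 0.0
        if is_functional:
            site_off = -shift
            if sd == 0:
                prof = (offs == site_off).astype(float)
            else:
                prof = np.exp(-0.5 * ((offs - site_off) / sd) ** 2)
                prof[np.abs(offs - site_off) > max_shift] = 0.0
            cleavage[i] = prof / prof.sum()
            strength[i] = (grammar.strength_base
                           + grammar.strength_per_motif * k
                           + rng.normal(0, grammar.strength_noise_sd))
        else:
            strength[i] = dead_strength
    for i in range(n_positive, n):
        window = _random_seq(rng, 240, grammar.background_gc)
        x[i] = eye[[index[b] for b in window]].T
    return WindowSet(x, label, cleavage, strength, motif_count, functional)


# --------------------------------------------------------------------------
# Variant simulation
# --------------------------------------------------------------------------

def simulate_variants(truth: TruthSet, n_per_class: int = 8,
                      seed: int = 2) -> pd.DataFrame:
    """Balanced PAS-destroying / PAS-creating / neutral point variants.

    Destroyers flip the third base of a planted AAUAAA (AAT→AAC); creators
    revert the latent AATCAA grammars back to AAUAAA; neutral variants sit
    in intergenic sequence ≥150 nt from any planted or latent site and touch
    no recognisable motif hexamer in either allele.
    """
    from .motifgrammar import classify_motif_family

    rng = np.random.default_rng(seed)
    rows = []
    grammar = truth.grammar
    pas_start = grammar.pas_span()[0]

    def allele_at(chrom, gpos, strand, sense_base):
        return sense_base if strand == "+" else revcomp(sense_base)

    sites = truth.sites.sample(frac=1.0, random_state=int(rng.integers(2 ** 31)))
    for site in sites.itertuples(index=False):
        if sum(r["intended_effect"] == "destroy" for r in rows) >= n_per_class:
            break
        off = pas_start + 2  # the T of AAT|AAA
        gpos = site.pos + off if site.strand == "+" else site.pos - off
        ref = allele_at(site.chrom, gpos, site.strand, "T")
        alt = allele_at(site.chrom, gpos, site.strand, "C")
        rows.append({"chrom": site.chrom, "pos": gpos, "ref": ref, "alt": alt,
                     "intended_effect": "destroy", "site_pos": site.pos,
                     "strand": site.strand, "gene_id": site.gene_id})

    if truth.latent_sites is not None:
        for site in truth.latent_sites.itertuples(index=False):
            if sum(r["intended_effect"] == "create" for r in rows) >= n_per_class:
                break
            off = pas_start + 3  # the C of AAT(C)AA
            gpos = site.pos + off if site.strand == "+" else site.pos - off
            ref = allele_at(site.chrom, gpos, site.strand, "C")
            alt = allele_at(site.chrom, gpos, site.strand, "A")
            rows.append({"chrom": site.chrom, "pos": gpos, "ref": ref,
                         "alt": alt, "intended_effect": "create",
                         "site_pos": site.pos, "strand": site.strand,
                         "gene_id": site.gene_id})

    all_sites = list(zip(truth.sites.chrom, truth.sites.pos))
    if truth.latent_sites is not None and len(truth.latent_sites):
        all_sites += list(zip(truth.latent_sites.chrom, truth.latent_sites.pos))
    n_neutral = 0
    chroms = sorted(truth.sequences)
    attempts = 0
    while n_neutral < n_per_class and attempts < 5000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = truth.sequences[chrom]
        gpos = int(rng.integers(150, len(seq) - 150))
        if any(c == chrom and abs(p - gpos) < 150 for c, p in all_sites):
            continue
        in_gene = any(g.start - 150 <= gpos < g.end + 150
                      for g in truth.annotation.genes_on(chrom))
        if in_gene:
            continue
        ref = seq[gpos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        clean = True
        for start in range(gpos - 5, gpos + 1):
            if start < 0 or start + 6 > len(seq):
                continue
            for allele_seq in (seq[start:start + 6],
                               seq[start:gpos] + alt + seq[gpos + 1:start + 6]):
                for probe in (allele_seq, revcomp(allele_seq)):
                    if classify_motif_family(probe).name != "none":
                        clean = False
        if not clean:
            continue
        rows.append({"chrom": chrom, "pos": gpos, "ref": ref, "alt": alt,
                     "intended_effect": "none", "site_pos": -1,
                     "strand": ".", "gene_id": None})
        n_neutral += 1
    variants = pd.DataFrame(rows)
    truth.variants = variants
    return variants


def variants_to_vcf(truth: TruthSet, variants: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(truth.sequences):
            fh.write(f"##contig=<ID={chrom},length={len(truth.sequences[chrom])}>\n")
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,'
                 'Description="Intended effect on planted grammar">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = variants.sort_values(["chrom", "pos"])
        for i, v in enumerate(ordered.itertuples(index=False)):
            fh.write(f"{v.chrom}\t{v.pos + 1}\tvar{i}\t{v.ref}\t{v.alt}\t.\t.\t"
                     f"EFFECT={v.intended_effect}\n")
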