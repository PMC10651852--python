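"""Nucleotide-resolution site prediction by 1-nt scanning and consolidation.

A 240-nt window slides one nucleotide per step across the nascent sense
sequence; anchors with classification probability > 0.5 whose cleavage
vector centre exceeds 0.05 are retained.  Within each run of retained
anchors the background-subtracted, renormalised cleavage vectors are
projected onto genomic coordinates and averaged position-wise; the position
of maximum averaged probability represents the putative site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import (Annotation, CLEAVAGE_HALF, CLEAVAGE_LENGTH,
                     SequenceStore, WINDOW_HALF, WINDOW_LENGTH, revcomp)
from .trainset import BACKGROUND, one_hot

logger = logging.getLogger(__name__)

P_CLASS_THRESHOLD = 0.5
CENTER_THRESHOLD = 0.05

_ENC = np.zeros(128, dtype=np.int8) + 4
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
_EYE5 = np.eye(5, dtype=np.float32)[:, :4]  # N row -> zero column


@dataclass
class ScanRecord:
    anchor_pos: int
    p_class: float
    cleavage: np.ndarray
    retained: bool


@dataclass
class PutativeSite:
    chrom: str | None
    pos: int
    strand: str
    p_class: float
    cleavage: np.ndarray            # consolidated vector, offsets −25..+24
    peak_probability: float         # averaged probability at the peak
    n_records: int
    genomic_class: str | None = None
    mcp: float | None = None
    entropy: float | None = None
    strength: float | None = None


def _encode_windows(sense_seq: str, n_windows: int) -> np.ndarray:
    """One-hot (n, 240, 4) for windows starting at indices 0..n_windows-1."""
    ints = _ENC[np.frombuffer(sense_seq.encode(), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(ints, WINDOW_LENGTH)[:n_windows]
    return _EYE5[windows]


def scan_sequence(seq: str, model, anchors_offset: int = WINDOW_HALF,
                  p_threshold: float = P_CLASS_THRESHOLD,
                  center_threshold: float = CENTER_THRESHOLD,
                  batch_size: int = 2048) -> list[ScanRecord]:
    """Scan a raw sense sequence; anchors run from index ``anchors_offset``
    to ``len(seq) - (240 - anchors_offset)``, one record per position."""
    n = len(seq) - WINDOW_LENGTH + 1
    if n <= 0:
        return []
    records = []
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        x = _encode_windows(seq[start:stop + WINDOW_LENGTH - 1],
                            stop - start).transpose(0, 2, 1)
        p, q = model.predict(x)
        for i in range(stop - start):
            anchor = anchors_offset + start + i
            retained = bool(p[i] > p_threshold
                            and q[i, CLEAVAGE_HALF] > center_threshold)
            records.append(ScanRecord(anchor, float(p[i]), q[i], retained))
    return records


def scan_region(genome: SequenceStore, chrom: str, start: int, end: int,
                strand: str, model, step: int = 1, **kwargs) -> list[ScanRecord]:
    """Scan genomic anchors in [start, end) on one strand.

    Anchors are genomic coordinates; records are emitted 5'→3' in
    transcript orientation.  The region plus 120-nt flanks must lie on the
    chromosome.
    """
    if end <= start:
        return []
    if strand == "+":
        sense = genome.fetch(chrom, start - WINDOW_HALF, end + WINDOW_HALF)
        records = scan_sequence(sense, model, **kwargs)
        for rec in records:
            rec.anchor_pos = start + (rec.anchor_pos - WINDOW_HALF)
    else:
        sense = revcomp(genome.fetch(chrom, start - WINDOW_HALF + 1,
                                     end + WINDOW_HALF))
        records = scan_sequence(sense, model, **kwargs)
        for rec in records:
            rec.anchor_pos = (end - 1) - (rec.anchor_pos - WINDOW_HALF)
    if step > 1:
        records = records[::step]
    return records


def consolidate(records: list[ScanRecord], strand: str = "+",
                chrom: str | None = None, gap: int = 0,
                background: float = BACKGROUND) -> list[PutativeSite]:
    """Merge runs of retained anchors into putative sites.

    Each retained record's cleavage vector is background-subtracted (floored
    at zero), renormalised, projected onto genomic coordinates, and averaged
    position-wise over the records of its cluster.  The position of maximum
    averaged probability is the representative site; ties break 5'-most.
    """
    retained = [r for r in records if r.retained]
    if not retained:
        return []
    retained.sort(key=lambda r: r.anchor_pos)
    clusters: list[list[ScanRecord]] = [[retained[0]]]
    for rec in retained[1:]:
        if rec.anchor_pos - clusters[-1][-1].anchor_pos <= 1 + gap:
            clusters[-1].append(rec)
        else:
            clusters.append([rec])
    sign = 1 if strand == "+" else -1
    sites = []
    for cluster in clusters:
        acc: dict[int, float] = {}
        n_used = 0
        p_max = 0.0
        for rec in cluster:
            v = np.maximum(rec.cleavage - background, 0.0)
            total = v.sum()
            if total <= 0:
                logger.info("anchor %d dropped: all-zero after background "
                            "subtraction", rec.anchor_pos)
                continue
            v = v / total
            n_used += 1
            p_max = max(p_max, rec.p_class)
            for j in range(CLEAVAGE_LENGTH):
                if v[j] > 0:
                    gpos = rec.anchor_pos + sign * (j - CLEAVAGE_HALF)
                    acc[gpos] = acc.get(gpos, 0.0) + v[j]
        if n_used == 0:
            continue
        mean = {p: s / n_used for p, s in acc.items()}
        peak = max(mean.values())
        candidates = [p for p, v in mean.items() if v == peak]
        rep = min(candidates) if strand == "+" else max(candidates)
        vec = np.zeros(CLEAVAGE_LENGTH)
        for j in range(CLEAVAGE_LENGTH):
            gpos = rep + sign * (j - CLEAVAGE_HALF)
            vec[j] = mean.get(gpos, 0.0)
        total = vec.sum()
        if total > 0:
            vec /= total
        sites.append(PutativeSite(chrom, rep, strand, p_max, vec, peak, n_used,
                                  mcp=mean_cleavage_position(vec)))
    return sites


def mean_cleavage_position(v: np.ndarray) -> float:
    """Probability-weighted mean 1-based index of a length-50 cleavage vector."""
    v = np.asarray(v, dtype=np.float64)
    total = v.sum()
    if total <= 0:
        raise ValueError("cleavage vector sums to zero")
    if abs(total - 1.0) > 1e-6:
        logger.warning("cleavage vector not normalised (sum %.4f); renormalising",
                       total)
        v = v / total
    return float(v @ np.arange(1, CLEAVAGE_LENGTH + 1))


_CLASS_PRECEDENCE = ("terminal_exonic", "upstream_exonic", "intronic",
                     "extended_terminal_exonic", "intergenic")


def classify_genomic_location(site, annotation: Annotation,
                              extensions: dict[str, tuple[int, int]] | None = None
                              ) -> str:
    """Assign a genomic class from gene structure.

    When isoforms or genes disagree the precedence is terminal exonic >
    upstream exonic > intronic > extended terminal exonic > intergenic.
    ``extensions`` maps gene_id to the 3'-extension interval.
    """
    extensions = extensions or {}
    labels = set()
    for gene in annotation.genes_on(site.chrom, site.strand):
        for tx in gene.transcripts:
            terminal = tx.exons[-1] if gene.strand == "+" else tx.exons[0]
            for exon in tx.exons:
                if exon.start <= site.pos < exon.end:
                    labels.add("terminal_exonic" if exon == terminal
                               else "upstream_exonic")
            for intron in tx.introns():
                if intron[0] <= site.pos < intron[1]:
                    labels.add("intronic")
        ext = extensions.get(gene.gene_id)
        if ext is not None and ext[0] <= site.pos < ext[1]:
            labels.add("extended_terminal_exonic")
    for label in _CLASS_PRECEDENCE:
        if label in labels:
            return label
    return "intergenic"


# --------------------------------------------------------------------------
# Variant effects
# --------------------------------------------------------------------------

@dataclass
class VariantEffect:
    variant_id: str
    gene: str | None
    strand: str
    site_pos_ref: int | None
    site_pos_alt: int | None
    p_class_ref: float
    p_class_alt: float
    strength_ref: float
    strength_alt: float
    delta_strength: float
    significant: bool
    intronic_expression_prob: float | None = None
    genomic_class: str | None = None


def _touches_important_hexamer(ref_ctx: str, alt_ctx: str, var_index: int,
                               important: set[str]) -> bool:
    """True if any hexamer overlapping the variant, in either allele or
    orientation, belongs to the important set."""
    for ctx in (ref_ctx, alt_ctx):
        for start in range(max(0, var_index - 5), var_index + 1):
            hexamer = ctx[start:start + 6]
            if len(hexamer) == 6 and (hexamer in important
                                      or revcomp(hexamer) in important):
                return True
    return False


def predict_variant_effect(variant, genome: SequenceStore, polyaid,
                           polyastrength, important_hexamers: set[str],
                           annotation: Annotation | None = None,
                           extensions: dict[str, tuple[int, int]] | None = None,
                           intronic_prob_fn=None,
                           strand: str | None = None,
                           scan_half: int = WINDOW_HALF,
                           p_sig: float = 0.9, strength_sig: float = -9.0,
                           delta_sig: float = 1.0,
                           max_extension_distance: int = 1000
                           ) -> VariantEffect | None:
    """Evaluate a single-nucleotide variant's effect on polyadenylation.

    Returns None when neither allele touches an important hexamer.  Both
    alleles are scanned over the identical ±120-nt anchor set; the
    representative position is the consolidated peak (taken from the allele
    with the stronger peak when only one allele yields a site), and
    significance requires max p_class ≥ 0.9, max strength ≥ −9 and
    |Δstrength| ≥ 1 (plus the intronic expression-probability gate and the
    ≤1-kb extended-region rule when applicable).
    """
    chrom, pos = variant["chrom"], int(variant["pos"])
    ref, alt = variant["ref"], variant["alt"]
    vid = variant.get("id", f"{chrom}:{pos}:{ref}>{alt}")
    margin = scan_half + WINDOW_HALF + CLEAVAGE_HALF + 10
    lo = max(0, pos - margin)
    hi = min(genome.chrom_length(chrom), pos + margin + 1)
    region = genome.fetch(chrom, lo, hi)
    vi = pos - lo
    if region[vi:vi + len(ref)] != ref:
        raise ValueError(f"reference mismatch for {vid}")
    ref_ctx = region
    alt_ctx = region[:vi] + alt + region[vi + len(ref):]
    if not _touches_important_hexamer(ref_ctx[vi - 5:vi + 6],
                                      alt_ctx[vi - 5:vi + 6], 5,
                                      important_hexamers):
        return None

    if strand is not None:
        strands = [strand]
    elif annotation is not None:
        strands = sorted({g.strand for g in annotation.genes_on(chrom)
                          if g.start - 1000 <= pos < g.end + 1000}) or ["+", "-"]
    else:
        strands = ["+", "-"]

    best_effect = None
    for st in strands:
        effect = _effect_on_strand(vid, chrom, pos, ref_ctx, alt_ctx, lo, st,
                                   polyaid, polyastrength, scan_half)
        if effect is None:
            continue
        gene_id, gclass = None, None
        if annotation is not None and effect.site_pos_alt is not None:
            probe = PutativeSite(chrom, effect.site_pos_alt, st, 0.0,
                                 np.zeros(CLEAVAGE_LENGTH), 0.0, 0)
            gclass = classify_genomic_location(probe, annotation, extensions)
            for gene in annotation.genes_on(chrom, st):
                lo_g, hi_g = gene.start, gene.end
                ext = (extensions or {}).get(gene.gene_id)
                if ext:
                    lo_g, hi_g = min(lo_g, ext[0]), max(hi_g, ext[1])
                if lo_g <= effect.site_pos_alt < hi_g:
                    gene_id = gene.gene_id
                    break
        effect.gene = gene_id
        effect.genomic_class = gclass
        significant = (max(effect.p_class_ref, effect.p_class_alt) >= p_sig
                       and max(effect.strength_ref, effect.strength_alt) >= strength_sig
                       and abs(effect.delta_strength) >= delta_sig)
        if gclass == "extended_terminal_exonic" and gene_id is not None:
            gene = annotation.get(gene_id)
            dist = (effect.site_pos_alt - gene.three_prime_end if st == "+"
                    else gene.three_prime_end - effect.site_pos_alt)
            if dist > max_extension_distance:
                significant = False
        if gclass == "intronic" and intronic_prob_fn is not None:
            prob = intronic_prob_fn(chrom, effect.site_pos_alt, st)
            effect.intronic_expression_prob = prob
            if prob < 0.9:
                significant = False
        effect.significant = significant
        if best_effect is None or effect.p_class_alt > best_effect.p_class_alt:
            best_effect = effect
    return best_effect


def _effect_on_strand(vid, chrom, pos, ref_ctx, alt_ctx, offset, strand,
                      polyaid, polyastrength, scan_half):
    """Scan both alleles on one strand over identical anchors."""
    results = {}
    for name, ctx in (("ref", ref_ctx), ("alt", alt_ctx)):
        if strand == "+":
            sense = ctx
            first_anchor = offset + WINDOW_HALF
            records = scan_sequence(sense, polyaid)
            for rec in records:
                rec.anchor_pos = first_anchor + (rec.anchor_pos - WINDOW_HALF)
        else:
            sense = revcomp(ctx)
            records = scan_sequence(sense, polyaid)
            last = offset + len(ctx) - 1
            for rec in records:
                rec.anchor_pos = last - WINDOW_HALF - (rec.anchor_pos - WINDOW_HALF)
        records = [r for r in records if abs(r.anchor_pos - pos) <= scan_half]
        sites = consolidate(records, strand=strand, chrom=chrom)
        best = max(sites, key=lambda s: s.peak_probability) if sites else None
        results[name] = (records, best, sense)

    rep = {}
    for name in ("ref", "alt"):
        best = results[name][1]
        rep[name] = best.pos if best is not None else None
    if rep["ref"] is None and rep["alt"] is None:
        # no site on either allele: evaluate at the max-p anchor
        ref_records = results["ref"][0]
        if not ref_records:
            return None
        anchor = max(ref_records, key=lambda r: r.p_class).anchor_pos
        rep = {"ref": anchor, "alt": anchor}
        site_ref = site_alt = None
    else:
        site_ref = rep["ref"] if rep["ref"] is not None else rep["alt"]
        site_alt = rep["alt"] if rep["alt"] is not None else rep["ref"]
        rep = {"ref": site_ref, "alt": site_alt}

    def predict_at(name, anchor):
        records, _best, sense = results[name]
        if strand == "+":
            idx = anchor - offset  # index in ref/alt context
            window = (ref_ctx if name == "ref" else alt_ctx)[idx - WINDOW_HALF:
                                                             idx + WINDOW_HALF]
        else:
            ctx = ref_ctx if name == "ref" else alt_ctx
            idx = anchor - offset
            window = revcomp(ctx[idx - WINDOW_HALF + 1: idx + WINDOW_HALF + 1])
        x = one_hot(window)[None]
        p, _q = polyaid.predict(x)
        s = polyastrength.predict(x)
        return float(p[0]), float(s[0])

    p_ref, s_ref = predict_at("ref", rep["ref"])
    p_alt, s_alt = predict_at("alt", rep["alt"])
    return VariantEffect(vid, None, strand, site_ref, site_alt, p_ref, p_alt,
                         s_ref, s_alt, s_alt - s_ref, False)
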