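"""Unit tests for the synthetic genome / grammar / read generator."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

from polyagrammar import motifgrammar, sites3p, synthgen
from polyagrammar.genome import extract_window
from polyagrammar.trainset import decode_one_hot
from conftest import reads_as_pass


def test_generate_genome_deterministic():
    seq_a, ann_a = synthgen.generate_genome(n_genes=6, seed=5)
    seq_b, ann_b = synthgen.generate_genome(n_genes=6, seed=5)
    assert seq_a == seq_b
    assert [(g.gene_id, g.chrom, g.strand, g.start, g.end)
            for g in ann_a] == [(g.gene_id, g.chrom, g.strand, g.start, g.end)
                                for g in ann_b]
    seq_c, _ = synthgen.generate_genome(n_genes=6, seed=6)
    assert seq_a != seq_c


def test_grammar_pas_span():
    grammar = synthgen.GrammarSpec()
    # pas_offset 21 puts the hexamer at sense offsets -26..-21
    assert grammar.pas_span() == (-26, -20)
    with pytest.raises(ValueError):
        synthgen.GrammarSpec(cleavage_dispersion=-1.0)


@pytest.fixture(scope="module")
def small_truth():
    sequences, annotation = synthgen.generate_genome(n_genes=8, seed=15)
    # one site per gene: no chance of optional motifs from a neighbouring
    # site overprinting another site's core grammar
    return synthgen.plant_polya_sites(sequences, annotation, seed=16,
                                      sites_per_gene=(1, 1))


def test_planted_sites_carry_the_grammar(small_truth):
    assert len(small_truth.sites) > 0
    strands = set()
    for site in small_truth.sites.itertuples(index=False):
        window = extract_window(small_truth.genome, site.chrom, int(site.pos),
                                site.strand)
        # PAS at sense offsets -26..-21 (window indices 94..100)
        assert window[94:100] == "AATAAA"
        # CstF element starting at +10 (window indices 130..136)
        assert window[130:136] == "TGTGTG"
        strands.add(site.strand)
    assert strands == {"+", "-"}


def test_usage_sums_to_one_per_gene(small_truth):
    sums = small_truth.sites.groupby("gene_id").usage.sum()
    np.testing.assert_allclose(sums.values, 1.0, atol=1e-12)
    # strength tracks the optional-motif count up to the planted noise
    g = small_truth.sites
    expected = -4.0 + 1.6 * g.n_optional
    assert (np.abs(g.strength - expected) < 4 * 0.3).all()


def test_simulate_reads_zero_dispersion_and_conservation(small_truth):
    reads = synthgen.simulate_pass_reads(small_truth, depth=300.0,
                                         dispersion=0.0, seed=3)
    assert (reads.pos == reads.true_site).all()
    assert set(reads.lineage) == {"lineageA", "lineageB"}
    again = synthgen.simulate_pass_reads(small_truth, depth=300.0,
                                         dispersion=0.0, seed=3)
    assert reads.equals(again)


def test_sam_round_trip_recovers_sites(tmp_path, small_truth):
    """reads -> SAM -> pysam -> PASS extraction -> clustering recovers the
    planted positions despite genomic A-run ambiguity."""
    import pysam

    reads = synthgen.simulate_pass_reads(small_truth, depth=150.0, seed=4)
    sam = tmp_path / "reads.sam"
    synthgen.reads_to_sam(small_truth, reads, sam)
    with pysam.AlignmentFile(str(sam)) as fh:
        extracted = sites3p.extract_pass_reads(fh, small_truth.genome)
    # a small fraction of reads is unrecoverable by design: when a tail A
    # chance-matches the reference beyond the alignment end, the genomic
    # subtraction pushes the nongenomic count below the PASS threshold
    assert len(extracted) >= 0.98 * len(reads)
    clusters = sites3p.cluster_sites(extracted)
    sd = small_truth.grammar.cleavage_dispersion
    for site in small_truth.sites.itertuples(index=False):
        near = [c for c in clusters if c.chrom == site.chrom
                and c.strand == site.strand and abs(c.pos - site.pos) <= sd]
        assert near, f"planted site {site.chrom}:{site.pos} lost in SAM round trip"


def test_training_windows_labels_and_targets():
    ws = synthgen.generate_training_windows(40, 20, seed=9, max_shift=0)
    assert ws.x.shape == (60, 4, 240)
    assert ws.label_class[:40].sum() == 40 and ws.label_class[40:].sum() == 0
    for i in range(40):
        np.testing.assert_allclose(ws.cleavage[i].sum(), 1.0, atol=1e-12)
        assert ws.cleavage[i].argmax() == 25      # unshifted anchor
        assert np.isfinite(ws.strength[i])
        window = decode_one_hot(ws.x[i])
        assert window[94:100] == "AATAAA"
    # negatives carry the constant background vector and NaN strength
    np.testing.assert_allclose(ws.cleavage[40:], 0.02)
    assert np.isnan(ws.strength[40:]).all()
    assert (ws.motif_count[40:] == -1).all()


def test_training_windows_shift_moves_cleavage_peak():
    ws = synthgen.generate_training_windows(200, 0, seed=12, max_shift=10)
    grammar = synthgen.GrammarSpec()
    for i in range(200):
        window = decode_one_hot(ws.x[i])
        peak = int(ws.cleavage[i].argmax()) - 25   # sense offset of the site
        # the grammar follows the peak: PAS ends 21 nt upstream of the site
        pas_at = 120 + peak - 26
        assert window[pas_at:pas_at + 6] == grammar.pas_hexamer


def test_training_windows_nonfunctional_modes():
    pas_mode = synthgen.generate_training_windows(
        60, 0, seed=21, max_shift=0, nonfunctional_frac=1.0)
    assert pas_mode.label_class.sum() == 0
    assert len(set(pas_mode.strength)) == 1       # the shared dead-site label
    assert pas_mode.strength[0] < -5
    for i in range(60):
        window = decode_one_hot(pas_mode.x[i])
        assert window[94:100] != "AATAAA"          # PAS corrupted
        assert window[130:136] == "TGTGTG"         # CstF left intact

    elem_mode = synthgen.generate_training_windows(
        120, 0, seed=22, max_shift=0, nonfunctional_frac=1.0,
        nonfunctional_mode="element")
    pas_broken = cstf_broken = 0
    for i in range(120):
        window = decode_one_hot(elem_mode.x[i])
        pas_ok = window[94:100] == "AATAAA"
        cstf_ok = window[130:136] == "TGTGTG"
        assert not (pas_ok and cstf_ok)            # never a functional pair
        pas_broken += not pas_ok
        cstf_broken += not cstf_ok
    assert pas_broken > 20 and cstf_broken > 20    # both branches exercised

    with pytest.raises(ValueError):
        synthgen.generate_training_windows(1, 0, nonfunctional_mode="bogus")


def test_spacing_range_couples_dispersion():
    """Wider PAS-CstF spacing must produce broader cleavage targets: the
    planted truth itself carries the distance-to-heterogeneity relationship."""
    # quiet grammar: drop the optional motifs so the planted CstF element is
    # the only TGTGTG and the spacing can be read back unambiguously
    quiet = synthgen.GrammarSpec(optional_motifs=[])
    ws = synthgen.generate_training_windows(300, 0, seed=30, grammar=quiet,
                                            cstf_spacing_range=(10, 50))
    spacings, entropies = [], []
    for i in range(300):
        window = decode_one_hot(ws.x[i])
        site = 120 + int(ws.cleavage[i].argmax()) - 25   # anchor may be shifted
        hits = [s for s in range(10, 51)
                if window[site + s:site + s + 6] == "TGTGTG"]
        if len(hits) != 1:      # skip chance extra matches
            continue
        spacings.append(hits[0])
        entropies.append(motifgrammar.cleavage_entropy(ws.cleavage[i]))
    assert len(spacings) > 200
    rho = spearmanr(spacings, entropies).statistic
    assert rho > 0.5


def test_latent_sites_and_variants(small_truth):
    synthgen.plant_latent_sites(small_truth, n=4, seed=17)
    assert len(small_truth.latent_sites) == 4
    for site in small_truth.latent_sites.itertuples(index=False):
        window = extract_window(small_truth.genome, site.chrom, int(site.pos),
                                site.strand)
        assert window[94:100] == "AATCAA"          # destroyed PAS
        assert window[130:136] == "TGTGTG"
    variants = synthgen.simulate_variants(small_truth, n_per_class=4, seed=18)
    counts = variants.intended_effect.value_counts()
    assert counts.get("destroy", 0) >= 4
    assert counts.get("create", 0) == 4
    assert counts.get("none", 0) == 4
    for v in variants.itertuples(index=False):
        base = small_truth.genome.fetch(v.chrom, int(v.pos), int(v.pos) + 1)
        assert base == v.ref                      # ref allele matches genome
        assert v.alt != v.ref


def test_variants_to_vcf(tmp_path, small_truth):
    if small_truth.variants is None:
        synthgen.plant_latent_sites(small_truth, n=4, seed=17)
        synthgen.simulate_variants(small_truth, n_per_class=4, seed=18)
    path = tmp_path / "variants.vcf"
    synthgen.variants_to_vcf(small_truth, small_truth.variants, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == len(small_truth.variants)
    chrom, pos, _vid, ref, _alt = lines[0].split("\t")[:5]
    # VCF positions are 1-based
    assert small_truth.genome.fetch(chrom, int(pos) - 1, int(pos)) == ref


def test_pass_reads_via_conftest_helper(small_truth):
    reads = synthgen.simulate_pass_reads(small_truth, depth=100.0, seed=5)
    as_pass = reads_as_pass(reads)
    assert len(as_pass) == len(reads)
    assert as_pass[0].chrom == reads.iloc[0].chrom
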