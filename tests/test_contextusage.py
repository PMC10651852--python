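"""Unit tests for gene-structure features, quantile matching, logistic
usage models, BH correction and APA differential testing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyagrammar.contextusage import (PWMSpliceScorer, apa_differential_test,
                                       benjamini_hochberg,
                                       classify_intronic_type,
                                       compute_features, find_host_intron,
                                       fit_usage_classifier, log_distance,
                                       predict_usage_probability,
                                       quantile_match_by_strength,
                                       select_terminal_pairs)
from polyagrammar.genome import (Annotation, Exon, Gene, SequenceStore,
                                 Transcript)
from polyagrammar.sites3p import PolyASite


@pytest.fixture(scope="module")
def toy_locus():
    """One plus-strand gene with two introns carrying canonical splice
    dinucleotides, on a random background."""
    rng = np.random.default_rng(71)
    chars = list("".join(rng.choice(list("ACGT"), size=3000)))
    # gene: exons [100,300) [500,800) [1100,1500)
    for intron in ((300, 500), (800, 1100)):
        chars[intron[0]:intron[0] + 2] = "GT"
        chars[intron[1] - 2:intron[1]] = "AG"
    genome = SequenceStore({"c": "".join(chars)})
    gene = Gene("g1", "c", "+", [Transcript(
        "g1.t", [Exon(100, 300), Exon(500, 800), Exon(1100, 1500)])])
    return genome, Annotation([gene])


def test_pwm_splice_scorer_prefers_real_sites(toy_locus):
    genome, annotation = toy_locus
    scorer = PWMSpliceScorer(genome, annotation)
    assert scorer.pwm5.shape == (9, 4)
    assert scorer.pwm3.shape == (23, 4)
    gene = annotation.get("g1")
    real = scorer.score_5ss(genome, gene, (300, 500))
    # a fake intron starting mid-exon lacks the GT and scores lower
    fake = scorer.score_5ss(genome, gene, (200, 500))
    assert real > fake


def test_find_host_intron_and_errors(toy_locus):
    _genome, annotation = toy_locus
    site = PolyASite("c", 400, "+")
    gene, tx, i = find_host_intron(site, annotation)
    assert gene.gene_id == "g1" and i == 0
    with pytest.raises(ValueError):
        find_host_intron(PolyASite("c", 200, "+"), annotation)  # exonic


def test_classify_intronic_type(toy_locus):
    _genome, annotation = toy_locus
    site = PolyASite("c", 400, "+")
    # no junction acceptor before the site -> composite
    assert classify_intronic_type(site, annotation, []) == "composite"
    # an acceptor used upstream of the site within the intron -> skipped
    assert classify_intronic_type(site, annotation,
                                  [(300, 380)]) == "skipped"
    # an acceptor downstream of the site does not change the call
    assert classify_intronic_type(site, annotation,
                                  [(300, 450)]) == "composite"


def test_compute_features_intronic(toy_locus):
    genome, annotation = toy_locus
    scorer = PWMSpliceScorer(genome, annotation)
    fv = compute_features(PolyASite("c", 400, "+"), annotation, genome,
                          scorer, site_type="composite", strength=-2.0)
    assert fv.dist_to_upstream_ss == 100       # 400 - 300
    assert fv.dist_to_downstream_ss == 100     # 500 - 400
    assert fv.upstream_exon_size == 200
    assert fv.downstream_exon_size == 300
    assert fv.intron_size == 200
    assert fv.is_last_intron == 0.0
    assert np.isfinite(fv.ss5_strength) and np.isfinite(fv.ss3_strength_down)
    # the feature dict exposes only the intronic feature set
    assert "pair_distance" not in fv.as_dict()
    last = compute_features(PolyASite("c", 900, "+"), annotation, genome,
                            scorer, site_type="composite")
    assert last.is_last_intron == 1.0


def test_compute_features_terminal_pair(toy_locus):
    genome, annotation = toy_locus
    fv = compute_features(PolyASite("c", 1300, "+"), annotation, genome,
                          site_type="terminal_pair", strength=1.5,
                          pair_distance=250.0,
                          relative_strength_vs_distal=0.7)
    d = fv.as_dict()
    assert d["pair_distance"] == 250.0
    assert d["last_intron_size"] == 300        # intron (800, 1100)
    assert d["relative_strength_vs_distal"] == 0.7
    assert "intron_size" not in d


def test_quantile_match_by_strength_balances_groups():
    rng = np.random.default_rng(2)
    used = rng.normal(1.0, 1.0, size=500)
    unused = rng.normal(-1.0, 1.0, size=500)
    iu, inu = quantile_match_by_strength(used, unused, seed=0)
    assert len(iu) == len(inu) > 0
    # matched subsets have much closer means than the raw groups
    raw_gap = abs(used.mean() - unused.mean())
    matched_gap = abs(used[iu].mean() - unused[inu].mean())
    assert matched_gap < 0.25 * raw_gap
    with pytest.raises(ValueError):
        quantile_match_by_strength(np.array([]), unused)


def test_fit_usage_classifier_prunes_noise_feature():
    rng = np.random.default_rng(6)
    n = 3000
    x = pd.DataFrame({"signal": rng.normal(size=n),
                      "noise": rng.normal(size=n)})
    logits = 1.5 * x.signal
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    clf = fit_usage_classifier(x, y, alpha=0.01)
    assert "signal" in clf.coefficients
    assert "noise" in clf.dropped and "noise" not in clf.coefficients
    assert clf.p_values["signal"] < 0.01
    # predicted probability responds in the fitted direction
    hi = predict_usage_probability(clf, {"signal": 2.0})
    lo = predict_usage_probability(clf, {"signal": -2.0})
    assert hi > 0.5 > lo


def test_fit_usage_classifier_perfect_separation_fallback(monkeypatch):
    import statsmodels.api as sm

    class ExplodingLogit:
        def __init__(self, *args, **kwargs):
            pass

        def fit(self, *args, **kwargs):
            raise np.linalg.LinAlgError("singular")

    monkeypatch.setattr(sm, "Logit", ExplodingLogit)
    x = pd.DataFrame({"f": np.concatenate([np.ones(50), -np.ones(50)])})
    y = np.concatenate([np.ones(50), np.zeros(50)])
    clf = fit_usage_classifier(x, y)
    assert clf.penalized
    assert clf.coefficients["f"] > 0
    assert np.isnan(clf.p_values["f"])


def test_log_distance():
    assert log_distance(0) == 0.0
    assert log_distance(99) == pytest.approx(2.0)


def _terminal_site(gene_id, pos, usage, strand="+"):
    s = PolyASite("c", pos, strand, gene_id=gene_id)
    s.usage = usage
    return s


def test_select_terminal_pairs_fold_rule_and_orientation():
    sites = [
        _terminal_site("gA", 100, 0.8), _terminal_site("gA", 400, 0.1),
        # gB: the partner misses the 8-fold requirement
        _terminal_site("gB", 100, 0.6), _terminal_site("gB", 300, 0.4),
        # gC: minus strand, strongest is 3'-most genomically (= proximal?)
        _terminal_site("gC", 150, 0.88, "-"), _terminal_site("gC", 500, 0.11, "-"),
        _terminal_site("gD", 200, 1.0),       # no partner at all
    ]
    pairs = select_terminal_pairs(sites, seed=0)
    by_gene = {p["gene_id"]: p for p in pairs}
    assert set(by_gene) == {"gA", "gC"}
    pa = by_gene["gA"]
    assert pa["proximal"].pos == 100 and pa["distal"].pos == 400
    assert pa["high_usage_is_proximal"]
    pc = by_gene["gC"]
    # minus strand: the smaller coordinate is the distal site
    assert pc["proximal"].pos == 500 and pc["distal"].pos == 150
    assert not pc["high_usage_is_proximal"]


def test_benjamini_hochberg_matches_reference():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(13)
    for _ in range(3):
        p = rng.random(97)
        ours = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, rtol=0, atol=1e-12)
    # monotone in the p-value ordering
    order = np.argsort(p)
    assert (np.diff(ours[order]) >= -1e-15).all()


def test_apa_differential_test_against_manual_fisher():
    counts = pd.DataFrame([
        {"gene_id": "g", "condition": "A", "proximal": 90, "distal": 10},
        {"gene_id": "g", "condition": "B", "proximal": 10, "distal": 90},
        {"gene_id": "h", "condition": "A", "proximal": 50, "distal": 50},
        {"gene_id": "h", "condition": "B", "proximal": 52, "distal": 48},
    ])
    result = apa_differential_test(counts)
    g_a = result[(result.gene_id == "g") & (result.condition == "A")].iloc[0]
    _odds, expected_p = stats.fisher_exact([[90, 10], [10, 90]])
    assert g_a.p_value == pytest.approx(expected_p)
    assert g_a.usage == pytest.approx(0.9)
    assert g_a.usage_change == pytest.approx(0.4)
    assert bool(g_a.significant)
    # the balanced gene shows no significant shift
    assert not result[result.gene_id == "h"].significant.any()
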