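"""Gene-structure features and logistic models of polyA-site usage.

Intronic sites are split into composite (no splicing between the upstream
5' splice site and the site) and skipped (spliced) types; independent
logistic regressions relate their usage to site strength and surrounding
gene structure.  Terminal-exon site pairs (strongest site vs a ≥8-fold
weaker partner) feed a third model of proximal/distal usage.  Splice-site
strengths come from a pluggable scorer, by default position-weight-matrix
log-odds trained on the annotation's own splice sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Annotation, SequenceStore, revcomp

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Splice-site scoring
# --------------------------------------------------------------------------

class PWMSpliceScorer:
    """Log-odds position-weight-matrix splice-site scorer.

    Windows follow the usual maximum-entropy-model conventions: 9 nt for the
    5'SS (last 3 exonic + first 6 intronic bases) and 23 nt for the 3'SS
    (last 20 intronic + first 3 exonic).  Matrices are trained from every
    intron in the annotation with a pseudocount of 1.
    """

    def __init__(self, genome: SequenceStore, annotation: Annotation):
        five, three = [], []
        for gene in annotation:
            for tx in gene.transcripts:
                for intron in tx.introns():
                    s5 = self._window_5ss(genome, gene, intron)
                    s3 = self._window_3ss(genome, gene, intron)
                    if s5:
                        five.append(s5)
                    if s3:
                        three.append(s3)
        self.pwm5 = self._train(five, 9)
        self.pwm3 = self._train(three, 23)

    @staticmethod
    def _train(seqs: list[str], width: int) -> np.ndarray:
        counts = np.ones((width, 4))
        index = {b: i for i, b in enumerate("ACGT")}
        for seq in seqs:
            for j, base in enumerate(seq):
                if base in index:
                    counts[j, index[base]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        return np.log2(freqs / 0.25)

    @staticmethod
    def _fetch(genome, gene, start, end):
        try:
            seq = genome.fetch(gene.chrom, start, end)
        except IndexError:
            return None
        return revcomp(seq) if gene.strand == "-" else seq

    def _window_5ss(self, genome, gene, intron):
        if gene.strand == "+":
            return self._fetch(genome, gene, intron[0] - 3, intron[0] + 6)
        return self._fetch(genome, gene, intron[1] - 6, intron[1] + 3)

    def _window_3ss(self, genome, gene, intron):
        if gene.strand == "+":
            return self._fetch(genome, gene, intron[1] - 20, intron[1] + 3)
        return self._fetch(genome, gene, intron[0] - 3, intron[0] + 20)

    @staticmethod
    def _score(pwm: np.ndarray, seq: str) -> float:
        index = {b: i for i, b in enumerate("ACGT")}
        return float(sum(pwm[j, index[b]] for j, b in enumerate(seq)
                         if b in index))

    def score_5ss(self, genome, gene, intron) -> float:
        seq = self._window_5ss(genome, gene, intron)
        return self._score(self.pwm5, seq) if seq else float("nan")

    def score_3ss(self, genome, gene, intron) -> float:
        seq = self._window_3ss(genome, gene, intron)
        return self._score(self.pwm3, seq) if seq else float("nan")


# --------------------------------------------------------------------------
# Site typing and features
# --------------------------------------------------------------------------

def find_host_intron(site, annotation: Annotation):
    """(gene, transcript, intron index) of the intron containing the site."""
    for gene in annotation.genes_on(site.chrom, site.strand):
        for tx in gene.transcripts:
            for i, intron in enumerate(tx.introns()):
                if intron[0] <= site.pos < intron[1]:
                    return gene, tx, i
    raise ValueError(f"site {site.chrom}:{site.pos} is not intronic")


def classify_intronic_type(site, annotation: Annotation,
                           junctions: list[tuple[int, int]]) -> str:
    """'skipped' when a used 3' splice site (junction acceptor) lies between
    the host intron's 5'SS and the site, else 'composite'.

    ``junctions`` holds (donor, acceptor) genomic positions of observed
    splicing events, donor at the intron's 5' end in transcript orientation.
    """
    gene, tx, i = find_host_intron(site, annotation)
    intron = tx.introns()[i]
    for _donor, acceptor in junctions:
        if gene.strand == "+":
            if intron[0] <= acceptor < site.pos:
                return "skipped"
        else:
            if site.pos < acceptor <= intron[1] - 1:
                return "skipped"
    return "composite"


@dataclass
class ContextFeatureVector:
    site_type: str  # composite | skipped | terminal_pair
    polyastrength: float = float("nan")
    dist_to_upstream_ss: float = float("nan")
    dist_to_downstream_ss: float = float("nan")
    ss5_strength: float = float("nan")
    ss3_strength_up: float = float("nan")
    ss3_strength_down: float = float("nan")
    upstream_exon_size: float = float("nan")
    downstream_exon_size: float = float("nan")
    intron_size: float = float("nan")
    is_last_intron: float = float("nan")
    pair_distance: float = float("nan")
    last_intron_size: float = float("nan")
    dist_to_downstream_antisense_gene: float = float("nan")
    relative_strength_vs_distal: float = float("nan")

    def as_dict(self) -> dict:
        intronic = ("polyastrength", "dist_to_upstream_ss",
                    "dist_to_downstream_ss", "ss5_strength",
                    "ss3_strength_up", "ss3_strength_down",
                    "upstream_exon_size", "downstream_exon_size",
                    "intron_size", "is_last_intron")
        terminal = ("polyastrength", "pair_distance", "last_intron_size",
                    "dist_to_downstream_antisense_gene",
                    "relative_strength_vs_distal")
        names = terminal if self.site_type == "terminal_pair" else intronic
        return {k: getattr(self, k) for k in names}


def compute_features(site, annotation: Annotation, genome: SequenceStore,
                     scorer: PWMSpliceScorer | None = None,
                     site_type: str = "composite",
                     strength: float = float("nan"),
                     pair_distance: float = float("nan"),
                     relative_strength_vs_distal: float = float("nan")
                     ) -> ContextFeatureVector:
    """Gene-structure features for one site; distances in nt on the sense
    strand."""
    if site_type == "terminal_pair":
        gene = None
        for g in annotation.genes_on(site.chrom, site.strand):
            if g.start <= site.pos < g.end:
                gene = g
                break
        if gene is None:
            raise ValueError("terminal site not inside any gene")
        tx = max(gene.transcripts, key=lambda t: len(t.exons))
        introns = tx.introns()
        last_intron = (introns[-1] if gene.strand == "+" else introns[0]) \
            if introns else None
        anti = annotation.next_antisense_gene_distance(gene)
        return ContextFeatureVector(
            site_type="terminal_pair", polyastrength=strength,
            pair_distance=pair_distance,
            last_intron_size=(last_intron[1] - last_intron[0])
            if last_intron else 0.0,
            dist_to_downstream_antisense_gene=float("nan") if anti is None else anti,
            relative_strength_vs_distal=relative_strength_vs_distal)

    gene, tx, i = find_host_intron(site, annotation)
    introns = tx.introns()
    intron = introns[i]
    exons = tx.exons
    if gene.strand == "+":
        dist_up = site.pos - intron[0]
        dist_down = intron[1] - site.pos
        up_exon, down_exon = exons[i], exons[i + 1]
        prev_intron = introns[i - 1] if i > 0 else None
        is_last = i == len(introns) - 1
    else:
        dist_up = intron[1] - 1 - site.pos
        dist_down = site.pos - intron[0] + 1
        up_exon, down_exon = exons[i + 1], exons[i]
        prev_intron = introns[i + 1] if i + 1 < len(introns) else None
        is_last = i == 0
    scorer = scorer or PWMSpliceScorer(genome, annotation)
    return ContextFeatureVector(
        site_type=site_type, polyastrength=strength,
        dist_to_upstream_ss=dist_up, dist_to_downstream_ss=dist_down,
        ss5_strength=scorer.score_5ss(genome, gene, intron),
        ss3_strength_up=(scorer.score_3ss(genome, gene, prev_intron)
                         if prev_intron else float("nan")),
        ss3_strength_down=scorer.score_3ss(genome, gene, intron),
        upstream_exon_size=up_exon.end - up_exon.start,
        downstream_exon_size=down_exon.end - down_exon.start,
        intron_size=intron[1] - intron[0],
        is_last_intron=float(is_last))


# --------------------------------------------------------------------------
# Quantile matching and logistic models
# --------------------------------------------------------------------------

def quantile_match_by_strength(used: np.ndarray, unused: np.ndarray,
                               n_bins: int = 10, seed: int = 0):
    """Sample equal numbers of used/unused sites per strength bin.

    ``used`` and ``unused`` are strength arrays; bins are quantiles of the
    pooled strengths; each bin contributes min(count_used, count_unused)
    samples from both groups.  Returns (used_indices, unused_indices).
    """
    if len(used) == 0 or len(unused) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([used, unused])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    used_bins = np.digitize(used, edges[1:-1])
    unused_bins = np.digitize(unused, edges[1:-1])
    used_idx, unused_idx = [], []
    for b in range(n_bins):
        iu = np.flatnonzero(used_bins == b)
        inu = np.flatnonzero(unused_bins == b)
        take = min(len(iu), len(inu))
        if take == 0:
            if len(iu) or len(inu):
                logger.warning("strength bin %d empty on one side; contributes 0", b)
            continue
        used_idx.extend(rng.choice(iu, size=take, replace=False))
        unused_idx.extend(rng.choice(inu, size=take, replace=False))
    return np.array(sorted(used_idx)), np.array(sorted(unused_idx))


@dataclass
class UsageClassifier:
    coefficients: dict
    intercept: float
    feature_scaling: dict          # name -> (mean, std)
    p_values: dict
    penalized: bool = False
    dropped: list = field(default_factory=list)


def fit_usage_classifier(features: pd.DataFrame, labels: np.ndarray,
                         alpha: float = 0.05,
                         max_rounds: int = 5) -> UsageClassifier:
    """Maximum-likelihood logistic regression with Wald-test pruning.

    Features are standardised; coefficients with two-sided p ≥ ``alpha``
    are dropped and the model refit until all survivors are significant.
    Perfect separation falls back to an L2-penalised fit (flagged, p-values
    unavailable).
    """
    import statsmodels.api as sm

    features = features.astype(float)
    scaling = {c: (features[c].mean(), features[c].std(ddof=0) or 1.0)
               for c in features.columns}
    z = (features - [scaling[c][0] for c in features.columns]) \
        / [scaling[c][1] for c in features.columns]
    y = np.asarray(labels, dtype=float)
    cols = list(z.columns)
    dropped = []
    for _round in range(max_rounds):
        X = sm.add_constant(z[cols], has_constant="add")
        try:
            with np.errstate(all="ignore"):
                result = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(result.bse)):
                raise ValueError("non-finite standard errors")
        except Exception as exc:  # perfect separation or non-convergence
            logger.warning("ML logistic fit failed (%s); penalised fallback", exc)
            from sklearn.linear_model import LogisticRegression

            clf = LogisticRegression(C=1.0, max_iter=1000)
            clf.fit(z[cols].values, y)
            return UsageClassifier(
                dict(zip(cols, clf.coef_[0])), float(clf.intercept_[0]),
                scaling, {c: float("nan") for c in cols}, penalized=True,
                dropped=dropped)
        pvals = result.pvalues.drop("const")
        weak = pvals[pvals >= alpha]
        if weak.empty or len(cols) == 1:
            return UsageClassifier(
                {c: float(result.params[c]) for c in cols},
                float(result.params["const"]), scaling,
                {c: float(pvals[c]) for c in cols}, dropped=dropped)
        worst = weak.idxmax()
        cols.remove(worst)
        dropped.append(worst)
    raise RuntimeError("feature pruning did not converge")


def predict_usage_probability(clf: UsageClassifier, feature_vector: dict) -> float:
    """Calibrated probability that the site is used, from a raw feature dict."""
    z = clf.intercept
    for name, coef in clf.coefficients.items():
        mean, std = clf.feature_scaling[name]
        z += coef * (float(feature_vector[name]) - mean) / std
    return float(1.0 / (1.0 + np.exp(-z)))


def log_distance(x) -> float:
    """log10(x+1) transform used for distance features before scaling."""
    return float(np.log10(np.asarray(x, dtype=float) + 1.0))


# --------------------------------------------------------------------------
# Terminal pairs and APA differential usage
# --------------------------------------------------------------------------

def select_terminal_pairs(gene_sites: list, min_fold: float = 8.0,
                          seed: int = 0) -> list[dict]:
    """Strongest terminal-exonic site per gene paired with a random ≥8-fold
    weaker partner; labelled by which member (proximal/distal in sense
    orientation) is the high-usage one.  Genes without a qualifying partner
    are skipped."""
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list] = {}
    for site in gene_sites:
        by_gene.setdefault(site.gene_id, []).append(site)
    pairs = []
    for gene_id in sorted(by_gene):
        sites = by_gene[gene_id]
        if len(sites) < 2:
            continue
        strongest = max(sites, key=lambda s: s.usage)
        partners = [s for s in sites if s is not strongest
                    and s.usage > 0 and strongest.usage / s.usage >= min_fold]
        if not partners:
            continue
        partner = partners[int(rng.integers(len(partners)))]
        first, second = sorted([strongest, partner], key=lambda s: s.pos)
        if strongest.strand == "-":
            proximal, distal = second, first
        else:
            proximal, distal = first, second
        pairs.append({"gene_id": gene_id, "proximal": proximal,
                      "distal": distal,
                      "high_usage_is_proximal": proximal is strongest})
    return pairs


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running_min = min(running_min, p[idx] * n / (rank + 1))
        adjusted[idx] = running_min
    return adjusted


def apa_differential_test(counts: pd.DataFrame, alpha: float = 0.05,
                          min_usage_change: float = 0.1) -> pd.DataFrame:
    """Per-gene, per-condition Fisher exact test of proximal vs distal usage.

    ``counts`` needs columns gene_id, condition, proximal, distal.  Each
    condition is compared against the pooled remaining conditions; p-values
    are BH-adjusted across all tests, and a call is significant when the
    adjusted p < ``alpha`` and the usage deviates from the gene's mean by at
    least ``min_usage_change``.  Genes with an all-zero margin are skipped.
    """
    rows = []
    for gene_id, sub in counts.groupby("gene_id"):
        total_p, total_d = sub.proximal.sum(), sub.distal.sum()
        if total_p + total_d == 0 or len(sub) < 2:
            continue
        usages = sub.proximal / (sub.proximal + sub.distal).replace(0, np.nan)
        mean_usage = usages.mean()
        for row, usage in zip(sub.itertuples(index=False), usages):
            rest_p = total_p - row.proximal
            rest_d = total_d - row.distal
            table = [[row.proximal, row.distal], [rest_p, rest_d]]
            if min(map(sum, table)) == 0 or min(map(sum, zip(*table))) == 0:
                continue
            _odds, p = stats.fisher_exact(table)
            rows.append({"gene_id": gene_id, "condition": row.condition,
                         "proximal": row.proximal, "distal": row.distal,
                         "usage": float(usage) if np.isfinite(usage) else np.nan,
                         "usage_change": float(usage - mean_usage),
                         "p_value": float(p)})
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["p_adjusted"] = benjamini_hochberg(result["p_value"].values)
    result["significant"] = ((result.p_adjusted < alpha)
                             & (result.usage_change.abs() >= min_usage_change))
    return result
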