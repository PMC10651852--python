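"""Training examples for the PolyaID and PolyaStrength models.

Positives are 240-nt windows anchored at every shift in −25..+25 around a
called site, labelled with the read-derived cleavage probability vector
re-centred on the shifted anchor.  Negatives are intergenic, shuffled
transcript, or site-neighbouring sequences, all labelled class 0 with the
constant background cleavage vector 0.02.  Usage labels follow the log2-odds
of a site's reads against the top-two expressed sites of its gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genome import (CLEAVAGE_HALF, CLEAVAGE_LENGTH, SequenceStore,
                     WINDOW_LENGTH, extract_window, revcomp)
from .sites3p import PolyASite

logger = logging.getLogger(__name__)

BACKGROUND = 0.02
BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class SequenceWindow:
    """A 240-nt sense-orientation window; offsets −120..+119 around its anchor."""

    seq: str
    chrom: str | None = None
    anchor_pos: int | None = None
    strand: str = "+"

    def __post_init__(self):
        if len(self.seq) != WINDOW_LENGTH:
            raise ValueError(f"window length {len(self.seq)} != {WINDOW_LENGTH}")
        if set(self.seq) - set("ACGTN"):
            raise ValueError("window alphabet must be within ACGTN")


@dataclass
class TrainingExample:
    window: SequenceWindow
    label_class: int
    label_cleavage: np.ndarray
    origin: str                    # positive_shifted | neg_intergenic | neg_shuffled | neg_neighbor
    site_id: str | None = None     # grouping key for site-level splits


@dataclass
class UsageRecord:
    site: PolyASite | None
    n_i: float
    n_top: float
    n_second: float
    u_i: float
    o_i: float


def one_hot(window: SequenceWindow | str) -> np.ndarray:
    """(4, 240) one-hot matrix, rows A,C,G,T; N gives an all-zero column."""
    seq = window.seq if isinstance(window, SequenceWindow) else window
    if len(seq) != WINDOW_LENGTH:
        raise ValueError("one_hot expects a 240-nt sequence")
    mat = np.zeros((4, WINDOW_LENGTH), dtype=np.float32)
    for j, base in enumerate(seq):
        idx = _BASE_INDEX.get(base)
        if idx is not None:
            mat[idx, j] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        out.append("N" if col.sum() == 0 else BASE_ORDER[int(col.argmax())])
    return "".join(out)


def cleavage_vector_from_reads(read_positions: dict[int, int], anchor: int,
                               strand: str) -> np.ndarray:
    """Length-50 probability vector of read 3'-ends at offsets −25..+24 from
    ``anchor``; reads outside the window are dropped before normalising."""
    vec = np.zeros(CLEAVAGE_LENGTH, dtype=np.float64)
    for pos, count in read_positions.items():
        offset = pos - anchor if strand == "+" else anchor - pos
        idx = offset + CLEAVAGE_HALF
        if 0 <= idx < CLEAVAGE_LENGTH:
            vec[idx] += count
    total = vec.sum()
    if total > 0:
        vec /= total
    return vec


def build_positive_examples(site: PolyASite, genome: SequenceStore,
                            max_shift: int = 25,
                            max_n_frac: float = 0.1) -> list[TrainingExample]:
    """One example per anchor shift in −max_shift..+max_shift (51 windows).

    Each shifted window is labelled with the site's read distribution
    re-centred on the shifted anchor and renormalised.  Windows running off
    the chromosome (or with too many Ns) are skipped.
    """
    examples = []
    for shift in range(-max_shift, max_shift + 1):
        anchor = site.pos + shift if site.strand == "+" else site.pos - shift
        try:
            seq = extract_window(genome, site.chrom, anchor, site.strand)
        except IndexError:
            logger.info("site %s shift %+d window off-chromosome, skipped",
                        site.site_id, shift)
            continue
        if seq.count("N") > max_n_frac * WINDOW_LENGTH:
            continue
        vec = cleavage_vector_from_reads(site.read_positions, anchor, site.strand)
        if vec.sum() == 0:
            continue
        window = SequenceWindow(seq, site.chrom, anchor, site.strand)
        examples.append(TrainingExample(window, 1, vec, "positive_shifted",
                                        site_id=site.site_id))
    return examples


def _shuffle_seq(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def build_negative_examples(genome: SequenceStore, transcripts: list[str],
                            sites: list[PolyASite],
                            coverage: dict[tuple[str, str], dict[int, int]],
                            n_per_origin: int | dict[str, int] = 1000,
                            intergenic_regions: list[tuple[str, int, int]] | None = None,
                            neighbor_band: tuple[int, int] = (50, 100),
                            rng: np.random.Generator | None = None) -> list[TrainingExample]:
    """Negatives of three origins, labelled class 0 / constant 0.02 vector.

    - ``neg_intergenic``: windows drawn from ``intergenic_regions``
    - ``neg_shuffled``: shuffled 240-nt stretches of transcript sequence
    - ``neg_neighbor``: windows anchored 50–100 nt from a called site whose
      central 50 nt contain no PASS read (``coverage`` maps (chrom, strand)
      to position->read count)

    When the neighbour pool is exhausted the remaining quota is rebalanced
    onto the other two origins with a warning.
    """
    rng = rng or np.random.default_rng()
    if isinstance(n_per_origin, int):
        quota = {"neg_intergenic": n_per_origin, "neg_shuffled": n_per_origin,
                 "neg_neighbor": n_per_origin}
    else:
        quota = dict(n_per_origin)
    const = np.full(CLEAVAGE_LENGTH, BACKGROUND, dtype=np.float64)
    examples: list[TrainingExample] = []

    def add(seq, origin, tag):
        if seq.count("N") > 0.1 * WINDOW_LENGTH:
            return False
        examples.append(TrainingExample(SequenceWindow(seq), 0, const.copy(),
                                        origin, site_id=tag))
        return True

    # neighbours first so a shortfall can be rebalanced
    lo, hi = neighbor_band
    neighbor_added = 0
    candidates = []
    for site in sites:
        for dist in range(lo, hi + 1):
            for sign in (+1, -1):
                candidates.append((site, sign * dist))
    order = rng.permutation(len(candidates))
    for idx in order:
        if neighbor_added >= quota.get("neg_neighbor", 0):
            break
        site, delta = candidates[idx]
        anchor = site.pos + delta if site.strand == "+" else site.pos - delta
        cov = coverage.get((site.chrom, site.strand), {})
        centre = range(anchor - CLEAVAGE_HALF, anchor + CLEAVAGE_HALF)
        if site.strand == "-":
            centre = range(anchor - CLEAVAGE_HALF + 1, anchor + CLEAVAGE_HALF + 1)
        if any(cov.get(p, 0) > 0 for p in centre):
            continue
        try:
            seq = extract_window(genome, site.chrom, anchor, site.strand)
        except IndexError:
            continue
        if add(seq, "neg_neighbor", f"nn:{site.chrom}:{anchor}:{site.strand}"):
            neighbor_added += 1
    shortfall = quota.get("neg_neighbor", 0) - neighbor_added
    if shortfall > 0:
        logger.warning("neighbor pool exhausted (%d short); rebalancing", shortfall)
        quota["neg_intergenic"] = quota.get("neg_intergenic", 0) + shortfall // 2
        quota["neg_shuffled"] = (quota.get("neg_shuffled", 0) + shortfall
                                 - shortfall // 2)

    regions = intergenic_regions or []
    n_added = 0
    attempts = 0
    while n_added < quota.get("neg_intergenic", 0) and regions and attempts < 50 * quota["neg_intergenic"]:
        attempts += 1
        chrom, start, end = regions[rng.integers(len(regions))]
        if end - start < WINDOW_LENGTH:
            continue
        s = int(rng.integers(start, end - WINDOW_LENGTH + 1))
        seq = genome.fetch(chrom, s, s + WINDOW_LENGTH)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if add(seq, "neg_intergenic", f"ni:{chrom}:{s}"):
            n_added += 1

    n_added = 0
    attempts = 0
    usable = [t for t in transcripts if len(t) >= WINDOW_LENGTH]
    while n_added < quota.get("neg_shuffled", 0) and usable and attempts < 50 * quota["neg_shuffled"]:
        attempts += 1
        t = usable[rng.integers(len(usable))]
        s = int(rng.integers(0, len(t) - WINDOW_LENGTH + 1))
        seq = _shuffle_seq(t[s:s + WINDOW_LENGTH], rng)
        if add(seq, "neg_shuffled", f"ns:{attempts}"):
            n_added += 1
    return examples


def usage_logodds(n_i: float, n_top: float, n_second: float,
                  site: PolyASite | None = None,
                  pseudocount: float = 0.5) -> UsageRecord:
    """Relative usage u = n_i/(n_top + n_second) and its log2-odds.

    Degenerate ratios (u of exactly 0 or 1) receive a ``pseudocount`` of
    reads before the log-odds so the transform stays finite.
    """
    if n_top < n_second or n_second < 0:
        raise ValueError("require n_top >= n_second >= 0")
    denom = n_top + n_second
    if denom <= 0:
        raise ValueError("n_top + n_second must be positive")
    u = n_i / denom
    u_adj = u
    if u <= 0.0:
        u_adj = pseudocount / (denom + pseudocount)
    elif u >= 1.0:
        u_adj = n_i / (n_i + pseudocount)
    o = math.log2(u_adj / (1.0 - u_adj))
    return UsageRecord(site, n_i, n_top, n_second, u, o)


def split_dataset(examples: list[TrainingExample],
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0):
    """Site-level train/validation/test partition with class balance.

    All shifted windows of a site travel together; positive and negative
    groups are partitioned separately so each split keeps the class ratio.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    splits = ([], [], [])
    for label in (1, 0):
        groups: dict[str, list[TrainingExample]] = {}
        for ex in (e for e in examples if e.label_class == label):
            groups.setdefault(ex.site_id or id(ex), []).append(ex)
        keys = sorted(groups)
        rng.shuffle(keys)
        n = len(keys)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        cut = [keys[:n_train], keys[n_train:n_train + n_val],
               keys[n_train + n_val:]]
        for bucket, part in zip(splits, cut):
            for key in part:
                bucket.extend(groups[key])
    return splits


def write_dataset(examples: list[TrainingExample], path,
                  manifest_extra: dict | None = None) -> None:
    """Gzip TSV of examples (sequence string + labels) with a JSON sidecar
    manifest recording counts per origin; extra keys (seed, fractions, ...)
    may be merged in via ``manifest_extra``."""
    import gzip
    import json
    from collections import Counter
    from pathlib import Path

    path = Path(path)
    with gzip.open(path, "wt") as fh:
        fh.write("seq\tlabel_class\tcleavage\torigin\tsite_id\n")
        for ex in examples:
            vec = ",".join(f"{v:.8g}" for v in ex.label_cleavage)
            fh.write(f"{ex.window.seq}\t{ex.label_class}\t{vec}\t"
                     f"{ex.origin}\t{ex.site_id or ''}\n")
    manifest = {"n_examples": len(examples),
                "counts_per_origin": dict(Counter(e.origin for e in examples))}
    manifest.update(manifest_extra or {})
    Path(f"{path}.manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(path) -> list[TrainingExample]:
    """Inverse of :func:`write_dataset`."""
    import gzip

    examples = []
    with gzip.open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("seq\t"):
            raise ValueError("not a polyagrammar dataset file")
        for line in fh:
            seq, label, vec, origin, site_id = line.rstrip("\n").split("\t")
            examples.append(TrainingExample(
                SequenceWindow(seq), int(label),
                np.array([float(v) for v in vec.split(",")]),
                origin, site_id=site_id or None))
    return examples


def to_arrays(examples: list[TrainingExample]):
    """Stack examples into (X, y, cleavage) arrays for the trainer."""
    x = np.stack([one_hot(e.window) for e in examples])
    y = np.array([e.label_class for e in examples], dtype=np.float64)
    c = np.stack([e.label_cleavage for e in examples])
    return x, y, c
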