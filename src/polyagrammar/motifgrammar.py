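"""Hexamer-disruption importance, motif families, and cleavage entropy.

Importance of a hexamer occurrence is measured by replacing it with random
hexamers (100 draws by default) and taking the median change in the model's
log-odds output (classification log-odds for PolyaID, raw score for
PolyaStrength).  Positional profiles aggregate −Δlog-odds over
well-expressed sites for hexamer starts −120..+114; flanking positions
(|offset| > 40) provide the null whose 99.99th percentile acts as the
false-discovery threshold.  Cleavage heterogeneity is the Shannon entropy
of the 50-long cleavage vector (natural log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import WINDOW_HALF, WINDOW_LENGTH
from .trainset import one_hot

logger = logging.getLogger(__name__)

N_POSITIONS = WINDOW_LENGTH - 6 + 1        # hexamer starts 0..234
POSITION_OFFSETS = np.arange(N_POSITIONS) - WINDOW_HALF   # −120..+114

# AAUAAA plus the twelve common single-nucleotide PAS variants (DNA alphabet).
# This packaged table is editable by passing a custom list where needed.
PAS_HEXAMERS = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AATATA", "AATACA", "CATAAA",
    "GATAAA", "AATGAA", "TTTAAA", "ACTAAA", "AATAGA", "AAGAAA",
)
GU_CU_CORES = ("GTGT", "TGTG", "GTCT", "TGTC", "CTGT", "TCTG")


@dataclass(frozen=True)
class MotifFamily:
    name: str  # PAS_AAUAAA | PAS_variant | UGUA | U_rich | GU_CU_rich | G_rich | none


@dataclass
class ImportanceRecord:
    hexamer: str
    position: int                 # hexamer start offset, −120..+114
    delta_logodds_id: float | None = None
    delta_logodds_strength: float | None = None
    n_occurrences: int = 1


@dataclass
class EntropyRecord:
    site_id: str
    entropy_observed: float
    entropy_predicted: float
    group: str  # low | high | middle


def classify_motif_family(hexamer: str) -> MotifFamily:
    """Deterministic family assignment with precedence
    PAS > UGUA-containing > GU/CU-rich > U-rich > G-rich > none."""
    if len(hexamer) != 6 or set(hexamer) - set("ACGT"):
        raise ValueError(f"not an ACGT hexamer: {hexamer!r}")
    if hexamer == "AATAAA":
        return MotifFamily("PAS_AAUAAA")
    if hexamer in PAS_HEXAMERS:
        return MotifFamily("PAS_variant")
    if "TGTA" in hexamer:
        return MotifFamily("UGUA")
    if any(core in hexamer for core in GU_CU_CORES):
        return MotifFamily("GU_CU_rich")
    if hexamer.count("T") >= 5 and hexamer[0] == "T":
        return MotifFamily("U_rich")
    if hexamer.count("G") >= 5 and hexamer[0] == "G":
        return MotifFamily("G_rich")
    return MotifFamily("none")


def cleavage_entropy(v: np.ndarray) -> float:
    """Shannon entropy −Σ p·ln p of a cleavage vector; 0·ln 0 := 0."""
    v = np.asarray(v, dtype=np.float64)
    total = v.sum()
    if total > 0 and abs(total - 1.0) > 1e-9:
        v = v / total
    nz = v[v > 0]
    return float(-(nz * np.log(nz)).sum())


# --------------------------------------------------------------------------
# Hexamer disruption
# --------------------------------------------------------------------------

def _model_logodds(model, x: np.ndarray) -> np.ndarray:
    """PolyaID: log-odds of p_class; PolyaStrength: the raw score."""
    out = model.predict(x)
    if isinstance(out, tuple):
        p = np.clip(out[0], 1e-7, 1 - 1e-7)
        return np.log(p / (1 - p))
    return out


def random_replacement_hexamers(n_repl: int, seed: int) -> list[str]:
    """The shared pool of random replacement hexamers (uniform over 4^6)."""
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=(n_repl, 6))
    return ["".join("ACGT"[b] for b in row) for row in draws]


def hexamer_importance(window, model, n_repl: int = 100, seed: int = 0,
                       positions: list[int] | None = None,
                       batch_size: int = 4096) -> list[ImportanceRecord]:
    """Median Δlog-odds from replacing each hexamer occurrence ``n_repl``
    times with random hexamers (the same pool reused across positions).

    ``window`` is a 240-nt sequence (or SequenceWindow); ``positions``
    restricts the hexamer start indices scanned (default all 0..234).
    Δ = log-odds(modified) − log-odds(original), so destructive motifs get
    negative medians.
    """
    seq = window.seq if hasattr(window, "seq") else window
    if len(seq) != WINDOW_LENGTH:
        raise ValueError("window must be 240 nt")
    replacements = random_replacement_hexamers(n_repl, seed)
    starts = list(range(N_POSITIONS)) if positions is None else list(positions)
    base = _model_logodds(model, one_hot(seq)[None])[0]
    records = []
    variants = []
    for start in starts:
        for repl in replacements:
            variants.append((start, seq[:start] + repl + seq[start + 6:]))
    deltas = np.empty(len(variants))
    for lo in range(0, len(variants), batch_size):
        chunk = variants[lo:lo + batch_size]
        x = np.stack([one_hot(s) for _p, s in chunk])
        deltas[lo:lo + len(chunk)] = _model_logodds(model, x) - base
    for i, start in enumerate(starts):
        med = float(np.median(deltas[i * n_repl:(i + 1) * n_repl]))
        records.append(ImportanceRecord(seq[start:start + 6],
                                        start - WINDOW_HALF, med))
    return records


def positional_profile(windows: list, polyaid=None, polyastrength=None,
                       n_repl: int = 100, seed: int = 0) -> pd.DataFrame:
    """Aggregate hexamer importance over a cohort of site windows.

    Windows should come from well-expressed sites (the genome-wide analysis
    restricts to ≥100 PASS reads and usage ≥5%).  Returns a frame indexed by
    (hexamer, position) with sum and per-site importance — the sum of
    −Δlog-odds and that sum divided by the occurrence count — for each model
    supplied.
    """
    acc: dict[tuple[str, int], dict] = {}
    for label, model in (("id", polyaid), ("strength", polyastrength)):
        if model is None:
            continue
        for window in windows:
            for rec in hexamer_importance(window, model, n_repl=n_repl, seed=seed):
                key = (rec.hexamer, rec.position)
                entry = acc.setdefault(key, {"sum_id": 0.0, "sum_strength": 0.0,
                                             "n_id": 0, "n_strength": 0})
                entry[f"sum_{label}"] += -rec.delta_logodds_id
                entry[f"n_{label}"] += 1
    rows = []
    for (hexamer, position), entry in acc.items():
        row = {"hexamer": hexamer, "position": position}
        for label in ("id", "strength"):
            n = entry[f"n_{label}"]
            row[f"sum_{label}"] = entry[f"sum_{label}"] if n else np.nan
            row[f"per_site_{label}"] = entry[f"sum_{label}"] / n if n else np.nan
            row[f"n_{label}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def significant_hexamers(profile: pd.DataFrame, window: int = 40,
                         flank: int = 40,
                         percentile: float = 99.99) -> set[tuple[str, int]]:
    """Hexamer × 40-nt-window calls exceeding the flank-null threshold.

    The background pools the per-position sum scores at |position| >
    ``flank`` for each model; a hexamer is called in a window when its
    windowed sum strictly exceeds the 99.99th percentile of that model's
    background (either model suffices).  Returns (hexamer, window_start)
    pairs with window_start the 5'-most position of the 40-nt window.
    """
    calls: set[tuple[str, int]] = set()
    for label in ("id", "strength"):
        col = f"sum_{label}"
        if col not in profile or profile[col].dropna().empty:
            continue
        flank_vals = profile.loc[profile.position.abs() > flank, col].dropna()
        if flank_vals.empty:
            raise ValueError("empty background: no positions beyond the flank")
        threshold = float(np.percentile(flank_vals, percentile))
        for hexamer, sub in profile.dropna(subset=[col]).groupby("hexamer"):
            series = dict(zip(sub.position, sub[col]))
            positions = sorted(series)
            for start in positions:
                total = sum(series.get(p, 0.0)
                            for p in range(start, start + window))
                if total > threshold:
                    calls.add((hexamer, start))
    return calls


# --------------------------------------------------------------------------
# Entropy groups and motif mechanics
# --------------------------------------------------------------------------

SUBREGIONS = ((-120, -31), (-30, 0), (1, 30), (31, 120))


def _count_motif_in_subregion(seq: str, family: str, lo: int, hi: int) -> int:
    """Occurrences of a motif family with hexamer start offsets in the
    closed interval [lo, hi]."""
    n = 0
    for off in range(lo, hi + 1):
        idx = off + WINDOW_HALF
        if 0 <= idx <= WINDOW_LENGTH - 6:
            hexamer = seq[idx:idx + 6]
            if "N" not in hexamer and classify_motif_family(hexamer).name == family:
                n += 1
    return n


def entropy_group_analysis(site_ids: list[str], observed: np.ndarray,
                           predicted: np.ndarray, windows: list[str],
                           families: tuple[str, ...] = ("PAS_AAUAAA", "U_rich",
                                                        "GU_CU_rich"),
                           quantile: float = 0.2):
    """Partition sites into low/high entropy groups and test motif
    composition differences per subregion.

    Groups are the intersections of the bottom (resp. top) ``quantile`` of
    entropy under both the observed (read-derived) and predicted vectors.
    For each subregion and motif family a chi-squared test on the
    with/without-motif 2×2 table and a two-proportion z-test are reported.
    Tests are skipped when a group has fewer than two sites.
    """
    from statsmodels.stats.proportion import proportions_ztest

    e_obs = np.array([cleavage_entropy(v) for v in observed])
    e_pred = np.array([cleavage_entropy(v) for v in predicted])
    records = []
    if np.ptp(e_obs) < 1e-12 and np.ptp(e_pred) < 1e-12:
        groups = np.array(["middle"] * len(site_ids))
    else:
        lo_o, hi_o = np.quantile(e_obs, [quantile, 1 - quantile])
        lo_p, hi_p = np.quantile(e_pred, [quantile, 1 - quantile])
        groups = np.where((e_obs <= lo_o) & (e_pred <= lo_p), "low",
                          np.where((e_obs >= hi_o) & (e_pred >= hi_p),
                                   "high", "middle"))
        # degenerate spread puts everything in both tails; call that middle
        if np.all(groups == "low") or np.all(groups == "high"):
            groups = np.array(["middle"] * len(site_ids))
    for sid, eo, ep, grp in zip(site_ids, e_obs, e_pred, groups):
        records.append(EntropyRecord(sid, float(eo), float(ep), str(grp)))

    low_idx = [i for i, g in enumerate(groups) if g == "low"]
    high_idx = [i for i, g in enumerate(groups) if g == "high"]
    tests = []
    if len(low_idx) >= 2 and len(high_idx) >= 2:
        for (lo, hi) in SUBREGIONS:
            for family in families:
                has_low = sum(_count_motif_in_subregion(windows[i], family,
                                                        lo, hi) > 0
                              for i in low_idx)
                has_high = sum(_count_motif_in_subregion(windows[i], family,
                                                         lo, hi) > 0
                               for i in high_idx)
                table = np.array([[has_low, len(low_idx) - has_low],
                                  [has_high, len(high_idx) - has_high]])
                if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                    continue
                chi2, chi_p = stats.chi2_contingency(table)[:2]
                z, z_p = proportions_ztest([has_low, has_high],
                                           [len(low_idx), len(high_idx)])
                tests.append({"subregion": f"{lo}..{hi}", "family": family,
                              "frac_low": has_low / len(low_idx),
                              "frac_high": has_high / len(high_idx),
                              "chi2": float(chi2), "chi2_p": float(chi_p),
                              "z": float(z), "z_p": float(z_p)})
    return records, pd.DataFrame(tests)


def motif_distance_perturbation(window: str, motif_a_span: tuple[int, int],
                                motif_b_span: tuple[int, int], shift: int,
                                model=None):
    """Slide motif B by ``shift`` nt through the unchanged context.

    Spans are window string indices [start, end).  The displaced context
    nucleotides refill the vacated span so the length stays 240.  Positive
    shifts move motif B towards larger indices; a collision with motif A (or
    the window edge) raises ValueError.  Returns (perturbed window,
    Δentropy) when a PolyaID-like model is given, else the window alone.
    """
    a0, a1 = motif_a_span
    b0, b1 = motif_b_span
    if a1 > b0 and b1 > a0:
        raise ValueError("motif spans overlap")
    new_b0, new_b1 = b0 + shift, b1 + shift
    if new_b0 < 0 or new_b1 > WINDOW_LENGTH:
        raise ValueError("shift moves motif outside the window")
    if a1 > new_b0 and new_b1 > a0:
        raise ValueError("shift collides with the fixed motif")
    chars = list(window)
    motif = chars[b0:b1]
    del chars[b0:b1]
    chars[new_b0:new_b0] = motif
    perturbed = "".join(chars)
    assert len(perturbed) == WINDOW_LENGTH
    if model is None:
        return perturbed, None
    _p0, q0 = model.predict(one_hot(window)[None])
    _p1, q1 = model.predict(one_hot(perturbed)[None])
    delta = cleavage_entropy(q1[0]) - cleavage_entropy(q0[0])
    return perturbed, float(delta)


# --------------------------------------------------------------------------
# Optimal motif configurations
# --------------------------------------------------------------------------

def count_optimal_motifs(window: str) -> dict | None:
    """Count optional elements at their optimal positions around a site.

    Precondition (else None): an AAUAAA ending 10–30 nt upstream of the
    cleavage position and a CstF motif (U-rich or GU/CU-rich) starting
    within 30 nt downstream.  The four optional elements counted are: UGUA
    0–40 nt upstream of the AAUAAA, a U-rich motif between the cleavage site
    and the AAUAAA, a G-rich element within 50 nt of the CstF motif
    downstream, and a second CstF motif.
    """
    centre = WINDOW_HALF

    def family_at(off: int) -> str:
        idx = off + centre
        if idx < 0 or idx + 6 > WINDOW_LENGTH:
            return "none"
        hexamer = window[idx:idx + 6]
        if "N" in hexamer:
            return "none"
        return classify_motif_family(hexamer).name

    pas_starts = [off for off in range(-35, -15 + 1)
                  if family_at(off) == "PAS_AAUAAA"
                  and 10 <= -(off + 5) <= 30]
    if not pas_starts:
        return None
    pas_start = max(pas_starts)  # the PAS closest to the cleavage site
    cstf_starts = [off for off in range(1, 30 + 1)
                   if family_at(off) in ("U_rich", "GU_CU_rich")]
    if not cstf_starts:
        return None
    cstf_start = min(cstf_starts)

    found = {"UGUA": False, "U_rich_upstream": False, "G_rich_downstream": False,
             "second_CstF": False}
    for off in range(pas_start - 40 - 3, pas_start - 4 + 1):
        if family_at(off) == "UGUA":
            found["UGUA"] = True
    for off in range(pas_start + 6, 0 - 5):
        if family_at(off) == "U_rich":
            found["U_rich_upstream"] = True
    for off in range(cstf_start + 6, cstf_start + 50 + 1):
        if family_at(off) == "G_rich":
            found["G_rich_downstream"] = True
    for off in range(cstf_start + 6, 120 - 5):
        if family_at(off) in ("U_rich", "GU_CU_rich"):
            found["second_CstF"] = True
    return {"pas_start": pas_start, "cstf_start": cstf_start,
            "n_optional": sum(found.values()), **found}
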