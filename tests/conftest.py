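"""Shared fixtures: one synthetic truth set and toy models per session.

Training the toy networks dominates the suite's runtime, so every model is
built exactly once (session scope) and reused by the unit and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from polyagrammar import sites3p, synthgen, trainset
from polyagrammar.nnmodels import (ModelConfig, build_polyaid,
                                   build_polyastrength, train,
                                   train_with_restarts)
from polyagrammar.sites3p import PassRead

TOY = dict(conv_filters=16, rnn_units=16, dense_units=32,
           learning_rate=0.003)


@pytest.fixture(scope="session")
def truth():
    """96-gene synthetic genome with planted sites, reads and variants."""
    sequences, annotation = synthgen.generate_genome(n_genes=96, seed=7)
    bundle = synthgen.plant_polya_sites(sequences, annotation, seed=8)
    synthgen.plant_latent_sites(bundle, seed=9)
    synthgen.simulate_pass_reads(bundle, seed=10)
    synthgen.simulate_variants(bundle, seed=11)
    return bundle


def reads_as_pass(reads_frame) -> list[PassRead]:
    return [PassRead(r.chrom, int(r.pos), r.strand, int(r.n_nongenomic_a),
                     r.sample_id, r.lineage)
            for r in reads_frame.itertuples(index=False)]


@pytest.fixture(scope="session")
def called_sites(truth):
    """Clustered, gene-assigned, filtered polyA sites from the truth reads."""
    reads = reads_as_pass(truth.reads)
    sites = sites3p.cluster_sites(reads)
    extensions = {
        g.gene_id: sites3p.extend_terminal_exon(
            g, truth.annotation, truth.genome.chrom_length(g.chrom))
        for g in truth.annotation}
    sites3p.assign_genes(sites, truth.annotation, extensions)
    totals = sites3p.gene_read_totals(sites)
    return sites3p.filter_sites(sites, totals), extensions


@pytest.fixture(scope="session")
def pipeline_dataset(truth, called_sites):
    """Site-level train/val/test arrays built from the called sites."""
    sites, _ = called_sites
    coverage: dict = {}
    for r in truth.reads.itertuples(index=False):
        key = (r.chrom, r.strand)
        coverage.setdefault(key, {})
        coverage[key][int(r.pos)] = coverage[key].get(int(r.pos), 0) + 1
    positives = []
    for site in sites:
        positives.extend(trainset.build_positive_examples(site, truth.genome))
    spans = {c: [] for c in truth.genome.chroms()}
    for g in truth.annotation:
        spans[g.chrom].append((g.start, g.end))
    intergenic = []
    for chrom, pairs in spans.items():
        cursor = 0
        for start, end in sorted(pairs):
            if start - 150 - cursor >= 240:
                intergenic.append((chrom, cursor, start - 150))
            cursor = max(cursor, end + 150)
    transcripts = [truth.genome.fetch(g.chrom, g.start, g.end)
                   for g in list(truth.annotation)[:30]]
    negatives = trainset.build_negative_examples(
        truth.genome, transcripts, sites, coverage,
        n_per_origin=max(1, len(positives) // 3),
        intergenic_regions=intergenic, rng=np.random.default_rng(7))
    splits = trainset.split_dataset(positives + negatives, seed=7)
    return tuple(trainset.to_arrays(s) for s in splits)


@pytest.fixture(scope="session")
def polyaid_toy(pipeline_dataset):
    """Toy PolyaID for scanning: pipeline dataset plus grammar windows with
    (i) element hard negatives (PAS-corrupted or CstF-erased grammars), so
    the model learns the PAS∧CstF conjunction rather than either element
    alone, and (ii) variable PAS↔CstF spacing with spacing-coupled cleavage
    dispersion, so the distance→heterogeneity relationship is learnable."""
    train_arrays, val_arrays, _ = pipeline_dataset
    hard_tr = synthgen.generate_training_windows(
        3000, 0, seed=40, nonfunctional_frac=0.5, nonfunctional_mode="element",
        cstf_spacing_range=(10, 50))
    hard_va = synthgen.generate_training_windows(
        300, 0, seed=41, nonfunctional_frac=0.5, nonfunctional_mode="element",
        cstf_spacing_range=(10, 50))
    datasets = {}
    for name, arrays, hard in (("train", train_arrays, hard_tr),
                               ("val", val_arrays, hard_va)):
        datasets[name] = (np.concatenate([arrays[0], hard.x]),
                          np.concatenate([arrays[1], hard.label_class]),
                          np.concatenate([arrays[2], hard.cleavage]))
    config = ModelConfig(max_epochs=8, seed=3, **TOY)
    model, history = train_with_restarts(build_polyaid, datasets, config)
    assert min(history.val_loss) < 1.0, "toy PolyaID failed to train"
    return model


@pytest.fixture(scope="session")
def spacing_polyaid():
    """Toy PolyaID trained to convergence on windows whose PAS↔CstF spacing
    varies (10..50 nt) with spacing-coupled cleavage dispersion — the model
    for distance→heterogeneity analyses."""
    tr = synthgen.generate_training_windows(10000, 2000, seed=50,
                                            cstf_spacing_range=(10, 50))
    va = synthgen.generate_training_windows(600, 120, seed=51,
                                            cstf_spacing_range=(10, 50))
    config = ModelConfig(max_epochs=14, seed=0, **TOY)
    model, _history = train_with_restarts(
        build_polyaid,
        {"train": (tr.x, tr.label_class, tr.cleavage),
         "val": (va.x, va.label_class, va.cleavage)}, config)
    return model


@pytest.fixture(scope="session")
def polyastrength_toy():
    """Toy PolyaStrength trained on generator windows incl. corrupted-PAS
    examples (used for variant-effect sign tests)."""
    tr = synthgen.generate_training_windows(5000, 0, seed=20, max_shift=0,
                                            nonfunctional_frac=0.2)
    va = synthgen.generate_training_windows(600, 0, seed=21, max_shift=0,
                                            nonfunctional_frac=0.2)
    config = ModelConfig(max_epochs=9, seed=0, **TOY)
    model = build_polyastrength(config)
    train(model, {"train": (tr.x, tr.strength), "val": (va.x, va.strength)},
          config)
    return model


@pytest.fixture(scope="session")
def criterion3_polyaid():
    """Reduced PolyaID per the published recipe: 4 epochs, 5,000 examples."""
    tr = synthgen.generate_training_windows(2500, 2500, seed=10)
    va = synthgen.generate_training_windows(300, 300, seed=11)
    te = synthgen.generate_training_windows(300, 300, seed=12)
    config = ModelConfig(max_epochs=4, seed=0, **TOY)
    model = build_polyaid(config)
    train(model, {"train": (tr.x, tr.label_class, tr.cleavage),
                  "val": (va.x, va.label_class, va.cleavage)}, config)
    return model, te


@pytest.fixture(scope="session")
def criterion3_polyastrength():
    """Reduced PolyaStrength trained to convergence on planted-strength
    windows (the generator randomises motif offsets, so this needs a larger
    budget than the classification recipe)."""
    tr = synthgen.generate_training_windows(10000, 0, seed=30, max_shift=0)
    va = synthgen.generate_training_windows(600, 0, seed=31, max_shift=0)
    te = synthgen.generate_training_windows(600, 0, seed=32, max_shift=0)
    # regression shows no saddle issue; use the standard learning rate
    config = ModelConfig(max_epochs=15, seed=0,
                         **{**TOY, "learning_rate": 0.001})
    model = build_polyastrength(config)
    train(model, {"train": (tr.x, tr.strength), "val": (va.x, va.strength)},
          config)
    return model, te
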