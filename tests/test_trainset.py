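"""Unit tests for training-example construction, encoding, usage labels and
dataset serialization."""

from __future__ import annotations

import json

import numpy as np
import pytest

from polyagrammar import trainset
from polyagrammar.genome import SequenceStore
from polyagrammar.sites3p import PolyASite
from polyagrammar.trainset import (SequenceWindow, TrainingExample,
                                   build_positive_examples,
                                   cleavage_vector_from_reads, decode_one_hot,
                                   one_hot, read_dataset, split_dataset,
                                   to_arrays, usage_logodds, write_dataset)


def _random_window(seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=240))


def test_one_hot_round_trip():
    seq = _random_window(1)
    mat = one_hot(seq)
    assert mat.shape == (4, 240)
    assert mat.dtype == np.float32
    np.testing.assert_array_equal(mat.sum(axis=0), np.ones(240))
    assert decode_one_hot(mat) == seq
    # row order is A, C, G, T
    probe = one_hot("ACGT" * 60)
    assert probe[0, 0] == 1 and probe[1, 1] == 1
    assert probe[2, 2] == 1 and probe[3, 3] == 1


def test_one_hot_n_gives_zero_column():
    seq = "N" + _random_window(2)[1:]
    mat = one_hot(seq)
    assert mat[:, 0].sum() == 0
    assert decode_one_hot(mat)[0] == "N"
    with pytest.raises(ValueError):
        one_hot("ACGT")


def test_sequence_window_validation():
    with pytest.raises(ValueError):
        SequenceWindow("ACGT")
    with pytest.raises(ValueError):
        SequenceWindow("X" * 240)


def test_cleavage_vector_from_reads_both_strands():
    reads = {100: 3, 99: 1, 124: 2, 125: 4}   # 125 is outside −25..+24 of 100
    vec = cleavage_vector_from_reads(reads, anchor=100, strand="+")
    assert vec.shape == (50,)
    assert vec.sum() == pytest.approx(1.0)
    assert vec[25] == pytest.approx(3 / 6)    # offset 0
    assert vec[24] == pytest.approx(1 / 6)    # offset −1
    assert vec[49] == pytest.approx(2 / 6)    # offset +24

    mvec = cleavage_vector_from_reads({100: 3, 101: 1}, anchor=100, strand="-")
    assert mvec[25] == pytest.approx(3 / 4)
    assert mvec[24] == pytest.approx(1 / 4)   # genomic +1 is sense offset −1

    assert cleavage_vector_from_reads({200: 5}, anchor=100,
                                      strand="+").sum() == 0


def test_build_positive_examples_shifts_and_labels():
    rng = np.random.default_rng(3)
    genome = SequenceStore({"c": "".join(rng.choice(list("ACGT"), size=2000))})
    site = PolyASite("c", 1000, "+", read_count_total=10,
                     read_positions={1000: 7, 999: 3})
    examples = build_positive_examples(site, genome)
    assert len(examples) == 51
    for ex in examples:
        assert ex.label_class == 1
        assert ex.origin == "positive_shifted"
        assert ex.site_id == site.site_id
        assert ex.label_cleavage.sum() == pytest.approx(1.0)
    # the zero-shift window is anchored on the site itself
    centre = next(e for e in examples if e.window.anchor_pos == 1000)
    assert centre.label_cleavage[25] == pytest.approx(0.7)
    assert centre.label_cleavage[24] == pytest.approx(0.3)
    # a +1 shifted anchor sees the reads one offset earlier
    shifted = next(e for e in examples if e.window.anchor_pos == 1001)
    assert shifted.label_cleavage[24] == pytest.approx(0.7)


def test_build_positive_examples_edge_of_chromosome():
    rng = np.random.default_rng(4)
    genome = SequenceStore({"c": "".join(rng.choice(list("ACGT"), size=500))})
    site = PolyASite("c", 130, "+", read_positions={130: 5})
    examples = build_positive_examples(site, genome)
    # shifts whose window would start before position 0 are skipped
    assert 0 < len(examples) < 51
    assert all(e.window.anchor_pos >= 120 for e in examples)


def test_usage_logodds_oracles():
    rec = usage_logodds(10, 10, 10)   # u = 10 / (10 + 10) = 0.5
    assert rec.u_i == pytest.approx(0.5)
    assert rec.o_i == pytest.approx(0.0)
    # u = 0 uses the pseudocount against the denominator
    rec0 = usage_logodds(0, 10, 10)
    u_adj = 0.5 / 20.5
    assert rec0.u_i == 0.0
    assert rec0.o_i == pytest.approx(np.log2(u_adj / (1 - u_adj)))
    # u = 1 (site is the only expressed one) uses n_i/(n_i + pseudocount)
    rec1 = usage_logodds(20, 20, 0)
    u_adj = 20 / 20.5
    assert rec1.o_i == pytest.approx(np.log2(u_adj / (1 - u_adj)))
    with pytest.raises(ValueError):
        usage_logodds(5, 3, 4)       # n_top < n_second
    with pytest.raises(ValueError):
        usage_logodds(5, 0, 0)       # zero denominator


def _toy_examples(n_sites, per_site, label, prefix):
    examples = []
    for s in range(n_sites):
        sid = f"{prefix}{s}"
        for k in range(per_site):
            seq = _random_window(seed=hash((prefix, s, k)) % (2**32))
            vec = np.full(50, 0.02)
            examples.append(TrainingExample(SequenceWindow(seq), label, vec,
                                            "positive_shifted" if label
                                            else "neg_intergenic", site_id=sid))
    return examples


def test_split_dataset_site_level_and_fractions():
    examples = _toy_examples(20, 5, 1, "p") + _toy_examples(20, 5, 0, "n")
    train, val, test = split_dataset(examples, seed=3)
    assert len(train) + len(val) + len(test) == len(examples)
    seen = [
        {e.site_id for e in split} for split in (train, val, test)]
    # no site straddles two splits
    assert not (seen[0] & seen[1]) and not (seen[0] & seen[2]) \
        and not (seen[1] & seen[2])
    # per-class 80/10/10 at site level
    for label, prefix in ((1, "p"), (0, "n")):
        counts = [sum(1 for sid in split if sid.startswith(prefix))
                  for split in seen]
        assert counts == [16, 2, 2]
    with pytest.raises(ValueError):
        split_dataset(examples, fractions=(0.5, 0.4, 0.2))


def test_write_read_dataset_round_trip(tmp_path):
    examples = _toy_examples(3, 4, 1, "p") + _toy_examples(2, 4, 0, "n")
    path = tmp_path / "data.tsv.gz"
    write_dataset(examples, path, manifest_extra={"seed": 11})
    back = read_dataset(path)
    assert len(back) == len(examples)
    for a, b in zip(examples, back):
        assert a.window.seq == b.window.seq
        assert a.label_class == b.label_class
        assert a.origin == b.origin
        assert a.site_id == b.site_id
        np.testing.assert_allclose(a.label_cleavage, b.label_cleavage,
                                   rtol=1e-6)
    manifest = json.loads((tmp_path / "data.tsv.gz.manifest.json").read_text())
    assert manifest["n_examples"] == len(examples)
    assert manifest["counts_per_origin"] == {"positive_shifted": 12,
                                             "neg_intergenic": 8}
    assert manifest["seed"] == 11


def test_to_arrays_shapes():
    examples = _toy_examples(2, 3, 1, "p")
    x, y, c = to_arrays(examples)
    assert x.shape == (6, 4, 240)
    assert y.shape == (6,) and set(y) == {1.0}
    assert c.shape == (6, 50)
    np.testing.assert_array_equal(x[0], one_hot(examples[0].window))


def test_build_negative_examples_origins():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    genome = SequenceStore({"c": seq})
    site = PolyASite("c", 3000, "+", read_count_total=50,
                     read_positions={3000: 50})
    coverage = {("c", "+"): {3000: 50}}
    negatives = trainset.build_negative_examples(
        genome, [seq[:2000]], [site], coverage, n_per_origin=5,
        intergenic_regions=[("c", 0, 2000)], rng=np.random.default_rng(0))
    origins = {e.origin for e in negatives}
    assert origins <= {"neg_intergenic", "neg_shuffled", "neg_neighbor"}
    assert len(origins) >= 2
    for e in negatives:
        assert e.label_class == 0
        np.testing.assert_allclose(e.label_cleavage, np.full(50, 0.02))
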