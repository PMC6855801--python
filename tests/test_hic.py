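"""Hi-C pair averages, relative change, and triplet round-trips."""

import numpy as np
import pytest

from ctkit.hic import (
    ContactMatrixPair,
    genome_delta_table,
    pair_average,
    read_triplets,
    relative_change,
    write_triplets,
)
from ctkit.synthetic import HiCSimSpec, generate_condition_set, generate_contact_matrix_pair


def _pair(values, pair=("2", "3"), resolution=5000):
    return ContactMatrixPair(pair=pair, values=np.asarray(values, dtype=float),
                             resolution=resolution)


def test_uniform_matrix_average():
    assert pair_average(_pair(np.full((4, 4), 2.0))) == pytest.approx(2.0)


def test_na_bins_excluded_from_average():
    assert pair_average(_pair([[1.0, 3.0], [np.nan, np.nan]])) == pytest.approx(2.0)


def test_all_na_raises():
    with pytest.raises(ValueError):
        pair_average(_pair(np.full((3, 3), np.nan)))


def test_average_matches_loop_oracle(rng):
    for _ in range(20):
        shape = tuple(rng.integers(3, 15, size=2))
        vals = rng.random(shape)
        vals[rng.random(shape) < 0.2] = np.nan
        if np.isnan(vals).all():
            continue
        total, count = 0.0, 0
        for v in vals.ravel():
            if not np.isnan(v):
                total += v
                count += 1
        assert pair_average(_pair(vals)) == pytest.approx(total / count, rel=1e-12)


def test_adding_mean_valued_na_bins_leaves_average_unchanged():
    vals = np.array([[1.0, 2.0], [3.0, 2.0]])
    mean = vals.mean()
    padded = np.array([[1.0, 2.0, np.nan], [3.0, 2.0, np.nan]])
    assert pair_average(_pair(padded)) == pytest.approx(mean)


def test_relative_change_identity_and_scaling():
    wt = _pair(np.arange(1.0, 10.0).reshape(3, 3))
    assert relative_change(wt, wt).relative_change == pytest.approx(0.0)
    kd = _pair(1.2 * np.arange(1.0, 10.0).reshape(3, 3))
    assert relative_change(wt, kd).relative_change == pytest.approx(0.2)


def test_relative_change_scale_equivariance():
    rng = np.random.default_rng(0)
    wt = _pair(rng.random((5, 5)) + 0.5)
    kd = _pair(rng.random((5, 5)) + 0.5)
    base = relative_change(wt, kd).relative_change
    for c in (0.1, 3.0, 100.0):
        swt = _pair(c * wt.values)
        skd = _pair(c * kd.values)
        assert relative_change(swt, skd).relative_change == pytest.approx(base, rel=1e-12)


def test_noiseless_toy_genome_deltas_exact():
    spec = HiCSimSpec(cis_scale=0.8, trans_scale=1.1, seed=1)
    table = genome_delta_table(
        generate_condition_set(spec, "WT"), generate_condition_set(spec, "KD")
    )
    cis = table[table.kind == "cis"].relative_change
    trans = table[table.kind == "trans"].relative_change
    assert np.allclose(cis, -0.2, atol=1e-12)
    assert np.allclose(trans, 0.1, atol=1e-12)


def test_trans_only_perturbation_leaves_cis_deltas_zero():
    spec = HiCSimSpec(cis_scale=1.0, trans_scale=1.25, seed=2)
    table = genome_delta_table(
        generate_condition_set(spec, "WT"), generate_condition_set(spec, "KD")
    )
    assert np.allclose(table[table.kind == "cis"].relative_change, 0.0, atol=1e-12)
    assert np.allclose(table[table.kind == "trans"].relative_change, 0.25, atol=1e-12)


def test_na_mask_deterministic_count_and_shared_between_conditions():
    spec = HiCSimSpec(na_fraction=0.1, noise_cv=0.05, seed=4)
    for pair in spec.pairs():
        wt = generate_contact_matrix_pair(spec, pair, "WT")
        kd = generate_contact_matrix_pair(spec, pair, "KD")
        assert wt.na_mask.sum() == round(0.1 * wt.values.size)
        np.testing.assert_array_equal(wt.na_mask, kd.na_mask)


def test_identity_scales_reproduce_wt_exactly():
    spec = HiCSimSpec(cis_scale=1.0, trans_scale=1.0, seed=5)
    for pair in spec.pairs():
        wt = generate_contact_matrix_pair(spec, pair, "WT")
        kd = generate_contact_matrix_pair(spec, pair, "KD")
        np.testing.assert_array_equal(wt.values, kd.values)


def test_mismatched_pair_sets_rejected():
    spec = HiCSimSpec(seed=6)
    wt = generate_condition_set(spec, "WT")
    kd = generate_condition_set(spec, "KD")[:-1]
    with pytest.raises(ValueError):
        genome_delta_table(wt, kd)


def test_triplet_roundtrip_preserves_values_and_na(tmp_path, rng):
    vals = rng.random((6, 8))
    vals[rng.random((6, 8)) < 0.25] = np.nan
    m = ContactMatrixPair(pair=("X", "3"), values=vals, resolution=5000,
                          lengths=(28_000, 38_500))
    path = tmp_path / "pair.txt"
    write_triplets(m, path)
    back = read_triplets(path)
    assert back.pair == ("X", "3")
    assert back.resolution == 5000
    assert back.lengths == (28_000, 38_500)
    np.testing.assert_array_equal(np.isnan(back.values), np.isnan(vals))
    np.testing.assert_array_equal(back.values[~np.isnan(vals)], vals[~np.isnan(vals)])
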