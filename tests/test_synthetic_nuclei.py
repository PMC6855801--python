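"""Generator truth consistency, calibration and determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from ctkit.imagestack import voxel_volume
from ctkit.synthetic import (
    InfeasibleGeometryError,
    NucleusSpec,
    generate_cohort,
    generate_nucleus_image,
)

SMALL = NucleusSpec(shape=(16, 40, 40), nucleus_semiaxes=(2.0, 2.6, 2.6))


def test_identical_seed_gives_bit_identical_output():
    s1, t1 = generate_nucleus_image(dataclasses.replace(SMALL, seed=5))
    s2, t2 = generate_nucleus_image(dataclasses.replace(SMALL, seed=5))
    for name in s1.channels:
        np.testing.assert_array_equal(s1.channels[name], s2.channels[name])
    for name in t1.territory_masks:
        np.testing.assert_array_equal(t1.territory_masks[name], t2.territory_masks[name])
    assert t1.true_pair_overlaps == t2.true_pair_overlaps


def test_truth_overlaps_match_brute_force_intersection():
    _, truth = generate_nucleus_image(dataclasses.replace(SMALL, seed=3))
    vv = voxel_volume(truth.voxel_size)
    names = list(truth.territory_masks)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = truth.territory_masks[names[i]] > 0
            b = truth.territory_masks[names[j]] > 0
            exact = int((a & b).sum()) * vv
            assert truth.true_pair_overlaps[(names[i], names[j])] == pytest.approx(exact, abs=0)


def test_territories_lie_inside_nucleus_and_are_connected():
    _, truth = generate_nucleus_image(dataclasses.replace(SMALL, seed=11))
    struct = ndi.generate_binary_structure(3, 3)
    for name, lab in truth.territory_masks.items():
        fg = lab > 0
        assert not (fg & ~truth.nucleus_mask).any()
        _, n = ndi.label(fg, structure=struct)
        assert n == 1, f"territory {name} fragmented into {n} components"


def test_zero_contact_probability_gives_disjoint_territories():
    spec = dataclasses.replace(SMALL, contact_probability=0.0, seed=2)
    _, truth = generate_nucleus_image(spec)
    assert all(v == 0.0 for v in truth.true_pair_overlaps.values())
    assert not any(truth.true_contacts.values())


def test_single_territory_volume_matches_requested_fraction():
    # nucleus ~100 µm³ with a 0.2 fraction territory -> ~20 µm³ true volume
    spec = NucleusSpec(
        shape=(20, 48, 48),
        nucleus_semiaxes=(2.4, 3.15, 3.15),  # 4/3·π·abc ≈ 99.7 µm³
        n_territories=1,
        target_volume_fraction=0.2,
        seed=4,
    )
    _, truth = generate_nucleus_image(spec)
    assert truth.true_volumes["X"] == pytest.approx(0.2 * truth.nucleus_volume(), rel=0.05)
    assert truth.true_volumes["X"] == pytest.approx(20.0, rel=0.05)


def test_no_territory_exceeds_28_percent_of_nucleus():
    for seed in range(5):
        _, truth = generate_nucleus_image(dataclasses.replace(SMALL, seed=seed))
        nv = truth.nucleus_volume()
        assert all(v / nv <= 0.28 for v in truth.true_volumes.values())


def test_cohort_contact_fraction_within_binomial_ci():
    # 500 nuclei at contact probability 0.95: the realised contact fraction
    # must fall in the central 99% binomial interval
    spec = dataclasses.replace(SMALL, contact_probability=0.95)
    flags = []
    for _, truth in generate_cohort(spec, 500, seed=1):
        flags += list(truth.true_contacts.values())
    from scipy import stats as sps

    n = len(flags)
    lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.95) / n
    assert lo <= np.mean(flags) <= hi


def test_split_homologs_yield_two_objects():
    spec = NucleusSpec(
        shape=(20, 48, 48),
        nucleus_semiaxes=(2.4, 3.15, 3.15),
        n_territories=1,
        target_volume_fraction=0.2,
        split_homologs=True,
        seed=9,
    )
    _, truth = generate_nucleus_image(spec)
    assert truth.territory_masks["X"].max() == 2


def test_infeasible_geometry_raises():
    # the nucleus ellipsoid misses every lattice point entirely
    bad = NucleusSpec(shape=(6, 8, 8), nucleus_semiaxes=(0.05, 0.05, 0.05),
                      target_volume_fraction=0.28)
    with pytest.raises((InfeasibleGeometryError, ValueError)):
        generate_nucleus_image(bad)


@pytest.mark.parametrize(
    "field,value",
    [
        ("target_volume_fraction", 0.3),  # beyond the 28% ceiling
        ("target_volume_fraction", [0.34, 0.34, 0.34]),
        ("contact_probability", 1.5),
        ("psf_sigma", -0.1),
    ],
)
def test_spec_validation_rejects_bad_values(field, value):
    with pytest.raises(ValueError):
        generate_nucleus_image(dataclasses.replace(SMALL, **{field: value}))
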