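"""Hysteresis and territory segmentation against first-principles oracles."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from oracle_helpers import hysteresis_flood_fill
from ctkit.imagestack import LabelMask
from ctkit.segmentation import (
    NUCLEUS_PARAMS,
    TERRITORY_PARAMS,
    SegmentationParams,
    segment_nucleus,
    segment_territories,
)
from ctkit.synthetic import NucleusSpec, generate_nucleus_image

VOX1 = (1.0, 1.0, 1.0)
# unit voxels, no small-object removal: pure hysteresis semantics
PURE = SegmentationParams(min_object_volume=0.5)


def _random_smooth_grid(rng, shape):
    g = rng.random(shape)
    return ndi.gaussian_filter(g, sigma=1.2)


def test_uniform_zero_grid_gives_empty_mask():
    out = segment_nucleus(np.zeros((8, 8, 8)), VOX1, PURE)
    assert out.labels.max() == 0
    assert "no-signal" in out.qc_flags


def test_binary_grid_thresholds_collapse_to_foreground():
    rng = np.random.default_rng(0)
    img = (rng.random((10, 12, 12)) < 0.3).astype(float)
    out = segment_nucleus(img, VOX1, dataclasses.replace(PURE, hysteresis_low=0.3, hysteresis_high=0.6))
    np.testing.assert_array_equal(out.labels > 0, img > 0)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_hysteresis_equals_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(1)
    params = dataclasses.replace(PURE, connectivity=connectivity)
    for _ in range(25):
        shape = tuple(rng.integers(6, 20, size=3))
        img = _random_smooth_grid(rng, shape)
        out = segment_nucleus(img, VOX1, params)
        rmax = np.percentile(img, 99.9)
        expect = hysteresis_flood_fill(
            img, params.hysteresis_low * rmax, params.hysteresis_high * rmax, connectivity
        )
        np.testing.assert_array_equal(out.labels > 0, expect)


def test_lowering_low_threshold_never_shrinks_mask():
    rng = np.random.default_rng(2)
    img = _random_smooth_grid(rng, (12, 14, 14))
    lows = [0.45, 0.35, 0.25, 0.15]
    masks = [
        segment_nucleus(img, VOX1, dataclasses.replace(PURE, hysteresis_low=lo)).foreground()
        for lo in lows
    ]
    for tighter, looser in zip(masks, masks[1:]):
        assert (tighter <= looser).all(), "lower threshold must give a superset"


def test_territory_channel_zero_inside_nucleus_gives_empty_mask():
    nucleus = LabelMask(labels=np.ones((8, 10, 10), dtype=np.int32), voxel_size=VOX1)
    out = segment_territories(np.zeros((8, 10, 10)), nucleus, VOX1)
    assert out.labels.max() == 0


def test_noise_free_recovery_volume_jaccard_containment():
    spec = NucleusSpec(gaussian_sd=0.0, seed=21)
    stack, truth = generate_nucleus_image(spec)
    nucleus = segment_nucleus(stack.channels["dna"], stack.voxel_size)
    for name in spec.channel_names:
        mask = segment_territories(
            stack.channels[name], nucleus, stack.voxel_size, channel_name=name
        )
        seg = mask.foreground()
        tr = truth.territory_masks[name] > 0
        jacc = (seg & tr).sum() / (seg | tr).sum()
        assert jacc >= 0.9
        assert seg.sum() == pytest.approx(tr.sum(), rel=0.10)
        assert not (seg & ~nucleus.foreground()).any()


def test_split_homologs_recovered_as_two_objects():
    spec = NucleusSpec(
        shape=(20, 48, 48),
        nucleus_semiaxes=(2.4, 3.15, 3.15),
        n_territories=1,
        target_volume_fraction=0.2,
        split_homologs=True,
        gaussian_sd=0.0,
        seed=9,
    )
    stack, truth = generate_nucleus_image(spec)
    nucleus = segment_nucleus(stack.channels["dna"], stack.voxel_size)
    mask = segment_territories(stack.channels["X"], nucleus, stack.voxel_size, channel_name="X")
    assert len(mask.label_ids()) == 2
    vv = mask.voxel_volume_um3
    true_sizes = sorted(np.bincount(truth.territory_masks["X"].ravel())[1:])
    seg_sizes = sorted(np.bincount(mask.labels.ravel())[1:])
    for s, t in zip(seg_sizes, true_sizes):
        assert s * vv == pytest.approx(t * vv, rel=0.10)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SegmentationParams(hysteresis_low=0.6, hysteresis_high=0.5).validate()
    with pytest.raises(ValueError):
        SegmentationParams(connectivity=4).validate()
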