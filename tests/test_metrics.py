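"""Volume, intermixing and contact-call metrics against counting oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracle_helpers import count_voxels_loop, intersection_loop
from ctkit.imagestack import LabelMask
from ctkit.metrics import (
    PairOverlapRecord,
    call_contact,
    intermixing_volume,
    measure_volume,
    summarize_population,
    total_volume,
)


def _mask(arr, voxel_size=(1.0, 1.0, 1.0)):
    return LabelMask(labels=np.asarray(arr, dtype=np.int32), voxel_size=voxel_size)


def test_volume_is_count_times_voxel_volume():
    labels = np.zeros((10, 10, 10), dtype=np.int32)
    labels.ravel()[:1000] = 1
    mask = _mask(labels, voxel_size=(0.25, 0.1, 0.1))
    assert measure_volume(mask)[1] == pytest.approx(1000 * 0.25 * 0.1 * 0.1)
    assert total_volume(mask) == pytest.approx(2.5)


def test_empty_mask_reports_zero_with_flag():
    mask = _mask(np.zeros((4, 4, 4)))
    assert measure_volume(mask) == {}
    assert "empty-mask" in mask.qc_flags
    assert total_volume(mask) == 0.0


def test_volume_and_intersection_match_loop_oracles(rng):
    for _ in range(15):
        shape = tuple(rng.integers(4, 12, size=3))
        a = (rng.random(shape) < 0.3).astype(np.int32)
        b = (rng.random(shape) < 0.3).astype(np.int32) * 2
        vs = tuple(rng.uniform(0.05, 0.4, size=3))
        ma, mb = _mask(a, vs), _mask(b, vs)
        vv = vs[0] * vs[1] * vs[2]
        assert total_volume(ma) == pytest.approx(count_voxels_loop(a) * vv, abs=0)
        assert intermixing_volume(ma, mb) == pytest.approx(intersection_loop(a, b) * vv, abs=0)


def test_intermixing_symmetry_and_min_bound(rng):
    shape = (8, 10, 10)
    for _ in range(10):
        a = (rng.random(shape) < 0.4).astype(np.int32)
        b = (rng.random(shape) < 0.4).astype(np.int32)
        ma, mb = _mask(a), _mask(b)
        assert intermixing_volume(ma, mb) == intermixing_volume(mb, ma)
        assert intermixing_volume(ma, mb) <= min(total_volume(ma), total_volume(mb))


def test_identical_masks_intermix_fully():
    a = np.zeros((5, 5, 5), dtype=np.int32)
    a.ravel()[:100] = 1
    mask = _mask(a, voxel_size=(0.1, 0.1, 0.1))
    assert intermixing_volume(mask, mask) == pytest.approx(0.1)


def test_shape_mismatch_raises():
    with pytest.raises(ValueError):
        intermixing_volume(_mask(np.zeros((4, 4, 4))), _mask(np.zeros((4, 4, 5))))


@pytest.mark.parametrize(
    "volume,expected",
    [(0.6, True), (0.5, False), (0.0, False), (0.5000001, True)],
)
def test_contact_call_is_strictly_greater_than_threshold(volume, expected):
    assert call_contact(volume) is expected


def test_contact_call_rejects_negative_volume():
    with pytest.raises(ValueError):
        call_contact(-0.1)


@given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.0, max_value=5.0))
def test_contact_call_consistent_with_definition(volume, threshold):
    assert call_contact(volume, threshold) == (volume > threshold)


def _records(overlaps, threshold=0.5, pair=("2", "3")):
    return [
        PairOverlapRecord(
            cell_id=f"c{i}",
            pair=pair,
            intermixing_volume=v,
            contact=call_contact(v, threshold),
            threshold_used=threshold,
        )
        for i, v in enumerate(overlaps)
    ]


def test_population_summary_frequency_and_median():
    recs = _records([2.0] * 9 + [0.0])  # 9 of 10 in contact
    out = summarize_population(recs)
    assert out.contact_frequency.iloc[0] == pytest.approx(0.9)
    recs = _records([0, 0, 1, 2, 3])
    out = summarize_population(recs)
    assert out.median_intermixing.iloc[0] == pytest.approx(1.0)


def test_contact_frequency_invariant_to_overlap_scaling_but_median_not():
    # the binary contact frequency cannot see a uniform inflation of
    # above-threshold overlaps; the median intermixing volume does
    base = [0.0, 0.0, 0.8, 1.5, 3.0]
    scaled = [v * 2 if v > 0.5 else v for v in base]
    s_base = summarize_population(_records(base))
    s_scaled = summarize_population(_records(scaled))
    assert s_base.contact_frequency.iloc[0] == s_scaled.contact_frequency.iloc[0]
    assert s_base.median_intermixing.iloc[0] != s_scaled.median_intermixing.iloc[0]


def test_empty_record_list_raises():
    with pytest.raises(ValueError):
        summarize_population([])
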