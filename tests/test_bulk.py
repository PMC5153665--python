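import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sogseg as sg
from sogseg import IntensityRange, VolumeGrid

from conftest import bfs_components, label_partition


def _grid(values, voxel_size=(50.0, 18.9, 18.9)):
    return VolumeGrid(np.asarray(values, dtype=np.float32), voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def test_threshold_bounds_are_inclusive():
    v = _grid(np.array([[[5.0, 10.0, 15.0, 20.0]]]))
    m = sg.threshold_range(v, IntensityRange(10, 15))
    assert m.tolist() == [[[False, True, True, False]]]


def test_threshold_full_range_selects_everything(small_mito):
    _, vol, _ = small_mito
    tr = sg.true_range(vol)
    assert sg.threshold_range(vol, tr).all()


def test_threshold_covers_labelled_voxels(small_mito):
    spec, vol, truth = small_mito
    m = sg.threshold_range(vol, spec.separating_range())
    mito = truth.mask("mitochondria")
    assert m[mito].mean() >= 0.99


@given(st.integers(0, 200), st.integers(0, 55), st.integers(0, 55))
@settings(max_examples=30, deadline=None)
def test_threshold_monotone_in_range_width(lo, d1, d2):
    rng = np.random.default_rng(12)
    v = _grid(rng.integers(0, 255, (5, 5, 5)).astype(np.float32))
    narrow = sg.threshold_range(v, IntensityRange(lo, min(lo + d1, 255)))
    wide = sg.threshold_range(v, IntensityRange(lo, min(lo + d1 + d2, 255)))
    assert not (narrow & ~wide).any()


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

def test_diagonal_voxels_split_by_connectivity():
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[0, 0, 0] = mask[1, 1, 1] = True
    assert sg.connected_components(mask, 26).n_objects == 1
    assert sg.connected_components(mask, 18).n_objects == 2
    assert sg.connected_components(mask, 6).n_objects == 2


def test_component_edge_cases():
    assert sg.connected_components(np.zeros((3, 3, 3), bool), 26).n_objects == 0
    full = sg.connected_components(np.ones((3, 3, 3), bool), 6)
    assert full.n_objects == 1
    assert full.object_sizes()[1] == 27


def test_labelling_order_is_raster_scan():
    mask = np.zeros((1, 3, 5), dtype=bool)
    mask[0, 0, 4] = True   # first in raster order
    mask[0, 2, 0] = True
    lv = sg.connected_components(mask, 26)
    assert lv.labels[0, 0, 4] == 1
    assert lv.labels[0, 2, 0] == 2


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_components_match_bfs_oracle_on_random_masks(connectivity):
    rng = np.random.default_rng(connectivity)
    for _ in range(300):
        mask = rng.random((3, 3, 3)) < rng.uniform(0.2, 0.8)
        lv = sg.connected_components(mask, connectivity)
        assert label_partition(lv.labels) == bfs_components(mask, connectivity)


def test_partition_property(small_mito):
    spec, vol, _ = small_mito
    mask = sg.threshold_range(vol, spec.separating_range())
    lv = sg.connected_components(mask, 26)
    assert np.array_equal(lv.labels > 0, mask)


# ---------------------------------------------------------------------------
# Size filter
# ---------------------------------------------------------------------------

def _labelled_sizes(sizes, voxel_size=(50.0, 18.9, 18.9)):
    """A label volume with one straight run of each requested size."""
    total = sum(sizes)
    labels = np.zeros((1, len(sizes), max(sizes)), dtype=np.int32)
    for i, s in enumerate(sizes):
        labels[0, i, :s] = i + 1
    return sg.LabelVolume(labels, connectivity=26, voxel_size=voxel_size), total


def test_min_voxels_cutoff_is_strict():
    lv, _ = _labelled_sizes([3, 10, 250])
    out, log = sg.filter_min_size(lv, min_voxels=10)
    assert out.n_objects == 2
    assert sorted(out.object_sizes()[1:].tolist()) == [10, 250]
    assert log.records[0].removed_ids == [1]


def test_min_volume_cutoff_at_binned_voxel_size():
    # voxel 18.9 x 18.9 x 50 nm -> 1.786e-5 um3; 11 voxels < 2e-4 um3 < 12 voxels
    lv, _ = _labelled_sizes([11, 12])
    out, _ = sg.filter_min_size(lv, min_volume_um3=0.0002)
    assert out.n_objects == 1
    assert out.object_sizes()[1] == 12


def test_size_filter_on_empty_labels():
    lv = sg.LabelVolume(np.zeros((2, 2, 2), np.int32), voxel_size=(50.0, 18.9, 18.9))
    out, log = sg.filter_min_size(lv, min_voxels=10)
    assert out.n_objects == 0
    assert log.removed_ids() == []


def test_size_filter_idempotent(small_mito):
    spec, vol, _ = small_mito
    lv, _ = sg.bulk_segment(vol, spec.separating_range(),
                            min_voxels=None, min_volume_um3=None, max_variance=None)
    once, _ = sg.filter_min_size(lv, min_voxels=10)
    twice, _ = sg.filter_min_size(once, min_voxels=10)
    assert np.array_equal(once.labels, twice.labels)


# ---------------------------------------------------------------------------
# Variance filter
# ---------------------------------------------------------------------------

def test_variance_filter_direct_computation():
    labels = np.zeros((1, 1, 20), dtype=np.int32)
    labels[0, 0, :10] = 1  # half 0, half 255 -> population variance 16256.25
    labels[0, 0, 10:15] = 2  # constant
    labels[0, 0, 15] = 3  # single voxel
    vals = np.zeros((1, 1, 20), dtype=np.float32)
    vals[0, 0, :5] = 255.0
    vals[0, 0, 10:15] = 80.0
    lv = sg.LabelVolume(labels, voxel_size=(50.0, 18.9, 18.9))
    vol = _grid(vals)
    var = sg.object_intensity_variance(lv, vol)
    assert var[0] == pytest.approx(16256.25)
    assert var[1] == 0.0 and var[2] == 0.0
    out, log = sg.filter_intensity_variance(lv, vol, max_variance=1000)
    assert out.n_objects == 2  # constant and single-voxel objects kept
    assert log.records[0].removed_ids == [1]


def test_variance_filter_removes_fragments_keeps_mitochondria(small_mito):
    spec, vol, truth = small_mito
    lv, _ = sg.bulk_segment(vol, spec.separating_range(),
                            min_voxels=10, min_volume_um3=None, max_variance=None)
    out, log = sg.filter_intensity_variance(lv, vol, max_variance=(4 * spec.label_sd) ** 2)
    frag = truth.mask("membrane_fragment")
    mito = truth.mask("mitochondria")
    # no surviving object overlaps a fragment; every mitochondrion survives
    assert not (out.labels[frag] > 0).any()
    removed_mask = (lv.labels > 0) & (out.labels == 0)
    assert not (removed_mask & mito).any()
    assert len(log.records[0].removed_ids) == truth.n_objects("membrane_fragment")


def test_variance_filter_idempotent(small_mito):
    spec, vol, _ = small_mito
    lv, _ = sg.bulk_segment(vol, spec.separating_range(),
                            min_voxels=10, min_volume_um3=None, max_variance=None)
    once, _ = sg.filter_intensity_variance(lv, vol, 400)
    twice, _ = sg.filter_intensity_variance(once, vol, 400)
    assert np.array_equal(once.labels, twice.labels)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def test_bulk_segment_equals_manual_composition(small_mito):
    spec, vol, _ = small_mito
    rng = spec.separating_range()
    auto, log = sg.bulk_segment(vol, rng, min_voxels=10, min_volume_um3=0.0002,
                                max_variance=400)
    mask = sg.threshold_range(vol, rng)
    manual = sg.connected_components(mask, 26, voxel_size=vol.voxel_size)
    manual, _ = sg.filter_min_size(manual, min_voxels=10, min_volume_um3=0.0002)
    manual, _ = sg.filter_intensity_variance(manual, vol, 400)
    assert np.array_equal(auto.labels, manual.labels)
    assert log.header["range"] == [rng.lo, rng.hi]
    # log ids refer to the raw numbering: disjoint across records
    ids = log.removed_ids()
    assert len(ids) == len(set(ids))


def test_bulk_segment_degenerate_ranges(small_mito):
    spec, vol, _ = small_mito
    # integer-valued phantom: an interval between integers selects nothing
    empty, _ = sg.bulk_segment(vol, IntensityRange(254.2, 254.8))
    assert empty.n_objects == 0
    raw_mask = sg.threshold_range(vol, spec.separating_range())
    raw = sg.connected_components(raw_mask, 26)
    nofilter, _ = sg.bulk_segment(vol, spec.separating_range(),
                                  min_voxels=None, min_volume_um3=None, max_variance=None)
    assert nofilter.n_objects == raw.n_objects
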