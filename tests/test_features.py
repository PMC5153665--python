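import numpy as np
import pytest

import sogseg as sg
from sogseg import LabelVolume, VolumeGrid
from sogseg.phantom import PhantomTruth, ObjectInfo, _rasterize_ellipsoid, _random_rotation


def _ellipsoid_labels(semi_axes_nm, voxel_nm=5.0, rotation=None, pad_nm=50.0):
    """Rasterise one solid ellipsoid on an isotropic grid as a label volume."""
    r = max(semi_axes_nm) + pad_nm
    n = int(np.ceil(2 * r / voxel_nm)) + 2
    shape = (n, n, n)
    center = np.full(3, n * voxel_nm / 2)
    rot = np.eye(3) if rotation is None else rotation
    sl, m = _rasterize_ellipsoid(shape, (voxel_nm,) * 3, center, semi_axes_nm, rot)
    labels = np.zeros(shape, dtype=np.int32)
    labels[sl][m] = 1
    return LabelVolume(labels, voxel_size=(voxel_nm,) * 3)


def _uniform_volume(labelvol, value=200.0):
    return VolumeGrid(np.full(labelvol.shape, value, dtype=np.float32),
                      voxel_size=labelvol.voxel_size)


# ---------------------------------------------------------------------------
# compute_features
# ---------------------------------------------------------------------------

def test_cutoff_scale_volume_of_ten_binned_voxels():
    labels = np.zeros((1, 2, 5), dtype=np.int32)
    labels[0, :, :] = 1
    lv = LabelVolume(labels, voxel_size=(50.0, 18.9, 18.9))
    rec = sg.compute_features(lv, _uniform_volume(lv))[0]
    assert rec.voxel_count == 10
    assert rec.volume_um3 == pytest.approx(1.786e-4, rel=1e-3)
    # rounds to the 0.0002 um3 cutoff scale at one significant figure
    assert float(f"{rec.volume_um3:.1g}") == 0.0002


def test_single_voxel_centroid_and_degenerate_axes():
    labels = np.zeros((5, 6, 7), dtype=np.int32)
    labels[2, 3, 4] = 1
    lv = LabelVolume(labels, voxel_size=(50.0, 10.0, 10.0))
    rec = sg.compute_features(lv, _uniform_volume(lv))[0]
    assert rec.centroid_um == pytest.approx((0.125, 0.035, 0.045))
    assert rec.principal_axis_lengths_um == pytest.approx((0.05, 0.01, 0.01))
    assert rec.aspect_ratio == pytest.approx(5.0)
    assert rec.intensity_variance == 0.0


def test_intensity_statistics():
    labels = np.zeros((1, 1, 4), dtype=np.int32)
    labels[0, 0, :] = 1
    lv = LabelVolume(labels, voxel_size=(10.0, 10.0, 10.0))
    vol = VolumeGrid(np.array([[[10.0, 20.0, 30.0, 40.0]]], dtype=np.float32),
                     voxel_size=(10.0, 10.0, 10.0))
    rec = sg.compute_features(lv, vol)[0]
    assert rec.intensity_mean == 25.0
    assert rec.intensity_min == 10.0 and rec.intensity_max == 40.0
    assert rec.intensity_variance == pytest.approx(125.0)  # population variance


def test_ellipsoid_axis_calibration_and_aspect_ratio():
    # solid ellipsoid semi-axes (200, 100, 100) nm on a 5 nm grid: >= 1e4 voxels
    lv = _ellipsoid_labels((200.0, 100.0, 100.0))
    rec = sg.compute_features(lv, _uniform_volume(lv))[0]
    assert rec.voxel_count >= 10_000
    assert rec.aspect_ratio == pytest.approx(2.0, abs=0.05)
    # lengths recover the full axes 2a within 5%
    assert rec.principal_axis_lengths_um[0] == pytest.approx(0.400, rel=0.05)
    assert rec.principal_axis_lengths_um[2] == pytest.approx(0.200, rel=0.05)
    assert np.linalg.norm(rec.orientation) == pytest.approx(1.0, abs=1e-9)


def test_rotation_consistency_on_isotropic_grid():
    rot = _random_rotation(np.random.default_rng(5))
    lv = _ellipsoid_labels((200.0, 100.0, 100.0), rotation=rot)
    rec = sg.compute_features(lv, _uniform_volume(lv))[0]
    # rotate the rasterised object 90 degrees about z: axis lengths invariant
    rotated = LabelVolume(np.rot90(lv.labels, axes=(1, 2)).copy(),
                          voxel_size=lv.voxel_size)
    rec2 = sg.compute_features(rotated, _uniform_volume(rotated))[0]
    for a, b in zip(rec.principal_axis_lengths_um, rec2.principal_axis_lengths_um):
        assert b == pytest.approx(a, rel=0.02)
    # orientation components permute (z stays, y/x swap up to sign)
    oz, oy, ox = rec.orientation
    rz, ry, rx = rec2.orientation
    assert abs(rz) == pytest.approx(abs(oz), abs=0.02)
    assert sorted([abs(ry), abs(rx)]) == pytest.approx(sorted([abs(oy), abs(ox)]), abs=0.02)


def test_volume_additivity_is_exact(small_mito):
    spec, vol, _ = small_mito
    lv, _ = sg.bulk_segment(vol, spec.separating_range(), min_voxels=None,
                            min_volume_um3=None, max_variance=None)
    records = sg.compute_features(lv, vol)
    total = sum(r.volume_um3 for r in records)
    expected = int((lv.labels > 0).sum()) * vol.voxel_volume_um3
    assert total == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# rank_by_volume
# ---------------------------------------------------------------------------

def _records_with_volumes(vols):
    labels = np.zeros((1, len(vols), max(int(v) for v in vols)), dtype=np.int32)
    for i, v in enumerate(vols):
        labels[0, i, : int(v)] = i + 1
    lv = LabelVolume(labels, voxel_size=(100.0, 100.0, 100.0))
    return sg.compute_features(lv, _uniform_volume(lv))


def test_rank_by_volume_normalised_index():
    ranked = sg.rank_by_volume(_records_with_volumes([2, 1, 3]))
    assert [r.object_id for r in ranked] == [2, 1, 3]
    assert [r.volume_index for r in ranked] == pytest.approx([0.0, 0.5, 1.0])


def test_rank_single_object_and_permutation_invariance():
    only = sg.rank_by_volume(_records_with_volumes([4]))
    assert only[0].volume_index == 0.0
    recs = _records_with_volumes([5, 2, 9, 7])
    fwd = {r.object_id: r.volume_index for r in sg.rank_by_volume(list(recs))}
    rev = {r.object_id: r.volume_index for r in sg.rank_by_volume(recs[::-1])}
    assert fwd == rev
    with pytest.raises(ValueError):
        sg.rank_by_volume([])


# ---------------------------------------------------------------------------
# evaluate_against_truth
# ---------------------------------------------------------------------------

def _truth_from_labels(labels, class_name="mitochondria"):
    truth = PhantomTruth(shape=labels.shape)
    truth.class_labels[class_name] = labels.astype(np.int32)
    for oid in np.unique(labels[labels > 0]):
        truth.catalogue.append(ObjectInfo(class_name, int(oid)))
    return truth


def test_evaluation_of_truth_against_itself_is_perfect(small_mito):
    spec, vol, truth = small_mito
    lv = LabelVolume(truth.class_labels["mitochondria"].copy(),
                     voxel_size=vol.voxel_size)
    rep = sg.evaluate_against_truth(lv, truth, "mitochondria", 0.5)
    assert rep.object_precision == 1.0 and rep.object_recall == 1.0
    assert rep.voxel_precision == 1.0 and rep.voxel_recall == 1.0
    assert all(m["rel_volume_error"] == 0.0 for m in rep.matches)


def test_half_coverage_matches_at_low_iou_threshold():
    tlab = np.zeros((1, 2, 10), dtype=np.int32)
    tlab[0, 0, :10] = 1
    tlab[0, 1, :4] = 2
    truth = _truth_from_labels(tlab)
    plab = np.zeros_like(tlab)
    plab[0, 0, :5] = 1  # half of truth object 1, nothing else
    lv = LabelVolume(plab, voxel_size=(10.0, 10.0, 10.0))
    rep = sg.evaluate_against_truth(lv, truth, "mitochondria", 0.4)
    assert len(rep.matches) == 1
    assert rep.matches[0]["iou"] == pytest.approx(0.5)
    assert rep.object_recall == pytest.approx(0.5)  # 1 of 2 truth objects
    assert rep.object_precision == 1.0
    strict = sg.evaluate_against_truth(lv, truth, "mitochondria", 0.6)
    assert len(strict.matches) == 0


def test_empty_prediction_convention():
    tlab = np.zeros((1, 1, 5), dtype=np.int32)
    tlab[0, 0, :3] = 1
    truth = _truth_from_labels(tlab)
    lv = LabelVolume(np.zeros_like(tlab), voxel_size=(10.0, 10.0, 10.0))
    rep = sg.evaluate_against_truth(lv, truth, "mitochondria", 0.5)
    assert rep.object_recall == 0.0
    assert rep.object_precision == 1.0
    assert rep.empty_prediction is True
    with pytest.raises(ValueError):
        sg.evaluate_against_truth(lv, truth, "mitochondria", 0.0)
    with pytest.raises(KeyError):
        sg.evaluate_against_truth(lv, truth, "no-such-class", 0.5)
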