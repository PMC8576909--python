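"""Preprocessing: windowing, parenchyma workflow, geometry, labeling rules."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lungnodule as ln
from lungnodule.volume import BinaryMask, CTVolume, NoduleAnnotation


# ---------------------------------------------------------------- windowing

def test_window_maps_bounds_and_midpoint():
    v = np.array([[[-1000.0, 400.0, -300.0, -2000.0, 900.0]]])
    out = ln.window_to_grayscale(v)
    assert out[0, 0, 0] == 0.0
    assert out[0, 0, 1] == 1.0
    assert out[0, 0, 2] == pytest.approx(0.5)
    assert out[0, 0, 3] == 0.0 and out[0, 0, 4] == 1.0  # clipped


def test_window_monotone_and_rejects_nonfinite(rng):
    hu = np.sort(rng.uniform(-1500, 900, size=64)).reshape(1, 1, 64)
    out = ln.window_to_grayscale(hu)
    assert np.all(np.diff(out[0, 0]) >= 0)
    bad = hu.copy()
    bad[0, 0, 3] = np.nan
    with pytest.raises(ValueError, match=r"\(0, 0, 3\)"):
        ln.window_to_grayscale(bad)
    with pytest.raises(ValueError, match="lo < hi"):
        ln.window_to_grayscale(hu, 100, 100)


# ------------------------------------------------------ parenchyma workflow

def test_parenchyma_mask_matches_phantom_truth(default_phantom):
    mask = ln.segment_lung_parenchyma(default_phantom.ct)
    assert ln.dice_coefficient(mask, default_phantom.lung_mask) >= 0.9


def test_parenchyma_fills_nodules_and_vessels(default_phantom):
    """Nodules are internal holes of the parenchyma and must be recovered."""
    mask = ln.segment_lung_parenchyma(default_phantom.ct).values.astype(bool)
    nod = default_phantom.nodule_mask.values.astype(bool)
    assert (mask & nod).sum() / nod.sum() > 0.8


def test_parenchyma_invariant_to_bed():
    cfg = ln.PhantomConfig(seed=13)
    with_bed = ln.generate_phantom(cfg)
    without = ln.generate_phantom(dataclasses.replace(cfg, include_bed=False))
    m1 = ln.segment_lung_parenchyma(with_bed.ct)
    m2 = ln.segment_lung_parenchyma(without.ct)
    assert np.array_equal(m1.values, m2.values)


def test_parenchyma_all_air_raises():
    ct = CTVolume(np.full((8, 32, 32), -1000.0), (3.0, 1.5, 1.5))
    with pytest.raises(ln.EmptyParenchymaError):
        ln.segment_lung_parenchyma(ct)


# ----------------------------------------------------------------- resample

def test_resample_identity_when_already_at_target(rng):
    ct = CTVolume(rng.normal(size=(16, 32, 32)).astype(np.float32), (3.0, 1.5, 1.5))
    out = ln.resample(ct)
    assert out.shape == ct.shape
    np.testing.assert_array_equal(out.values, ct.values)


def test_resample_output_shape_formula():
    assert ln.resample_output_shape((300, 512, 512), (1.0, 0.7, 0.7),
                                    (3.0, 1.5, 1.5)) == (100, 239, 239)
    with pytest.raises(ValueError):
        ln.resample_output_shape((10, 10, 10), (1, 1, 1), (0, 1, 1))


def test_resample_constant_volume_stays_constant():
    ct = CTVolume(np.full((30, 64, 64), 37.0, dtype=np.float32), (1.0, 0.7, 0.7))
    out = ln.resample(ct)
    assert out.shape == (10, 30, 30)
    np.testing.assert_allclose(out.values, 37.0, atol=1e-4)


def test_resample_mask_preserves_center_of_mass():
    mask = np.zeros((30, 60, 60), dtype=np.uint8)
    mask[12:18, 20:30, 33:43] = 1
    spacing, target = (1.0, 0.7, 0.7), (3.0, 1.5, 1.5)
    out = ln.resample_mask(BinaryMask(mask), spacing, target)
    assert set(np.unique(out.values)) <= {0, 1}
    com_in = np.array(np.argwhere(mask).mean(0)) * spacing
    com_out = np.array(np.argwhere(out.values).mean(0)) * target
    assert np.all(np.abs(com_in - com_out) <= np.array(target))


# ----------------------------------------------------------- subcase split

def test_split_even_depth_concatenation_recovers_input(rng):
    ct = CTVolume(rng.normal(size=(96, 192, 192)).astype(np.float32), (3.0, 1.5, 1.5))
    a, b, windows = ln.split_subcases(ct)
    assert a.shape == b.shape == (48, 192, 192)
    np.testing.assert_array_equal(np.concatenate([a.values, b.values]), ct.values)


def test_split_odd_depth_pads_with_air():
    ct = CTVolume(np.zeros((90, 192, 192), dtype=np.float32), (3.0, 1.5, 1.5))
    a, b, _ = ln.split_subcases(ct)
    for half in (a, b):
        assert half.shape == (48, 192, 192)
        pad_slices = int(np.sum(np.all(half.values == -1000.0, axis=(1, 2))))
        assert pad_slices == 3


def test_split_window_round_trip_is_identity(rng):
    ct = CTVolume(rng.normal(size=(80, 100, 150)).astype(np.float32), (3.0, 1.5, 1.5))
    _, _, windows = ln.split_subcases(ct)
    for w in windows:
        for voxel in [(0, 0, 0), (10, 20, 30), (47, 191, 191)]:
            assert w.to_crop(w.to_case(voxel)) == tuple(voxel)


# ---------------------------------------------------------------- crop_roi

def _component_at(shape, voxels):
    m = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        m[v] = 1
    return BinaryMask(m)


def test_crop_roi_centered_on_single_voxel(rng):
    ct = CTVolume(rng.normal(size=(48, 96, 96)).astype(np.float32), (3.0, 1.5, 1.5))
    roi, win = ln.crop_roi(ct, _component_at(ct.shape, [(24, 48, 48)]))
    assert roi.shape == (16, 48, 48)
    assert win.start == (24 - 8, 48 - 24, 48 - 24)
    np.testing.assert_array_equal(roi.values,
                                  ct.values[16:32, 24:72, 24:72])


def test_crop_roi_near_corner_pads_with_air(rng):
    ct = CTVolume(rng.uniform(0, 100, size=(48, 96, 96)).astype(np.float32),
                  (3.0, 1.5, 1.5))
    roi, win = ln.crop_roi(ct, _component_at(ct.shape, [(1, 2, 2)]))
    assert roi.shape == (16, 48, 48)
    n_pad = int(np.sum(roi.values == -1000.0))
    # overhang: 7 slices in z, 22 rows in y, 22 cols in x
    expected = 16 * 48 * 48 - (16 - 7) * (48 - 22) * (48 - 22)
    assert n_pad == expected


def test_crop_roi_translation_equivariance(rng):
    ct = CTVolume(rng.normal(size=(48, 96, 96)).astype(np.float32), (3.0, 1.5, 1.5))
    _, w1 = ln.crop_roi(ct, _component_at(ct.shape, [(20, 40, 40), (22, 44, 44)]))
    _, w2 = ln.crop_roi(ct, _component_at(ct.shape, [(22, 44, 44), (24, 48, 48)]))
    assert tuple(np.subtract(w2.start, w1.start)) == (2, 4, 4)
    with pytest.raises(ValueError, match="empty"):
        ln.crop_roi(ct, _component_at(ct.shape, []))


# ----------------------------------------------------------- consensus mask

def _ann(rater, mask, level=3):
    return NoduleAnnotation(rater_id=rater, malignancy_level=level,
                            mask=BinaryMask(mask.astype(np.uint8)))


def test_consensus_requires_three_of_four_raters():
    shape = (4, 8, 8)
    votes3 = np.zeros(shape); votes3[2, 4, 4] = 1
    votes2 = np.zeros(shape); votes2[1, 2, 2] = 1
    anns = [_ann(0, votes3), _ann(1, votes3), _ann(2, votes3),
            _ann(2, votes2), _ann(3, votes2)]  # rater 2 marks both voxels
    out = ln.consensus_mask(anns, min_raters=3).values
    assert out[2, 4, 4] == 1          # marked by raters 0,1,2
    assert out[1, 2, 2] == 0          # marked by raters 2,3 only


def test_consensus_min_raters_one_is_union(rng):
    shape = (4, 8, 8)
    masks = [(rng.random(shape) < 0.3) for _ in range(4)]
    anns = [_ann(i, m) for i, m in enumerate(masks)]
    out = ln.consensus_mask(anns, min_raters=1).values.astype(bool)
    union = np.logical_or.reduce(masks)
    np.testing.assert_array_equal(out, union)


@given(st.integers(0, 2 ** 32 - 1))
def test_consensus_antitone_in_min_raters(seed):
    r = np.random.default_rng(seed)
    anns = [_ann(i, r.random((3, 6, 6)) < 0.4) for i in range(4)]
    prev = None
    for k in (1, 2, 3, 4):
        cur = ln.consensus_mask(anns, min_raters=k).values.astype(bool)
        if prev is not None:
            assert np.all(cur <= prev)
        prev = cur


def test_consensus_rejects_mixed_grids():
    with pytest.raises(ValueError, match="grid"):
        ln.consensus_mask([_ann(0, np.zeros((2, 4, 4))),
                           _ann(1, np.zeros((2, 4, 5)))])


# ------------------------------------------------------------------ labels

@pytest.mark.parametrize("levels,expected", [
    ([1, 2, 2, 1], "benign"),
    ([5, 4, 4], "malignant"),
    ([3], "excluded"),
    ([2, 4], "benign"),        # median tie rounds down
    ([3, 3, 4, 4], "excluded"),
    ([4, 4, 5, 5], "malignant"),
])
def test_malignancy_label_rules(levels, expected):
    assert ln.malignancy_label(levels) == expected


def test_malignancy_label_rejects_bad_input():
    with pytest.raises(ValueError):
        ln.malignancy_label([])
    with pytest.raises(ValueError):
        ln.malignancy_label([0, 3])


@pytest.mark.parametrize("d,cat", [
    (5.0, "micro"), (3.0, "micro"),
    (5.1, "small"), (10.0, "small"),
    (10.1, "nodule"), (30.0, "nodule"),
    (30.1, "mass"), (35.0, "mass"),
])
def test_size_category_bin_edges(d, cat):
    assert ln.size_category(d) is ln.SizeCategory(cat)


def test_size_category_rejects_nonpositive():
    with pytest.raises(ValueError):
        ln.size_category(0.0)
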