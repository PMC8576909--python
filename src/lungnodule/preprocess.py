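"""CT preprocessing: lung window, parenchyma extraction, geometry, labels.

The parenchyma workflow follows the classic threshold-and-repair recipe:
binarize at a fixed Hounsfield cut, delete ambient air and anything
outside the body, keep the lungs as the largest remaining low-density
components, fill internal holes slicewise and close the boundary
morphologically.  Geometry helpers implement the fixed training layout:
resampling to 3 x 1.5 x 1.5 mm, splitting a case into two 48x192x192
subcases, and cropping 16x48x48 classification ROIs.  Labeling rules
aggregate multi-rater annotations into a consensus mask (>= 3 raters),
a benign/malignant/excluded label (median level; 1-2 benign, 4-5
malignant, 3 excluded) and the four diameter size bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, CTVolume, NoduleAnnotation, SizeCategory

#: fixed binarization cut separating lung/air from soft tissue
BINARIZE_HU = -320.0
#: lung-window bounds
WINDOW_LO_HU, WINDOW_HI_HU = -1000.0, 400.0
#: morphological repair radius (closing), millimetres
CLOSING_RADIUS_MM = 4.5
PAD_HU = -1000.0
SUBCASE_SHAPE = (48, 192, 192)
ROI_SHAPE = (16, 48, 48)


class EmptyParenchymaError(RuntimeError):
    def __init__(self, n_low, n_candidates):
        super().__init__(
            f"no lung component found ({n_low} low-density voxels, "
            f"{n_candidates} candidate components)")
        self.n_low = n_low
        self.n_candidates = n_candidates


def window_to_grayscale(ct, lo_hu: float = WINDOW_LO_HU, hi_hu: float = WINDOW_HI_HU):
    """Affine map of clipped HU onto [0, 1] (the lung display window)."""
    if lo_hu >= hi_hu:
        raise ValueError(f"window bounds must satisfy lo < hi, got {lo_hu} >= {hi_hu}")
    v = np.asarray(getattr(ct, "values", ct), dtype=np.float64)
    if not np.all(np.isfinite(v)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(v))[0])
        raise ValueError(f"non-finite voxel at index {idx}")
    return ((np.clip(v, lo_hu, hi_hu) - lo_hu) / (hi_hu - lo_hu)).astype(np.float32)


def _ellipsoid_structure(radius_mm, spacing_mm):
    semi = [max(1, int(round(radius_mm / s))) for s in spacing_mm]
    grids = np.meshgrid(*[np.arange(-a, a + 1) / a for a in semi], indexing="ij")
    return sum(g * g for g in grids) <= 1.0


def segment_lung_parenchyma(ct: CTVolume) -> BinaryMask:
    """Extract the lung parenchyma mask from a chest CT volume."""
    if ct.shape[0] < 2:
        raise ValueError("need at least 2 axial slices")
    low = ct.values < BINARIZE_HU
    n_low = int(low.sum())

    # (1) drop low-density components 6-connected to any volume face (ambient air)
    lab, n = ndimage.label(low)
    border = set()
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(lab, sl, axis=ax)
            border.update(np.unique(face[face > 0]).tolist())
    interior = np.isin(lab, [i for i in range(1, n + 1) if i not in border]) & low

    # (2) drop components outside the body (e.g. the air gap under the bed):
    # the body is the filled high-density region; keep components mostly inside it.
    body = ~low
    body_lab, bn = ndimage.label(body)
    if bn > 0:
        sizes = ndimage.sum_labels(np.ones_like(body_lab), body_lab, range(1, bn + 1))
        body = body_lab == (1 + int(np.argmax(sizes)))
    body_filled = np.stack([ndimage.binary_fill_holes(s) for s in body])
    lab2, n2 = ndimage.label(interior)
    keep = []
    for i in range(1, n2 + 1):
        comp = lab2 == i
        inside = float((comp & body_filled).sum()) / float(comp.sum())
        if inside >= 0.5:
            keep.append((int(comp.sum()), i))

    if not keep:
        raise EmptyParenchymaError(n_low, n2)

    # (3) largest one-or-two components are the lungs; the second is kept
    # only if it is at least 10% of the first (separate left/right lobes)
    keep.sort(reverse=True)
    ids = [keep[0][1]]
    if len(keep) > 1 and keep[1][0] >= 0.1 * keep[0][0]:
        ids.append(keep[1][1])
    lungs = np.isin(lab2, ids)

    # (4) fill internal holes (vessels, nodules) per axial slice
    lungs = np.stack([ndimage.binary_fill_holes(s) for s in lungs])

    # (5) morphological closing to repair the boundary
    structure = _ellipsoid_structure(CLOSING_RADIUS_MM, ct.spacing_mm)
    lungs = ndimage.binary_closing(lungs, structure=structure)

    return BinaryMask(lungs.astype(np.uint8))


def resample_output_shape(shape, spacing_mm, target_spacing_mm):
    """round(shape * spacing / target) per axis, at least 1 voxel."""
    target = np.array([float(t) for t in target_spacing_mm])
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {tuple(target)}")
    out = np.round(np.array(shape) * np.array(spacing_mm) / target)
    return tuple(int(v) for v in np.maximum(1, out))


def resample(ct: CTVolume, target_spacing_mm=(3.0, 1.5, 1.5), *, is_mask=False) -> CTVolume:
    """Resample to a common spacing; trilinear for intensities, nearest for masks."""
    target = tuple(float(t) for t in target_spacing_mm)
    in_shape = np.array(ct.shape, dtype=float)
    spacing = np.array(ct.spacing_mm, dtype=float)
    out_shape = np.array(resample_output_shape(ct.shape, ct.spacing_mm, target))
    if tuple(out_shape) == ct.shape and np.allclose(spacing, target):
        return CTVolume(ct.values.copy(), target, ct.origin)
    zoom = out_shape / in_shape
    out = ndimage.zoom(ct.values.astype(np.float32), zoom,
                       order=0 if is_mask else 1, mode="nearest", grid_mode=True)
    out = out[:out_shape[0], :out_shape[1], :out_shape[2]]
    return CTVolume(out, target, ct.origin)


def resample_mask(mask: BinaryMask, spacing_mm, target_spacing_mm=(3.0, 1.5, 1.5)) -> BinaryMask:
    ct = CTVolume(mask.values.astype(np.float32), spacing_mm)
    out = resample(ct, target_spacing_mm, is_mask=True)
    return BinaryMask((out.values > 0.5).astype(np.uint8))


@dataclass(frozen=True)
class CropWindow:
    """Half-open crop window: voxel v of the crop sits at case voxel v + start."""

    start: tuple[int, int, int]
    shape: tuple[int, int, int]

    def to_case(self, voxel):
        return tuple(int(v) + s for v, s in zip(voxel, self.start))

    def to_crop(self, voxel):
        return tuple(int(v) - s for v, s in zip(voxel, self.start))


def _crop_with_pad(values, start, shape, pad_value):
    out = np.full(shape, pad_value, dtype=values.dtype)
    src, dst = [], []
    for ax in range(3):
        s0 = start[ax]
        src_lo, src_hi = max(0, s0), min(values.shape[ax], s0 + shape[ax])
        if src_lo >= src_hi:
            return out  # window entirely outside
        src.append(slice(src_lo, src_hi))
        dst.append(slice(src_lo - s0, src_hi - s0))
    out[tuple(dst)] = values[tuple(src)]
    return out


def split_subcases(ct: CTVolume, subcase_shape=SUBCASE_SHAPE):
    """Split a case along the axial axis into two fixed-size subcases.

    Returns (subcase0, subcase1, windows) where each window records the
    case-coordinate offset of the subcase origin, so mask coordinates map
    back exactly.  Voxels outside the half (or in-plane outside the case)
    are padded with -1000 HU (air); crops are centered.
    """
    d, h, w = ct.shape
    td, th, tw = subcase_shape
    split = (d + 1) // 2
    subs, windows = [], []
    for z0, z1 in ((0, split), (split, d)):
        half = ct.values[z0:z1]
        start_rel = tuple((s - t) // 2 for s, t in zip(half.shape, subcase_shape))
        vals = _crop_with_pad(half, start_rel, subcase_shape,
                              np.asarray(PAD_HU, ct.values.dtype))
        subs.append(CTVolume(vals, ct.spacing_mm, ct.origin))
        windows.append(CropWindow((z0 + start_rel[0], start_rel[1], start_rel[2]),
                                  subcase_shape))
    return subs[0], subs[1], windows


def crop_roi(ct: CTVolume, nodule_component: BinaryMask, roi_shape=ROI_SHAPE):
    """Crop the classification ROI centered on a nodule component.

    The window is centered on the component's rounded voxel centroid and
    padded with -1000 HU where it overhangs the volume.  Returns
    (roi: CTVolume, window: CropWindow).
    """
    coords = np.argwhere(np.asarray(nodule_component.values, dtype=bool))
    if coords.size == 0:
        raise ValueError("empty nodule component")
    centroid = np.round(coords.mean(axis=0)).astype(int)
    start = tuple(int(c) - s // 2 for c, s in zip(centroid, roi_shape))
    vals = _crop_with_pad(ct.values, start, roi_shape,
                          np.asarray(PAD_HU, ct.values.dtype))
    return CTVolume(vals, ct.spacing_mm, ct.origin), CropWindow(start, tuple(roi_shape))


def consensus_mask(annotations: list[NoduleAnnotation], min_raters: int = 3) -> BinaryMask:
    """Voxels marked by at least ``min_raters`` distinct raters."""
    if not annotations:
        raise ValueError("no annotations")
    shapes = {a.mask.shape for a in annotations if a.mask is not None}
    if len(shapes) != 1 or any(a.mask is None for a in annotations):
        raise ValueError(f"annotation masks must share one grid, got shapes {shapes}")
    shape = shapes.pop()
    by_rater: dict[int, np.ndarray] = {}
    for a in annotations:
        m = a.mask.values.astype(bool)
        by_rater[a.rater_id] = by_rater.get(a.rater_id, np.zeros(shape, bool)) | m
    votes = np.zeros(shape, dtype=np.int32)
    for m in by_rater.values():
        votes += m
    return BinaryMask((votes >= min_raters).astype(np.uint8))


def malignancy_label(levels: list[int]) -> str:
    """Median rater level (ties round down): <=2 benign, >=4 malignant, else excluded."""
    if not levels:
        raise ValueError("empty level list")
    if any(l not in (1, 2, 3, 4, 5) for l in levels):
        raise ValueError(f"levels must be in 1..5, got {levels}")
    med = sorted(levels)[(len(levels) - 1) // 2]  # lower median
    if med <= 2:
        return "benign"
    if med >= 4:
        return "malignant"
    return "excluded"


def size_category(diameter_mm: float) -> SizeCategory:
    """Diameter bins: d<=5 micro, 5<d<=10 small, 10<d<=30 nodule, 30<d mass."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    if diameter_mm <= 5:
        return SizeCategory.MICRO
    if diameter_mm <= 10:
        return SizeCategory.SMALL
    if diameter_mm <= 30:
        return SizeCategory.NODULE
    return SizeCategory.MASS
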