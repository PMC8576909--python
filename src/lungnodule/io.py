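"""Volume I/O (NIfTI canonical, DICOM input-only), annotations, manifests.

On-disk convention: NIfTI arrays are stored in (axial, coronal,
sagittal) index order with an affine whose diagonal carries the voxel
spacing in the same order, so a write/read round trip preserves both the
array and the spacing exactly.  DICOM series are read slice-by-slice,
sorted by image position along the slice normal, with rescale
slope/intercept applied to obtain Hounsfield units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .volume import CTVolume, BinaryMask, NoduleAnnotation

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def write_volume(ct: CTVolume, path) -> Path:
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(ct.spacing_mm) + [1.0])
    values = ct.values
    if values.dtype.kind in "ui" or (
            values.dtype.kind == "f" and np.all(values == np.round(values))
            and np.abs(values).max(initial=0) < 3e4):
        data = np.round(values).astype(np.int16)
    else:
        data = values.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(ct.spacing_mm)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid voxel spacing in {path}: zooms={zooms}")
    values = np.asanyarray(img.dataobj).astype(np.float32)
    return CTVolume(values, tuple(float(z) for z in zooms))


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM slices found in {directory}")
    for ds in slices:
        for attr in ("ImagePositionPatient", "PixelSpacing"):
            if getattr(ds, attr, None) is None:
                raise ValueError(f"missing {attr} in {directory}")
    # sort along the slice normal (z component of image position)
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise ValueError("duplicate or unsorted slice positions")
        if np.ptp(dz) > 1e-3:
            raise ValueError(f"inconsistent DICOM slice spacing (range {np.ptp(dz):.4g} mm)")
        slice_dz = float(dz.mean())
    else:
        slice_dz = float(getattr(slices[0], "SliceThickness", 0) or 0)
        if slice_dz <= 0:
            raise ValueError("cannot determine slice spacing from a single slice")
    ps = [float(v) for v in slices[0].PixelSpacing]
    vol = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        vol.append(arr * slope + intercept)
    values = np.stack(vol)  # (z, row=y, col=x)
    return CTVolume(values, (slice_dz, ps[0], ps[1]))


def read_volume(path) -> CTVolume:
    """Read a NIfTI file or a DICOM series directory into HU + spacing."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if _is_nifti(path):
        return _read_nifti(path)
    raise ValueError(f"unsupported volume path: {path}")


def read_mask(path) -> BinaryMask:
    ct = read_volume(path)
    return BinaryMask((ct.values > 0.5).astype(np.uint8))


def write_annotations(path, annotations: list[NoduleAnnotation]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(json.dumps({
                "nodule_id": a.nodule_id,
                "rater_id": a.rater_id,
                "center_voxel": list(a.center_voxel) if a.center_voxel else None,
                "diameter_mm": a.diameter_mm,
                "malignancy_level": a.malignancy_level,
            }) + "\n")
    return path


def read_annotations(path) -> list[NoduleAnnotation]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(NoduleAnnotation(
            rater_id=rec["rater_id"],
            malignancy_level=rec["malignancy_level"],
            center_voxel=tuple(rec["center_voxel"]) if rec.get("center_voxel") else None,
            diameter_mm=rec.get("diameter_mm"),
            nodule_id=rec.get("nodule_id", 0),
        ))
    return out


@dataclass
class CaseRecord:
    case_id: str
    ct_path: str
    lung_mask_path: str | None = None
    nodule_mask_path: str | None = None
    annotations_path: str | None = None
    split: str | None = None
    provenance: str | None = None
    flags: list[str] = field(default_factory=list)


def manifest(cohort_dir, write: bool = True) -> list[CaseRecord]:
    """Validated, deterministically ordered manifest of a cohort directory.

    Cases with missing masks/annotations are kept but flagged.
    """
    cohort_dir = Path(cohort_dir)
    records = []
    for d in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        ct = d / "ct.nii.gz"
        if not ct.exists():
            continue
        rec = CaseRecord(case_id=d.name, ct_path=str(ct))
        for attr, fname in (("lung_mask_path", "lung_mask.nii.gz"),
                            ("nodule_mask_path", "nodule_mask.nii.gz"),
                            ("annotations_path", "annotations.jsonl")):
            p = d / fname
            if p.exists():
                setattr(rec, attr, str(p))
            else:
                rec.flags.append(f"missing:{fname}")
        meta = d / "meta.json"
        if meta.exists():
            rec.provenance = f"seed={json.loads(meta.read_text()).get('seed')}"
        records.append(rec)
    ids = [r.case_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate case ids in cohort")
    if write:
        (cohort_dir / "manifest.json").write_text(
            json.dumps([asdict(r) for r in records], indent=1))
    return records
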