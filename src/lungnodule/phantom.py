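"""Synthetic 3-D CT phantoms with known lung and nodule ground truth.

A phantom emulates the geometry a chest CT presents to the parenchyma
workflow: an elliptical soft-tissue body (~+40 HU) surrounded by air
(~-1000 HU), two low-attenuation lung lobes (~-850 HU), an optional
scanner-bed slab (~+200 HU) posterior to the body, optional bright
tubular vessels (~+50 HU) inside the lungs, and soft-tissue nodules
(-100..+100 HU) painted either as smooth spheres (benign trait) or as
spiculated blobs with radial spikes and an irregular boundary
(malignant trait).  Gaussian noise is added last; the returned masks are
exactly the painted geometry.

The generator is deterministic: identical config (including seed) gives
bit-identical volumes.  It makes no attempt at realistic texture,
beam hardening or scanner artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, CTVolume, NoduleAnnotation

HU_AIR = -1000.0
HU_BODY = 40.0
HU_LUNG = -850.0
HU_BED = 200.0
HU_VESSEL = 50.0
HU_NODULE_RANGE = (-100.0, 100.0)

N_RATERS = 4
MAX_PLACEMENT_RETRIES = 100


class PlacementError(RuntimeError):
    """Raised when a nodule cannot be placed inside a lung."""

    def __init__(self, seed, index, msg):
        super().__init__(f"nodule {index} (seed {seed}): {msg}")
        self.seed = seed
        self.index = index


@dataclass(frozen=True)
class PhantomConfig:
    volume_shape: tuple[int, int, int] = (48, 192, 192)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 1.5, 1.5)
    n_nodules: int = 2
    diameter_range_mm: tuple[float, float] = (6.0, 25.0)
    malignant_fraction: float = 0.5
    noise_sd_hu: float = 20.0
    include_bed: bool = True
    include_vessels: bool = True
    seed: int = 0

    def validate(self):
        if len(self.volume_shape) != 3 or any(s < 16 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be 3 values >= 16, got {self.volume_shape}")
        lo, hi = self.diameter_range_mm
        if not (0 < lo <= hi <= 60):
            raise ValueError(f"diameter_range_mm must lie in (0, 60], got {self.diameter_range_mm}")
        if not (0 <= self.malignant_fraction <= 1):
            raise ValueError("malignant_fraction must be in [0, 1]")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be non-negative")


@dataclass
class PhantomSample:
    ct: CTVolume
    lung_mask: BinaryMask
    nodule_mask: BinaryMask
    annotations: list[NoduleAnnotation]
    per_nodule_diameter_mm: list[float]
    per_nodule_malignant: list[bool]
    config: PhantomConfig | None = None


def _mm_grids(shape, spacing):
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(grids, center_mm, semi_mm):
    z, y, x = grids
    cz, cy, cx = center_mm
    az, ay, ax = semi_mm
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def _paint_vessels(rng, lung_mask, spacing, n_range=(4, 8)):
    """Random bright tubes inside the lungs: polyline of sphere stamps."""
    vessel = np.zeros_like(lung_mask)
    coords = np.argwhere(lung_mask)
    if coords.size == 0:
        return vessel
    extent = np.array(lung_mask.shape) * np.array(spacing)
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    for _ in range(n):
        start = coords[rng.integers(len(coords))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length_mm = 0.35 * float(extent.min())
        radius_mm = float(rng.uniform(1.0, 2.0))
        step_mm = min(spacing) / 2.0
        n_steps = max(2, int(length_mm / step_mm))
        rz, ry, rx = [max(1, int(round(radius_mm / s))) for s in spacing]
        for t in range(n_steps):
            p = start + direction * (t * step_mm) / np.array(spacing)
            z, y, x = np.round(p).astype(int)
            if not (0 <= z < vessel.shape[0] and 0 <= y < vessel.shape[1]
                    and 0 <= x < vessel.shape[2]):
                break
            vessel[max(0, z - rz):z + rz + 1,
                   max(0, y - ry):y + ry + 1,
                   max(0, x - rx):x + rx + 1] = True
    vessel &= lung_mask
    return vessel


def _nodule_voxels(rng, shape, spacing, center_vox, radius_mm, malignant):
    """Boolean stamp of one nodule within a local bounding box."""
    reach = radius_mm * (1.35 if malignant else 1.0)
    lo = [max(0, int(np.floor(c - reach / s)) - 1) for c, s in zip(center_vox, spacing)]
    hi = [min(n, int(np.ceil(c + reach / s)) + 2)
          for c, s, n in zip(center_vox, spacing, shape)]
    axes = [(np.arange(a, b) - c) * s for a, b, c, s in zip(lo, hi, center_vox, spacing)]
    dz, dy, dx = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt(dz * dz + dy * dy + dx * dx)
    if not malignant:
        stamp = rho <= radius_mm
    else:
        base = 0.88 * radius_mm
        # low-frequency boundary irregularity
        w = rng.normal(size=(3, 3))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        with np.errstate(invalid="ignore", divide="ignore"):
            uz, uy, ux = dz / rho, dy / rho, dx / rho
        uz, uy, ux = (np.nan_to_num(a) for a in (uz, uy, ux))
        pert = np.zeros_like(rho)
        for j in range(3):
            proj = uz * w[j, 0] + uy * w[j, 1] + ux * w[j, 2]
            pert += np.sin(3.0 * proj * np.pi + phase[j])
        stamp = rho <= base * (1.0 + 0.06 * pert)
        # radial spikes out to ~1.3 of the base radius
        n_spikes = int(rng.integers(4, 11))
        dirs = rng.normal(size=(n_spikes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        tip = 1.3 * base
        shell = (rho > base) & (rho <= tip)
        if shell.any():
            frac = np.clip((rho - base) / (tip - base), 0, 1)
            cos_cut = 0.88 + 0.12 * frac  # cone narrows toward the tip
            hit = np.zeros_like(shell)
            for d in dirs:
                cosang = uz * d[0] + uy * d[1] + ux * d[2]
                hit |= shell & (cosang >= cos_cut)
            stamp |= hit
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2])), stamp


def _rater_annotations(rng, nodule_id, comp_mask, center_vox, diameter_mm, malignant):
    """Four raters: slightly perturbed masks and a 1-5 malignancy level."""
    anns = []
    level_choices = ([3, 4, 5], [0.1, 0.45, 0.45]) if malignant else \
                    ([1, 2, 3], [0.45, 0.45, 0.1])
    for rater in range(N_RATERS):
        tweak = int(rng.integers(-1, 2))  # erode, keep, or dilate by one voxel
        m = comp_mask
        if tweak == 1:
            m = ndimage.binary_dilation(comp_mask)
        elif tweak == -1:
            er = ndimage.binary_erosion(comp_mask)
            m = er if er.any() else comp_mask
        level = int(rng.choice(level_choices[0], p=level_choices[1]))
        anns.append(NoduleAnnotation(
            rater_id=rater,
            malignancy_level=level,
            mask=BinaryMask(m.astype(np.uint8)),
            center_voxel=tuple(int(c) for c in np.round(center_vox)),
            diameter_mm=float(diameter_mm),
            nodule_id=nodule_id,
        ))
    return anns


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom volume with exact lung/nodule ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape)
    spacing = tuple(config.voxel_spacing_mm)
    extent = np.array(shape) * np.array(spacing)
    center = extent / 2.0
    grids = _mm_grids(shape, spacing)

    body = _ellipsoid(grids, center, (0.46 * extent[0], 0.40 * extent[1], 0.46 * extent[2]))
    lung_semi = (0.36 * extent[0], 0.28 * extent[1], 0.20 * extent[2])
    lungs = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = (center[0], center[1] - 0.02 * extent[1], center[2] + side * 0.23 * extent[2])
        lungs |= _ellipsoid(grids, c, lung_semi)
    # keep a soft-tissue shell around the lungs so they never touch outside air
    lungs &= ndimage.binary_erosion(body, iterations=2)

    hu = np.full(shape, HU_AIR, dtype=np.float32)
    hu[body] = HU_BODY
    hu[lungs] = HU_LUNG

    if config.include_bed:
        y_mm = np.arange(shape[1]) * spacing[1]
        bed_rows = (y_mm > center[1] + 0.43 * extent[1]) & (y_mm <= center[1] + 0.47 * extent[1])
        bed = np.zeros(shape, dtype=bool)
        bed[:, bed_rows, :] = True
        bed &= ~body
        hu[bed] = HU_BED

    if config.include_vessels:
        vessels = _paint_vessels(rng, lungs, spacing)
        hu[vessels] = HU_VESSEL

    # distance (mm) to the lung boundary, for nodule placement margins
    dist_mm = ndimage.distance_transform_edt(lungs, sampling=spacing)

    nodule_mask = np.zeros(shape, dtype=bool)
    annotations: list[NoduleAnnotation] = []
    diameters: list[float] = []
    traits: list[bool] = []
    for i in range(config.n_nodules):
        malignant = bool(rng.random() < config.malignant_fraction)
        d_mm = float(rng.uniform(*config.diameter_range_mm))
        r_mm = d_mm / 2.0
        margin = min(1.2 * r_mm, r_mm + 3.0) if malignant else r_mm
        eligible = np.argwhere(dist_mm >= margin)
        if len(eligible) == 0:
            raise PlacementError(config.seed, i,
                                 f"no lung voxel has clearance {margin:.1f} mm "
                                 f"for a {d_mm:.1f} mm nodule")
        placed = False
        for _ in range(MAX_PLACEMENT_RETRIES):
            center_vox = eligible[rng.integers(len(eligible))].astype(float)
            sl, stamp = _nodule_voxels(rng, shape, spacing, center_vox, r_mm, malignant)
            stamp &= lungs[sl]  # clip spikes; guarantees nodule_mask subset of lung
            if not stamp.any():
                continue
            if (nodule_mask[sl] & stamp).any():
                continue  # overlap with an earlier nodule
            nodule_mask[sl] |= stamp
            hu_val = float(rng.uniform(*HU_NODULE_RANGE))
            region = hu[sl]
            region[stamp] = hu_val
            comp = np.zeros(shape, dtype=bool)
            comp[sl] = stamp
            annotations.extend(
                _rater_annotations(rng, i, comp, center_vox, d_mm, malignant))
            diameters.append(d_mm)
            traits.append(malignant)
            placed = True
            break
        if not placed:
            raise PlacementError(config.seed, i,
                                 f"placement failed after {MAX_PLACEMENT_RETRIES} retries")

    if config.noise_sd_hu > 0:
        hu += rng.normal(0.0, config.noise_sd_hu, size=shape).astype(np.float32)

    return PhantomSample(
        ct=CTVolume(hu, spacing),
        lung_mask=BinaryMask(lungs.astype(np.uint8)),
        nodule_mask=BinaryMask(nodule_mask.astype(np.uint8)),
        annotations=annotations,
        per_nodule_diameter_mm=diameters,
        per_nodule_malignant=traits,
        config=config,
    )


def generate_cohort(n_samples: int, config: PhantomConfig) -> list[PhantomSample]:
    """Independent samples with per-sample seeds derived from config.seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_samples) % (2 ** 31)
    return [generate_phantom(replace(config, seed=int(s))) for s in seeds]


def equivalent_sphere_diameter_mm(voxel_count: int, spacing_mm) -> float:
    """Diameter of the sphere whose volume matches the voxel count."""
    vol = voxel_count * float(np.prod(spacing_mm))
    return float((6.0 * vol / np.pi) ** (1.0 / 3.0))


def save_sample(sample: PhantomSample, out_dir, case_id: str):
    """Write ct/lung_mask/nodule_mask as NIfTI plus JSON-lines annotations."""
    from .io import write_volume  # local import to avoid a cycle

    d = Path(out_dir) / case_id
    d.mkdir(parents=True, exist_ok=True)
    write_volume(sample.ct, d / "ct.nii.gz")
    sp = sample.ct.spacing_mm
    write_volume(CTVolume(sample.lung_mask.values.astype(np.float32), sp),
                 d / "lung_mask.nii.gz")
    write_volume(CTVolume(sample.nodule_mask.values.astype(np.float32), sp),
                 d / "nodule_mask.nii.gz")
    with open(d / "annotations.jsonl", "w") as fh:
        for a in sample.annotations:
            fh.write(json.dumps({
                "nodule_id": a.nodule_id,
                "rater_id": a.rater_id,
                "center_voxel": list(a.center_voxel),
                "diameter_mm": a.diameter_mm,
                "malignancy_level": a.malignancy_level,
            }) + "\n")
    meta = {
        "case_id": case_id,
        "seed": sample.config.seed if sample.config else None,
        "per_nodule_diameter_mm": sample.per_nodule_diameter_mm,
        "per_nodule_malignant": sample.per_nodule_malignant,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d
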