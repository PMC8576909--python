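"""Core volumetric data types.

Axis convention throughout the package: arrays are indexed
``(axial, coronal, sagittal)`` i.e. (slice z, row y, column x), 0-based,
with voxel spacing given in millimetres in the same order.  Crop windows
are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


@dataclass
class CTVolume:
    """A 3-D scalar field in Hounsfield units with anisotropic spacing."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            idx = tuple(int(i) for i in np.argwhere(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite voxel at index {idx}")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class BinaryMask:
    """A {0,1} field aligned voxelwise to a CTVolume."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={v.ndim}")
        if not np.isin(np.unique(v), (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = v.astype(np.uint8)

    @property
    def shape(self):
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class NoduleAnnotation:
    """One rater's record of one nodule.

    Either a contour ``mask`` or a ``(center_voxel, diameter_mm)`` pair is
    given; ``malignancy_level`` follows the 5-point scale (1 clearly
    benign .. 5 clearly malignant).
    """

    rater_id: int
    malignancy_level: int
    mask: BinaryMask | None = None
    center_voxel: tuple[int, int, int] | None = None
    diameter_mm: float | None = None
    nodule_id: int = 0

    def __post_init__(self):
        if self.malignancy_level not in (1, 2, 3, 4, 5):
            raise ValueError(f"malignancy_level must be 1..5, got {self.malignancy_level}")
        if self.mask is None and (self.center_voxel is None or self.diameter_mm is None):
            raise ValueError("annotation needs a mask or (center_voxel, diameter_mm)")


class SizeCategory(Enum):
    """Diameter bins: micro d<=5, small 5<d<=10, nodule 10<d<=30, mass 30<d (mm)."""

    MICRO = "micro"
    SMALL = "small"
    NODULE = "nodule"
    MASS = "mass"


@dataclass
class ClassProbabilities:
    """Two-way (benign, malignant) probability vector; ties label malignant."""

    p_benign: float
    p_malignant: float

    def __post_init__(self):
        if self.p_benign < 0 or self.p_malignant < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_benign + self.p_malignant - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")

    @property
    def label(self) -> str:
        return "malignant" if self.p_malignant >= self.p_benign else "benign"
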