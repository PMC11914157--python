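"""Lesion-to-brain-surface distance from voxel masks.

The minimum distance between the tumor surface and the brain surface is
computed on the voxel grid: an anisotropic Euclidean distance transform of
the brain mask gives, for every in-brain voxel, the center-to-center
distance to the nearest brain-exterior voxel; the minimum over lesion voxels,
reduced by one voxel pitch so that a lesion flush against the brain boundary
scores exactly 0 mm, is the reported surface-to-surface distance.  The
convention is exact to within one voxel diagonal, which is immaterial at the
1.5 cm peripheral/central cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    pass


class Location(str, Enum):
    PERIPHERAL = "PERIPHERAL"
    CENTRAL = "CENTRAL"


@dataclass(frozen=True)
class VoxelMaskPair:
    """Paired binary masks (same grid) with voxel spacing in mm, index order."""

    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        brain = np.asarray(self.brain_mask, dtype=bool)
        lesion = np.asarray(self.lesion_mask, dtype=bool)
        object.__setattr__(self, "brain_mask", brain)
        object.__setattr__(self, "lesion_mask", lesion)
        if brain.shape != lesion.shape:
            raise GeometryError("brain and lesion masks must share one grid")
        if brain.ndim != 3:
            raise GeometryError("masks must be 3-D")
        if not brain.any():
            raise GeometryError("brain mask is empty")
        if not lesion.any():
            raise GeometryError("lesion mask is empty")
        if np.any(lesion & ~brain):
            raise GeometryError("lesion mask extends outside the brain mask")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise GeometryError("spacing must be three positive numbers (mm)")


def min_surface_distance(pair: VoxelMaskPair) -> float:
    """Minimum lesion-to-brain-surface distance in mm (0 on contact)."""
    edt = ndimage.distance_transform_edt(pair.brain_mask, sampling=pair.spacing_mm)
    center_dist = float(edt[pair.lesion_mask].min())
    return max(0.0, center_dist - min(pair.spacing_mm))


def classify_location(distance_mm: float, cutoff_mm: float = 15.0) -> Location:
    """Peripheral when the lesion lies within ``cutoff_mm`` of the brain surface."""
    if distance_mm < 0:
        raise GeometryError("distance must be non-negative")
    return Location.PERIPHERAL if distance_mm <= cutoff_mm else Location.CENTRAL


def sphere_mask(
    shape: tuple[int, int, int],
    center_mm: tuple[float, float, float],
    radius_mm: float,
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    """Analytic sphere phantom on a voxel grid (voxel centers inside radius)."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing_mm)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm**2


def load_mask_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a binary label map from NIfTI; returns (mask, spacing_mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data > 0, spacing
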