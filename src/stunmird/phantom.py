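"""Synthetic voxel phantom for self-dose Monte Carlo.

The thyroid is modelled as a voxelised sphere of soft tissue embedded in a
homogeneous soft-tissue body on a cubic grid.  Only the *self* S-value of the
thyroid is computed downstream, so the surrounding anatomy (bone, lung, air
cavities) is irrelevant and deliberately omitted; what matters is the thyroid
mass, its shape, and the density of the medium electrons traverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "GeometryError",
    "VoxelPhantom",
    "build_phantom",
    "LABEL_AIR",
    "LABEL_BODY",
    "LABEL_THYROID",
    "SOFT_TISSUE_DENSITY",
    "AIR_DENSITY",
]

LABEL_AIR = 0
LABEL_BODY = 1
LABEL_THYROID = 2

SOFT_TISSUE_DENSITY = 1.05  # g/cm^3
AIR_DENSITY = 1.2e-3  # g/cm^3

_MASS_RTOL = 0.02  # realized thyroid mass must be within 2% of request


class GeometryError(ValueError):
    """Raised when a phantom cannot realise the requested geometry."""


@dataclass
class VoxelPhantom:
    """Labelled cubic-voxel grid with per-region densities.

    Attributes
    ----------
    labels:
        uint8 array of region ids (air/body/thyroid), shape ``(nx, ny, nz)``.
    voxel_size:
        Edge length of a voxel in micrometres.
    densities:
        g/cm^3 per region id.
    target_mass:
        The thyroid mass (mg) that was requested at build time.
    """

    labels: np.ndarray
    voxel_size: float  # um
    densities: dict[int, float] = field(
        default_factory=lambda: {
            LABEL_AIR: AIR_DENSITY,
            LABEL_BODY: SOFT_TISSUE_DENSITY,
            LABEL_THYROID: SOFT_TISSUE_DENSITY,
        }
    )
    target_mass: float | None = None  # mg

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size * 1e-3) ** 3

    @cached_property
    def thyroid_voxels(self) -> np.ndarray:
        """Integer (k, 3) indices of thyroid voxels."""
        return np.argwhere(self.labels == LABEL_THYROID)

    @property
    def thyroid_volume_mm3(self) -> float:
        return float(len(self.thyroid_voxels)) * self.voxel_volume_mm3

    @property
    def thyroid_mass(self) -> float:
        """Realised thyroid mass in mg (voxel count x volume x density)."""
        return self.thyroid_volume_mm3 * self.densities[LABEL_THYROID]

    @property
    def thyroid_equivalent_radius_mm(self) -> float:
        """Radius of the sphere with the thyroid's voxelised volume."""
        v = self.thyroid_volume_mm3
        return float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)) if v > 0 else 0.0

    def thyroid_mean_chord_mm(self) -> float:
        """Mean chord length 4V/S of the volume-equivalent sphere (= 4R/3)."""
        return 4.0 * self.thyroid_equivalent_radius_mm / 3.0


def build_phantom(
    thyroid_mass: float = 5.4,
    voxel_size: float = 200.0,
    body_extent: float = 20.0,
) -> VoxelPhantom:
    """Build a cubic soft-tissue body with a centred voxelised thyroid sphere.

    Parameters
    ----------
    thyroid_mass:
        Requested thyroid mass in mg (realised within 2%).
    voxel_size:
        Cubic voxel edge in micrometres.
    body_extent:
        Body edge length in mm per axis; must contain the thyroid sphere
        plus a 2 mm margin.

    Raises
    ------
    GeometryError
        If the voxel size is too coarse to realise the mass within 2%, or
        the body is too small.
    """
    if thyroid_mass <= 0:
        raise GeometryError("thyroid_mass must be > 0")
    if voxel_size <= 0:
        raise GeometryError("voxel_size must be > 0")
    if body_extent <= 0:
        raise GeometryError("body_extent must be > 0")

    target_volume_mm3 = thyroid_mass / SOFT_TISSUE_DENSITY  # mg / (mg/mm^3)
    radius_mm = (3.0 * target_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    if 2.0 * (radius_mm + 2.0) > body_extent:
        raise GeometryError(
            f"body_extent {body_extent} mm cannot contain a thyroid of radius "
            f"{radius_mm:.2f} mm plus a 2 mm margin"
        )

    n = int(round(body_extent * 1e3 / voxel_size))
    if n < 1:
        raise GeometryError("body_extent smaller than one voxel")
    voxel_volume_mm3 = (voxel_size * 1e-3) ** 3
    k = int(round(target_volume_mm3 / voxel_volume_mm3))
    realized = k * voxel_volume_mm3 * SOFT_TISSUE_DENSITY
    if k < 1 or abs(realized - thyroid_mass) / thyroid_mass > _MASS_RTOL:
        raise GeometryError(
            f"voxel size {voxel_size} um is too coarse to realise {thyroid_mass} mg "
            f"within {100 * _MASS_RTOL:.0f}% (best achievable {realized:.3g} mg); "
            "use finer voxels"
        )

    labels = np.full((n, n, n), LABEL_BODY, dtype=np.uint8)

    # Select the k voxels whose centres are nearest the grid centre inside a
    # bounding box; ties broken by flat index so the build is deterministic.
    center = n / 2.0  # in voxel units; voxel centres are at i + 0.5
    half_box = int(np.ceil(radius_mm * 1e3 / voxel_size)) + 2
    lo = max(0, int(np.floor(center)) - half_box)
    hi = min(n, int(np.ceil(center)) + half_box)
    idx = np.arange(lo, hi)
    ix, iy, iz = np.meshgrid(idx, idx, idx, indexing="ij")
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    d2 = (ix + 0.5 - center) ** 2 + (iy + 0.5 - center) ** 2 + (iz + 0.5 - center) ** 2
    flat = (ix * n + iy) * n + iz
    order = np.lexsort((flat, d2))
    if k > len(order):
        raise GeometryError("internal bounding box too small for thyroid")  # pragma: no cover
    sel = order[:k]
    labels[ix[sel], iy[sel], iz[sel]] = LABEL_THYROID

    return VoxelPhantom(labels=labels, voxel_size=float(voxel_size), target_mass=thyroid_mass)
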