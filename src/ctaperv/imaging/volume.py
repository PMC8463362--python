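"""HU-calibrated CT volumes with an axis-aligned world frame.

Volumes are stored as float arrays indexed ``(i, j, k)`` with world
position ``origin + index * spacing`` (mm, right-handed). NIfTI files are
read and written with :mod:`nibabel`; loading requires an axis-aligned
affine (conversion/reorientation is upstream of this package).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import GeometryError, RigidTransform

__all__ = ["CTVolume", "VolumeError", "resample_to"]


class VolumeError(ValueError):
    """Unreadable or unsupported volume input."""


@dataclass
class CTVolume:
    """3-D scalar field of Hounsfield units with voxel spacing and origin."""

    values: np.ndarray            # (nx, ny, nz) float HU
    spacing: tuple[float, float, float]  # mm per voxel along each axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise VolumeError("volume must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise VolumeError("HU values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError("voxel spacing must be positive on all axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def slice_thickness_mm(self) -> float:
        """Spacing along the slice (z) axis — the cohort covariate."""
        return self.spacing[2]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def center_mm(self) -> np.ndarray:
        lo, hi = self.world_bounds()
        return (lo + hi) / 2.0

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(
            self.origin
        )

    def interp_world(self, points: np.ndarray, order: int = 1,
                     cval: float = -1024.0) -> np.ndarray:
        """Linear interpolation of HU at (N, 3) world points (mm)."""
        vox = np.atleast_2d(self.world_to_voxel(points))
        return ndimage.map_coordinates(
            self.values, vox.T, order=order, mode="constant", cval=cval
        )

    def affine(self) -> np.ndarray:
        A = np.diag(list(self.spacing) + [1.0])
        A[:3, 3] = self.origin
        return A

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "CTVolume":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several classes
            raise VolumeError(f"unreadable NIfTI file {path!r}: {exc}") from exc
        aff = img.affine
        off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
        if np.max(np.abs(off_diag)) > 1e-6 or np.any(np.diag(aff[:3, :3]) <= 0):
            raise VolumeError(
                "only axis-aligned volumes with positive spacing are supported; "
                "reorient upstream"
            )
        data = np.asarray(img.get_fdata(), dtype=float)
        return cls(
            values=data,
            spacing=tuple(np.diag(aff[:3, :3])),
            origin=tuple(aff[:3, 3]),
        )


def resample_to(moving: CTVolume, transform: RigidTransform,
                reference: CTVolume, order: int = 1,
                cval: float = -1024.0) -> CTVolume:
    """Resample *moving* onto the grid of *reference*.

    ``transform`` maps reference-frame world points to moving-frame world
    points (the registration convention): the output voxel at reference
    index ``idx`` takes the value of *moving* interpolated at
    ``transform(reference.voxel_to_world(idx))``.
    """
    if not _overlap(moving, reference, transform):
        raise GeometryError("volumes have no world-space overlap under transform")
    idx = np.indices(reference.shape).reshape(3, -1).T
    pts = reference.voxel_to_world(idx)
    vals = moving.interp_world(transform.apply(pts), order=order, cval=cval)
    return CTVolume(
        values=vals.reshape(reference.shape),
        spacing=reference.spacing,
        origin=reference.origin,
    )


def _overlap(moving: CTVolume, reference: CTVolume,
             transform: RigidTransform) -> bool:
    lo_r, hi_r = reference.world_bounds()
    corners = np.array(
        [[x, y, z] for x in (lo_r[0], hi_r[0])
         for y in (lo_r[1], hi_r[1]) for z in (lo_r[2], hi_r[2])]
    )
    mapped = transform.apply(corners)
    lo_m, hi_m = moving.world_bounds()
    return bool(
        np.all(mapped.max(axis=0) >= lo_m - 1e-6)
        and np.all(mapped.min(axis=0) <= hi_m + 1e-6)
    )
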