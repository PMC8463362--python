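"""Rigid transforms and vessel centerlines in world (mm) coordinates.

All geometry lives in a right-handed world frame measured in millimetres.
A :class:`RigidTransform` is parameterised by three Euler angles (degrees,
extrinsic x-y-z order) and a translation, optionally about a rotation
centre; it is the 6-DOF object returned by registration and used to map
fixed-image world points into moving-image world points when resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "CenterlinePath", "GeometryError"]


class GeometryError(ValueError):
    """Invalid geometric input (degenerate centerline, out-of-bounds ROI...)."""


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix for extrinsic rotations about world x, y then z (degrees)."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R (p - c) + c + t``.

    Parameters
    ----------
    rotation_deg : (3,) float
        Extrinsic Euler angles about the world x, y, z axes, in degrees.
    translation_mm : (3,) float
        Translation in mm, applied after rotation.
    center_mm : (3,) float
        Centre of rotation in world mm (defaults to the origin).

    Notes
    -----
    ``rotation_deg=(0, 180, 0)`` doubles as the left/right mirror used to
    map an occluded-side point onto the contralateral side for centerlines
    lying in the ``z = center_z`` plane.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of the transform."""
        R = _euler_matrix(*self.rotation_deg)
        c = np.asarray(self.center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or single 3-vector) of world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        M = self.matrix()
        out = pts @ M[:3, :3].T + M[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply *other* first)."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix())

    def inverse(self) -> "RigidTransform":
        M = self.matrix()
        Minv = np.eye(4)
        Minv[:3, :3] = M[:3, :3].T
        Minv[:3, 3] = -M[:3, :3].T @ M[:3, 3]
        return RigidTransform.from_matrix(Minv)

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        """Build from a homogeneous matrix with a proper-rotation block."""
        R = np.asarray(M, dtype=float)[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise GeometryError("matrix block is not a proper rotation")
        # extrinsic x-y-z Euler extraction (R = Rz Ry Rx)
        sy = -R[2, 0]
        cy = np.hypot(R[0, 0], R[1, 0])
        ry = np.arctan2(sy, cy)
        if cy > 1e-12:
            rx = np.arctan2(R[2, 1], R[2, 2])
            rz = np.arctan2(R[1, 0], R[0, 0])
        else:  # gimbal lock
            rx = np.arctan2(-R[1, 2], R[1, 1])
            rz = 0.0
        return cls(
            rotation_deg=tuple(np.rad2deg([rx, ry, rz])),
            translation_mm=tuple(np.asarray(M, dtype=float)[:3, 3]),
        )

    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) of the rotation block."""
        R = self.matrix()[:3, :3]
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.rad2deg(np.arccos(c)))

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(map(float, self.rotation_deg)),
            "translation_mm": list(map(float, self.translation_mm)),
            "center_mm": list(map(float, self.center_mm)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=tuple(d.get("rotation_deg", (0, 0, 0))),
            translation_mm=tuple(d.get("translation_mm", (0, 0, 0))),
            center_mm=tuple(d.get("center_mm", (0, 0, 0))),
        )


@dataclass
class CenterlinePath:
    """Ordered polyline tracing a vessel proximal-to-distal, in world mm.

    ``mirror`` maps occluded-side points onto the contralateral side; when
    ``contralateral_points`` are supplied, mirrored points are additionally
    snapped to the nearest point of that polyline.
    """

    points: np.ndarray  # (N, 3) world mm, proximal -> distal
    mirror: RigidTransform | None = None
    contralateral_points: np.ndarray | None = None
    _cumlen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise GeometryError("centerline needs >= 2 world points of dim 3")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise GeometryError("consecutive centerline points must be distinct")
        self.points = pts
        if self.contralateral_points is not None:
            self.contralateral_points = np.asarray(self.contralateral_points, dtype=float)
        self._cumlen = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self._cumlen[-1])

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc-length (mm) at each polyline vertex."""
        return self._cumlen.copy()

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolate the world point at arc-length ``s`` (mm)."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any(s_arr < -1e-9) or np.any(s_arr > self.total_length + 1e-9):
            raise GeometryError(
                f"arc-length out of range [0, {self.total_length:.3f}] mm"
            )
        s_arr = np.clip(s_arr, 0.0, self.total_length)
        out = np.empty((len(s_arr), 3))
        for ax in range(3):
            out[:, ax] = np.interp(s_arr, self._cumlen, self.points[:, ax])
        return out[0] if np.isscalar(s) or np.asarray(s).ndim == 0 else out

    def sample(self, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
        """Uniform arc-length sampling: returns (s values, (N,3) points)."""
        s = np.arange(0.0, self.total_length + step / 2, step)
        s = np.clip(s, 0.0, self.total_length)
        return s, self.point_at(s)

    def mirror_point(self, point: np.ndarray) -> np.ndarray:
        """Map an occluded-side point to the contralateral side.

        Applies ``mirror`` then, when a contralateral polyline is present,
        snaps to its nearest vertex-interpolated position.
        """
        if self.mirror is None:
            raise GeometryError("centerline has no mirror transform")
        p = self.mirror.apply(np.asarray(point, dtype=float))
        if self.contralateral_points is not None:
            contra = CenterlinePath(self.contralateral_points)
            s_dense, pts = contra.sample(step=0.1)
            p = pts[np.argmin(np.linalg.norm(pts - p, axis=1))]
        return p

    def to_dict(self) -> dict:
        d: dict = {"points_mm": self.points.tolist()}
        if self.mirror is not None:
            d["mirror"] = self.mirror.to_dict()
        if self.contralateral_points is not None:
            d["contralateral_points_mm"] = self.contralateral_points.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlinePath":
        if "points_mm" not in d:
            raise GeometryError("centerline JSON missing required key 'points_mm'")
        mirror = RigidTransform.from_dict(d["mirror"]) if "mirror" in d else None
        contra = d.get("contralateral_points_mm")
        return cls(
            points=np.asarray(d["points_mm"], dtype=float),
            mirror=mirror,
            contralateral_points=None if contra is None else np.asarray(contra, float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CenterlinePath":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
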