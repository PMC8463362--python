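"""Paired NCCT/CTA vessel phantoms with a known perviousness ground truth.

The phantom is two parallel tubular vessels in a uniform background: an
occluded vessel carrying a thrombus segment of configurable baseline
density and contrast uptake, and a fully patent contralateral mirror
vessel. Both volumes share one grid, so a generated pair is perfectly
co-registered by construction; misalignment for registration tests is
applied afterwards by resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ..imaging.geometry import CenterlinePath, GeometryError, RigidTransform
from ..imaging.volume import CTVolume

__all__ = ["PhantomSpec", "PhantomGroundTruth", "generate_phantom", "render_scene", "default_phantom_spec"]


@dataclass
class PhantomSpec:
    """Geometry, HU assignments and degradation model of one phantom pair.

    HU defaults sit inside plausible head-CT ranges: soft-tissue background
    35 HU, unenhanced blood 45 HU, fresh clot 55 HU, opacified lumen 300 HU.
    ``thrombus_uptake_frac`` is the true contrast-penetration fraction: the
    CTA thrombus value is
    ``thrombus_hu_ncct + thrombus_uptake_frac * (contrast_hu - thrombus_hu_ncct)``.
    """

    volume_shape: tuple[int, int, int] = (96, 96, 65)
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.6)
    origin: tuple[float, float, float] = (-28.2, -28.5, -19.2)
    background_hu: float = 35.0
    blood_hu: float = 45.0
    vessel_radius: float = 1.5
    contrast_hu: float = 300.0
    thrombus_hu_ncct: float = 55.0
    thrombus_uptake_frac: float = 0.25
    thrombus_start: float = 30.0        # arc-length (mm) where contrast stops
    thrombus_length: float = 10.0       # mm along the centerline
    vessel_offset_mm: float = 6.0       # lateral distance of each vessel from x=0
    vessel_length_mm: float = 50.0
    noise_sd: float = 8.0
    blur_fwhm: float = 0.8
    texture_hu: float = 30.0            # amplitude of background tissue texture
    texture_blobs: int = 80             # smooth random blobs shared by both scans
    centerline: CenterlinePath | None = None   # built automatically when None

    def __post_init__(self) -> None:
        if self.contrast_hu <= self.background_hu:
            raise ValueError("contrast_hu must exceed background_hu")
        if self.thrombus_length <= 0:
            raise ValueError("thrombus_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.thrombus_uptake_frac <= 1.0:
            raise ValueError("thrombus_uptake_frac must lie in [0, 1]")
        if self.centerline is None:
            self.centerline = self._default_centerline()

    def _default_centerline(self) -> CenterlinePath:
        """Two straight vessels along +y at x = +/- vessel_offset_mm, z = 0."""
        half = self.vessel_length_mm / 2.0
        y = np.arange(-half, half + 0.5, 1.0)
        occluded = np.column_stack(
            [np.full_like(y, self.vessel_offset_mm), y, np.zeros_like(y)]
        )
        contra = occluded.copy()
        contra[:, 0] *= -1
        # 180 deg about the world y axis maps (x, y, z) -> (-x, y, -z); both
        # vessels lie in the z=0 plane, so this is the left/right mirror.
        mirror = RigidTransform(rotation_deg=(0.0, 180.0, 0.0))
        return CenterlinePath(points=occluded, mirror=mirror,
                              contralateral_points=contra)

    @property
    def thrombus_hu_cta(self) -> float:
        return self.thrombus_hu_ncct + self.thrombus_uptake_frac * (
            self.contrast_hu - self.thrombus_hu_ncct
        )


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Ledger of the exact quantities a perfect measurement would recover."""

    true_hu_t_cta: float
    true_hu_c_cta: float
    true_hu_t_ncct: float
    true_hu_c_ncct: float
    true_delta_t: float
    true_delta_c: float
    true_void_fraction: float
    true_cta_index: float
    occlusion_arclength: float

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PhantomGroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_phantom_spec(**overrides) -> PhantomSpec:
    return PhantomSpec(**overrides)


def render_scene(
    spec: PhantomSpec, world: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free NCCT/CTA values of the phantom scene at arbitrary world
    points (mm). The scene is analytic, so it can be evaluated on any
    (e.g. rigidly transformed) grid without interpolation loss."""
    path = spec.centerline

    s_dense, occl_pts = path.sample(step=0.25)
    d_occl, nearest = cKDTree(occl_pts).query(world)
    s_nearest = s_dense[nearest]

    contra = CenterlinePath(path.contralateral_points)
    _, contra_pts = contra.sample(step=0.25)
    d_contra, _ = cKDTree(contra_pts).query(world)

    in_occl = d_occl <= spec.vessel_radius
    in_contra = d_contra <= spec.vessel_radius
    s0, s1 = spec.thrombus_start, spec.thrombus_start + spec.thrombus_length
    in_thrombus = in_occl & (s_nearest >= s0) & (s_nearest <= s1)
    in_distal = in_occl & (s_nearest > s1)  # stagnant column beyond the clot

    ncct = np.full(len(world), spec.background_hu)
    ncct[in_occl | in_contra] = spec.blood_hu
    ncct[in_thrombus] = spec.thrombus_hu_ncct

    cta = np.full(len(world), spec.background_hu)
    cta[in_occl | in_contra] = spec.contrast_hu
    cta[in_thrombus] = spec.thrombus_hu_cta
    cta[in_distal] = spec.blood_hu  # no contrast reaches distal to the occlusion

    # Smooth "tissue" texture shared by both scans, confined to the
    # background so lumen/thrombus HU stay exactly at their spec values.
    # A featureless background would make rigid registration degenerate
    # along the vessel axis; real scans are never featureless.
    if spec.texture_hu > 0 and spec.texture_blobs > 0:
        rng_tex = np.random.default_rng(seed + 131071)
        lo = np.asarray(spec.origin, dtype=float)
        hi = lo + (np.asarray(spec.volume_shape) - 1) * np.asarray(spec.spacing)
        centers = rng_tex.uniform(lo, hi, size=(spec.texture_blobs, 3))
        sigmas = rng_tex.uniform(1.5, 4.0, size=spec.texture_blobs)
        amps = rng_tex.uniform(-spec.texture_hu, spec.texture_hu, spec.texture_blobs)
        texture = np.zeros(len(world))
        for c, sg, am in zip(centers, sigmas, amps):
            d2 = np.sum((world - c) ** 2, axis=1)
            texture += am * np.exp(-d2 / (2.0 * sg * sg))
        texture[in_occl | in_contra] = 0.0
        ncct = ncct + texture
        cta = cta + texture

    return ncct, cta


def generate_phantom(
    spec: PhantomSpec, seed: int, grid_transform: RigidTransform | None = None
) -> tuple[CTVolume, CTVolume, PhantomGroundTruth]:
    """Render the NCCT/CTA pair and its ground-truth ledger.

    Deterministic: the same (spec, seed) yields bit-identical volumes.
    ``grid_transform`` renders the scene on a rigidly transformed grid
    (voxel index ``i`` samples the scene at ``transform(origin + i *
    spacing)``) — the analytic way to produce a misaligned scan for
    registration tests. Raises :class:`GeometryError` when the vessel
    tube leaves an untransformed volume's bounds.
    """
    shape = tuple(spec.volume_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    path = spec.centerline

    if grid_transform is None:
        lo = origin
        hi = origin + (np.asarray(shape) - 1) * spacing
        for pts in (path.points, path.contralateral_points):
            if pts is None:
                continue
            if np.any(pts - spec.vessel_radius < lo - 1e-9) or np.any(
                pts + spec.vessel_radius > hi + 1e-9
            ):
                raise GeometryError("vessel tube leaves the volume bounds")

    idx = np.indices(shape).reshape(3, -1).T
    world = idx * spacing + origin
    if grid_transform is not None:
        world = grid_transform.apply(world)

    ncct, cta = render_scene(spec, world, seed)
    ncct = ncct.reshape(shape)
    cta = cta.reshape(shape)

    if spec.blur_fwhm > 0:
        sigma_vox = (spec.blur_fwhm / 2.35482) / spacing
        ncct = ndimage.gaussian_filter(ncct, sigma_vox)
        cta = ndimage.gaussian_filter(cta, sigma_vox)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        ncct = ncct + rng.normal(0.0, spec.noise_sd, shape)
        cta = cta + rng.normal(0.0, spec.noise_sd, shape)

    truth = PhantomGroundTruth(
        true_hu_t_cta=spec.thrombus_hu_cta,
        true_hu_c_cta=spec.contrast_hu,
        true_hu_t_ncct=spec.thrombus_hu_ncct,
        true_hu_c_ncct=spec.blood_hu,
        true_delta_t=spec.thrombus_hu_cta - spec.thrombus_hu_ncct,
        true_delta_c=spec.contrast_hu - spec.blood_hu,
        true_void_fraction=(spec.thrombus_hu_cta - spec.thrombus_hu_ncct)
        / (spec.contrast_hu - spec.blood_hu),
        true_cta_index=(spec.thrombus_hu_cta - spec.contrast_hu)
        / (spec.thrombus_hu_cta + spec.contrast_hu),
        occlusion_arclength=spec.thrombus_start,
    )

    mk = lambda arr: CTVolume(arr, spacing=tuple(spacing), origin=tuple(origin))
    return mk(ncct), mk(cta), truth
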