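"""Contrast-stop localization, paired ROI placement and mean-HU sampling.

The occlusion site is found on the CTA by walking the centerline HU
profile: the stop is the first arc-length where the (optionally smoothed)
profile drops below threshold and stays below for a persistence length.
Because a pervious thrombus can enhance well above any fixed HU cutoff,
the default threshold is *relative* — a fraction of the patent proximal
plateau — with an absolute-HU mode available.

Measurement ROIs are in-plane circular discs: a voxel contributes when
its centre lies within the disc radius in the ROI plane and within half
a slice thickness along the plane normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import CenterlinePath, GeometryError, RigidTransform
from .registration import RegistrationConfig, RegistrationResult, register_rigid
from .volume import CTVolume, resample_to

__all__ = [
    "StopConfig", "MeasureConfig", "ROIPair", "AttenuationSample",
    "MeasurementResult", "OcclusionNotFoundError", "NoPatentProximalError",
    "SamplingError", "PipelineStageError",
    "locate_contrast_stop", "place_rois", "sample_mean_hu", "measure_patient",
]


class OcclusionNotFoundError(RuntimeError):
    """Centerline profile never drops below threshold: no occlusion detected."""


class NoPatentProximalError(RuntimeError):
    """Profile starts below threshold: no patent proximal segment."""


class SamplingError(RuntimeError):
    """ROI contains no voxel centres."""


class PipelineStageError(RuntimeError):
    """Error from a named stage of the measurement pipeline."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StopConfig:
    step_mm: float = 0.25           # profile sampling step
    smooth_sigma_mm: float = 1.0    # Gaussian smoothing of the profile (0 = off)
    mode: str = "relative"          # "relative" | "absolute"
    relative_frac: float = 0.65     # threshold as fraction of patent plateau
    absolute_hu: float = 100.0      # threshold in HU for mode="absolute"
    persistence_mm: float = 1.0     # profile must stay below this long


@dataclass
class MeasureConfig:
    roi_radius_mm: float = 1.0
    distal_offset_mm: float = 1.5   # ROI sits this far beyond the contrast stop
    stop: StopConfig = field(default_factory=StopConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    registration_mode: str = "full"  # "full" | "init" | "none"


@dataclass
class ROIPair:
    center_t: np.ndarray        # occlusion-site centre, world mm
    center_c: np.ndarray        # contralateral centre, world mm
    radius: float               # in-plane radius, mm
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("ROI radius must be positive")
        self.center_t = np.asarray(self.center_t, dtype=float)
        self.center_c = np.asarray(self.center_c, dtype=float)
        n = np.asarray(self.plane_normal, dtype=float)
        self.plane_normal = n / np.linalg.norm(n)


@dataclass(frozen=True)
class AttenuationSample:
    mean_hu: float
    voxel_count: int
    scan: str   # "NCCT" | "CTA"
    side: str   # "T" | "C"


@dataclass
class MeasurementResult:
    """Four mean-HU samples plus full provenance of how they were obtained."""

    samples: dict[tuple[str, str], AttenuationSample]
    transform: RigidTransform
    registration: RegistrationResult | None
    s_stop_mm: float
    roi: ROIPair

    def sample(self, scan: str, side: str) -> AttenuationSample:
        return self.samples[(scan, side)]

    def provenance(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "registration": None if self.registration is None
            else self.registration.to_dict(),
            "s_stop_mm": float(self.s_stop_mm),
            "roi": {
                "center_t_mm": self.roi.center_t.tolist(),
                "center_c_mm": self.roi.center_c.tolist(),
                "radius_mm": float(self.roi.radius),
                "plane_normal": self.roi.plane_normal.tolist(),
            },
            "voxel_counts": {
                f"{scan}_{side}": s.voxel_count
                for (scan, side), s in self.samples.items()
            },
        }


def locate_contrast_stop(
    cta: CTVolume, path: CenterlinePath, config: StopConfig | None = None
) -> float:
    """Arc-length (mm) of the contrast stop along *path* on the CTA.

    Returns the smallest arc-length at which the profile falls below
    threshold and remains below for at least ``persistence_mm`` (or to
    the end of the path, whichever comes first).
    """
    config = config or StopConfig()
    s, pts = path.sample(step=config.step_mm)
    profile = cta.interp_world(pts)
    if config.smooth_sigma_mm > 0:
        profile = ndimage.gaussian_filter1d(
            profile, config.smooth_sigma_mm / config.step_mm
        )
    if config.mode == "absolute":
        threshold = config.absolute_hu
    elif config.mode == "relative":
        plateau = float(np.percentile(profile, 90))
        threshold = config.relative_frac * plateau
    else:
        raise ValueError(f"unknown stop mode {config.mode!r}")

    below = profile < threshold
    if not below.any():
        raise OcclusionNotFoundError(
            f"no occlusion detected: profile never falls below {threshold:.1f} HU"
        )
    n_persist = max(1, int(round(config.persistence_mm / config.step_mm)))
    for i in np.flatnonzero(below):
        run = below[i : i + n_persist]
        if run.all():
            if i == 0:
                raise NoPatentProximalError(
                    "profile below threshold at the proximal end: "
                    "no patent proximal segment"
                )
            return float(s[i])
    raise OcclusionNotFoundError(
        "no occlusion detected: sub-threshold dips shorter than the "
        f"persistence length {config.persistence_mm} mm"
    )


def place_rois(
    path: CenterlinePath,
    s_stop: float,
    offset: float = 1.5,
    radius: float = 1.0,
    plane_normal=(0.0, 0.0, 1.0),
) -> ROIPair:
    """Occlusion-site ROI at ``s_stop + offset`` plus its contralateral twin."""
    s_t = s_stop + offset
    if s_t > path.total_length + 1e-9:
        raise GeometryError(
            f"ROI arc-length {s_t:.2f} mm runs past the distal end "
            f"({path.total_length:.2f} mm)"
        )
    center_t = path.point_at(s_t)
    center_c = path.mirror_point(center_t)
    return ROIPair(center_t=center_t, center_c=center_c, radius=radius,
                   plane_normal=np.asarray(plane_normal, dtype=float))


def sample_mean_hu(
    vol: CTVolume, roi: ROIPair, side: str, scan: str = "CTA"
) -> AttenuationSample:
    """Mean HU over voxel centres inside the circular disc for one side."""
    if side not in ("T", "C"):
        raise ValueError("side must be 'T' or 'C'")
    center = roi.center_t if side == "T" else roi.center_c
    n = roi.plane_normal
    spacing = np.asarray(vol.spacing)
    half_thick = float(np.abs(n) @ spacing) / 2.0

    margin = roi.radius + half_thick + np.max(spacing)
    lo_idx = np.floor(vol.world_to_voxel(center - margin)).astype(int)
    hi_idx = np.ceil(vol.world_to_voxel(center + margin)).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.asarray(vol.shape) - 1)
    if np.any(lo_idx > hi_idx):
        raise SamplingError(f"ROI {side} lies outside the volume")

    ranges = [np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = vol.voxel_to_world(grid)
    d = pts - center
    axial = d @ n
    inplane = np.linalg.norm(d - np.outer(axial, n), axis=1)
    mask = (inplane <= roi.radius + 1e-9) & (np.abs(axial) <= half_thick + 1e-9)
    if not mask.any():
        raise SamplingError(f"ROI {side} contains no voxel centres")
    vals = vol.values[tuple(grid[mask].T)]
    return AttenuationSample(
        mean_hu=float(vals.mean()), voxel_count=int(mask.sum()),
        scan=scan, side=side,
    )


def measure_patient(
    ncct: CTVolume,
    cta: CTVolume,
    path: CenterlinePath,
    config: MeasureConfig | None = None,
) -> MeasurementResult:
    """Full measurement: register, locate the stop, place ROIs, sample.

    NCCT is the moving image and is resampled onto the CTA grid before
    sampling, so all four ROI samples share one voxel lattice. Stage
    failures re-raise as :class:`PipelineStageError` with the stage name.
    """
    config = config or MeasureConfig()

    reg_result: RegistrationResult | None = None
    try:
        if config.registration_mode == "none":
            transform = RigidTransform()
            ncct_on_cta = ncct if _same_grid(ncct, cta) else resample_to(
                ncct, transform, cta
            )
        else:
            reg_cfg = config.registration
            if config.registration_mode == "init":
                reg_cfg = RegistrationConfig(
                    metric=reg_cfg.metric, bins=reg_cfg.bins, refine=False
                )
            reg_result = register_rigid(ncct, cta, reg_cfg)
            transform = reg_result.transform
            ncct_on_cta = resample_to(ncct, transform, cta)
    except Exception as exc:
        raise PipelineStageError("registration", exc) from exc

    try:
        s_stop = locate_contrast_stop(cta, path, config.stop)
    except Exception as exc:
        raise PipelineStageError("localization", exc) from exc

    try:
        roi = place_rois(path, s_stop, offset=config.distal_offset_mm,
                         radius=config.roi_radius_mm)
    except Exception as exc:
        raise PipelineStageError("roi-placement", exc) from exc

    try:
        samples = {
            (scan, side): sample_mean_hu(vol, roi, side, scan=scan)
            for scan, vol in (("CTA", cta), ("NCCT", ncct_on_cta))
            for side in ("T", "C")
        }
    except Exception as exc:
        raise PipelineStageError("sampling", exc) from exc

    return MeasurementResult(
        samples=samples,
        transform=transform,
        registration=reg_result,
        s_stop_mm=s_stop,
        roi=roi,
    )


def _same_grid(a: CTVolume, b: CTVolume) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing)
        and np.allclose(a.origin, b.origin)
    )
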