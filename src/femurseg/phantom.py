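"""Synthetic femur-like MR phantoms with paired ground-truth masks.

The foreground is the union of a spherical head, a cylindrical neck meeting
the shaft at a configurable angle, and a cylindrical shaft segment —
the simplest geometry exhibiting the head/neck/shaft topology a volumetric
segmenter must connect. Appearance is bright marrow with band-limited
trabecular texture on a darker background, a darkened cortical rim at the
boundary, plus i.i.d. Gaussian noise. Optional corruptions model rare
acquisition/pathology failure modes: in-plane fold-over (aliasing) and
hypointense intra-bone lesions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core_io import ImageVolume, LabelMask


class DegeneratePhantomError(ValueError):
    """Foreground clipped by the grid boundary beyond tolerance."""


@dataclass
class LesionParams:
    center: Tuple[float, float, float]  # mm
    radius: float  # mm
    intensity_drop: float


@dataclass
class FoldoverParams:
    wrap_fraction: float
    gain: float

    def __post_init__(self) -> None:
        if not (0.0 < self.wrap_fraction < 0.5):
            raise ValueError(f"wrap_fraction must lie in (0, 0.5), got {self.wrap_fraction}")


@dataclass
class PhantomParams:
    """Geometry and appearance parameters of one phantom volume.

    Default grid is desk-scale 96x96x48 with spacing (0.5, 0.5, 1.5) mm,
    preserving the in-plane/out-of-plane anisotropy of the emulated
    acquisition (0.234 mm in-plane, 1.5 mm sections) at ~2x downscale.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 48)
    spacing: Tuple[float, float, float] = (0.5, 0.5, 1.5)
    head_radius: float = 9.0  # mm
    neck_radius: float = 5.0
    neck_length: float = 12.0
    shaft_radius: float = 7.0
    shaft_length: float = 20.0
    neck_shaft_angle: float = 130.0  # degrees
    marrow_intensity: float = 1.0
    background_intensity: float = 0.2
    trabecular_amplitude: float = 0.08
    trabecular_scale: float = 2.0  # mm correlation length
    noise_sd: float = 0.05
    cortical_rim_mm: float = 1.0
    lesion: Optional[LesionParams] = None
    foldover: Optional[FoldoverParams] = None

    def __post_init__(self) -> None:
        for name in ("head_radius", "neck_radius", "neck_length", "shaft_radius",
                     "shaft_length", "neck_shaft_angle", "trabecular_scale",
                     "cortical_rim_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape too small: {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive: {self.spacing}")
        if self.noise_sd < 0 or self.trabecular_amplitude < 0:
            raise ValueError("noise_sd and trabecular_amplitude must be non-negative")

    @property
    def physical_extent(self) -> Tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))

    def analytic_volume(self) -> float:
        """Sum of part volumes (sphere + two cylinders), overlaps not removed."""
        head = 4.0 / 3.0 * np.pi * self.head_radius ** 3
        neck = np.pi * self.neck_radius ** 2 * self.neck_length
        shaft = np.pi * self.shaft_radius ** 2 * self.shaft_length
        return head + neck + shaft


def _geometry(params: PhantomParams):
    """Head center, neck segment and shaft segment in mm coordinates."""
    X, Y, Z = params.physical_extent
    head_c = np.array([0.66 * X, 0.30 * Y, 0.50 * Z])
    phi = np.deg2rad(180.0 - params.neck_shaft_angle)
    neck_dir = np.array([-np.sin(phi), np.cos(phi), 0.0])
    neck_a = head_c
    neck_b = head_c + params.neck_length * neck_dir
    shaft_a = neck_b
    shaft_b = neck_b + np.array([0.0, params.shaft_length, 0.0])
    return head_c, (neck_a, neck_b), (shaft_a, shaft_b)


def _rasterize(params: PhantomParams, origin_vox: Tuple[int, int, int],
               shape: Tuple[int, int, int]) -> np.ndarray:
    """Rasterize the union shape on a grid whose voxel (0,0,0) sits at
    ``origin_vox`` (possibly negative) in the phantom's own voxel frame."""
    sx, sy, sz = params.spacing
    ox, oy, oz = origin_vox
    xs = (np.arange(shape[0]) + ox) * sx
    ys = (np.arange(shape[1]) + oy) * sy
    zs = (np.arange(shape[2]) + oz) * sz
    px, py, pz = np.meshgrid(xs, ys, zs, indexing="ij")
    head_c, neck, shaft = _geometry(params)

    mask = ((px - head_c[0]) ** 2 + (py - head_c[1]) ** 2
            + (pz - head_c[2]) ** 2) <= params.head_radius ** 2

    for (a, b), r in ((neck, params.neck_radius), (shaft, params.shaft_radius)):
        u = b - a
        length = float(np.linalg.norm(u))
        u = u / length
        t = (px - a[0]) * u[0] + (py - a[1]) * u[1] + (pz - a[2]) * u[2]
        rad2 = ((px - a[0] - t * u[0]) ** 2 + (py - a[1] - t * u[1]) ** 2
                + (pz - a[2] - t * u[2]) ** 2)
        mask |= (t >= 0) & (t <= length) & (rad2 <= r ** 2)
    return mask


def rasterize_mask(params: PhantomParams) -> np.ndarray:
    """Boolean foreground mask on the phantom grid.

    Raises :class:`DegeneratePhantomError` when more than 5% of the shape's
    volume falls outside the grid.
    """
    margin = (int(np.ceil(20.0 / params.spacing[0])), int(np.ceil(20.0 / params.spacing[1])),
              int(np.ceil(20.0 / params.spacing[2])))
    ext_shape = tuple(n + 2 * m for n, m in zip(params.grid_shape, margin))
    ext = _rasterize(params, tuple(-m for m in margin), ext_shape)
    inner = ext[margin[0]:margin[0] + params.grid_shape[0],
                margin[1]:margin[1] + params.grid_shape[1],
                margin[2]:margin[2] + params.grid_shape[2]]
    total = int(ext.sum())
    if total == 0:
        raise DegeneratePhantomError("foreground shape is empty")
    kept = int(inner.sum())
    if kept < 0.95 * total:
        raise DegeneratePhantomError(
            f"foreground clipped by grid boundary: only {kept}/{total} voxels inside")
    return inner.copy()


def generate_phantom(params: PhantomParams, seed: int) -> Tuple[ImageVolume, LabelMask]:
    """Deterministically generate one phantom image/mask pair."""
    mask = rasterize_mask(params)
    rng = np.random.default_rng(seed)

    img = np.full(params.grid_shape, params.background_intensity, dtype=np.float64)
    img[mask] = params.marrow_intensity

    if params.trabecular_amplitude > 0:
        noise = rng.standard_normal(params.grid_shape)
        sigma = tuple(params.trabecular_scale / s for s in params.spacing)
        tex = ndimage.gaussian_filter(noise, sigma=sigma)
        sd = tex.std()
        if sd > 0:
            tex = (tex - tex.mean()) / sd * params.trabecular_amplitude
        img[mask] += tex[mask]

    if params.cortical_rim_mm > 0 and mask.any():
        dist_in = ndimage.distance_transform_edt(mask, sampling=params.spacing)
        rim = mask & (dist_in <= params.cortical_rim_mm)
        contrast = params.marrow_intensity - params.background_intensity
        img[rim] = params.background_intensity + 0.25 * contrast

    if params.noise_sd > 0:
        img += params.noise_sd * rng.standard_normal(params.grid_shape)

    vol = ImageVolume(data=img.astype(np.float32), spacing=params.spacing)
    lab = LabelMask(data=mask.astype(np.uint8), spacing=params.spacing)

    if params.lesion is not None:
        vol = apply_lesion(vol, lab, params.lesion.center, params.lesion.radius,
                           params.lesion.intensity_drop,
                           background_intensity=params.background_intensity)
    if params.foldover is not None:
        vol = apply_foldover(vol, params.foldover.wrap_fraction, params.foldover.gain,
                             seed=seed)
    return vol, lab


def apply_foldover(v: ImageVolume, wrap_fraction: float, gain: float, seed: int) -> ImageVolume:
    """Add an aliasing (fold-over) band: the outer ``wrap_fraction`` of the
    in-plane field of view on one x-side is flipped and added, scaled by
    ``gain``, onto the opposite edge. The paired mask is untouched by
    construction."""
    if not (0.0 < wrap_fraction < 0.5):
        raise ValueError(f"wrap_fraction must lie in (0, 0.5), got {wrap_fraction}")
    nx = v.shape[0]
    w = max(1, int(round(wrap_fraction * nx)))
    rng = np.random.default_rng(seed)
    out = v.data.astype(np.float64).copy()
    if rng.random() < 0.5:  # wrap low-x band onto high-x edge
        band = out[:w][::-1]
        out[nx - w:] += gain * band
    else:
        band = out[nx - w:][::-1]
        out[:w] += gain * band
    return ImageVolume(data=out, spacing=v.spacing, side=v.side, subject_id=v.subject_id)


def apply_lesion(v: ImageVolume, m: LabelMask, center: Sequence[float], radius: float,
                 intensity_drop: float, background_intensity: Optional[float] = None) -> ImageVolume:
    """Darken intensities inside sphere(center, radius) ∩ mask by
    ``intensity_drop``, floored at the background intensity."""
    if v.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    sx, sy, sz = v.spacing
    xs = np.arange(v.shape[0]) * sx
    ys = np.arange(v.shape[1]) * sy
    zs = np.arange(v.shape[2]) * sz
    px, py, pz = np.meshgrid(xs, ys, zs, indexing="ij")
    sphere = ((px - center[0]) ** 2 + (py - center[1]) ** 2 + (pz - center[2]) ** 2) <= radius ** 2
    region = sphere & (m.data > 0)
    if not region.any():
        raise ValueError("lesion sphere does not intersect the mask")
    if background_intensity is None:
        background_intensity = float(np.median(v.data[m.data == 0])) if (m.data == 0).any() else 0.0
    out = v.data.astype(np.float64).copy()
    out[region] = np.maximum(out[region] - intensity_drop, background_intensity)
    return ImageVolume(data=out, spacing=v.spacing, side=v.side, subject_id=v.subject_id)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Numeric PhantomParams fields that cohort ranges may vary.
RANGE_FIELDS = ("head_radius", "neck_radius", "neck_length", "shaft_radius",
                "shaft_length", "neck_shaft_angle", "marrow_intensity",
                "background_intensity", "trabecular_amplitude", "trabecular_scale",
                "noise_sd", "cortical_rim_mm")

#: Default per-field sampling intervals for cohort generation.
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "head_radius": (8.0, 10.0),
    "neck_radius": (4.0, 6.0),
    "neck_length": (10.0, 14.0),
    "shaft_radius": (6.0, 8.0),
    "shaft_length": (16.0, 22.0),
    "neck_shaft_angle": (120.0, 140.0),
    "noise_sd": (0.03, 0.07),
    "trabecular_amplitude": (0.05, 0.10),
}

#: Stratum-positive probability emulating the 36/86 prevalence of the cohort
#: the networks are meant for.
STRATUM_PROBABILITY = 36.0 / 86.0


@dataclass
class CohortSubject:
    """One simulated subject: image, mask and sampling metadata."""

    image: ImageVolume
    mask: LabelMask
    side: str
    stratum: int
    seed: int
    params: PhantomParams

    @property
    def subject_id(self) -> str:
        return self.image.subject_id


def generate_cohort(n: int, params_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
                    seed: int = 0, base_params: Optional[PhantomParams] = None,
                    stratum_probability: float = STRATUM_PROBABILITY) -> List[CohortSubject]:
    """Generate ``n`` phantoms with per-field parameters drawn uniformly from
    ``params_ranges``, alternating laterality (p=0.5 left/right via mirroring)
    and a binary stratum label for stratified cross-validation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_RANGES if params_ranges is None else params_ranges)
    for key, (lo, hi) in ranges.items():
        if key not in RANGE_FIELDS:
            raise ValueError(f"unknown range field {key!r}")
        if hi < lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
    base = base_params if base_params is not None else PhantomParams()
    rng = np.random.default_rng(seed)
    cohort: List[CohortSubject] = []
    for i in range(n):
        overrides = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        params = dataclasses.replace(base, **overrides)
        side = "left" if rng.random() < 0.5 else "right"
        stratum = int(rng.random() < stratum_probability)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        image, mask = generate_phantom(params, seed=sub_seed)
        if side == "left":  # mirror in-plane left-right axis for laterality
            image = ImageVolume(data=image.data[::-1].copy(), spacing=image.spacing)
            mask = LabelMask(data=mask.data[::-1].copy(), spacing=mask.spacing)
        sid = f"phantom{i:03d}"
        image.subject_id = sid
        image.side = side
        mask.subject_id = sid
        cohort.append(CohortSubject(image=image, mask=mask, side=side,
                                    stratum=stratum, seed=sub_seed, params=params))
    return cohort
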