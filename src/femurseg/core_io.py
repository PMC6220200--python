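"""Domain types, NIfTI I/O, in-plane resampling and run configuration.

Arrays are indexed ``(x, y, z)`` with ``z`` the slice (coronal-section) axis.
All physical-distance computations place voxel centers at
``(i * sx, j * sy, k * sz)`` millimetres.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when a file does not hold a 3D scalar image."""


class InvariantError(ValueError):
    """Raised when a domain-type invariant is violated."""


Spacing = Tuple[float, float, float]

SIDES = ("left", "right", "unknown")


def _check_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise InvariantError(f"spacing must have 3 components, got {spacing!r}")
    if any(s <= 0 for s in spacing):
        raise InvariantError(f"spacing components must be strictly positive: {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """3D scalar intensity grid with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: Spacing
    side: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvariantError(f"ImageVolume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise InvariantError("ImageVolume data contains non-finite values")
        self.spacing = _check_spacing(self.spacing)
        if self.side not in SIDES:
            raise InvariantError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """Binary {0,1} grid aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: Spacing
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvariantError(f"LabelMask data must be 3D, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise InvariantError(f"LabelMask values must be exactly 0 or 1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class ProbabilityMap:
    """Per-voxel foreground probability in [0, 1]."""

    data: np.ndarray
    spacing: Spacing
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise InvariantError(f"ProbabilityMap data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise InvariantError("ProbabilityMap contains non-finite values")
        if self.data.min() < 0 or self.data.max() > 1:
            raise InvariantError("ProbabilityMap values must lie in [0, 1]")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


AnyVolume = Union[ImageVolume, LabelMask, ProbabilityMap]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: Union[str, Path]) -> ImageVolume:
    """Read a 3D scalar NIfTI-1 file into an :class:`ImageVolume`.

    The image is reoriented to the closest canonical (RAS) axis order so
    downstream code never branches on orientation; voxel spacing is taken
    from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path} holds a {len(img.shape)}D image; a 3D scalar image is required")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing=spacing, subject_id=path.stem.split(".")[0])


def read_mask(path: Union[str, Path]) -> LabelMask:
    """Read a binary NIfTI mask."""
    v = read_volume(path)
    data = np.rint(v.data).astype(np.uint8)
    return LabelMask(data=data, spacing=v.spacing, subject_id=v.subject_id)


def write_volume(v: AnyVolume, path: Union[str, Path]) -> Path:
    """Write a volume, mask or probability map as NIfTI-1.

    Masks are stored as unsigned 8-bit, probability maps as 32-bit float,
    intensity volumes as 32-bit float. Spacing goes into the header affine
    and pixdim.
    """
    path = Path(path)
    if isinstance(v, LabelMask):
        data = v.data.astype(np.uint8)
    elif isinstance(v, ProbabilityMap):
        data = v.data.astype(np.float32)
    elif isinstance(v, ImageVolume):
        data = v.data.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(v).__name__}")
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def resample_inplane(v: ImageVolume, target_xy: Tuple[int, int]) -> ImageVolume:
    """Resample every axial-plane slice to ``target_xy`` with bicubic splines.

    The out-of-plane (slice) axis is untouched and spacing is rescaled so the
    physical field of view is preserved.
    """
    tx, ty = int(target_xy[0]), int(target_xy[1])
    if tx < 8 or ty < 8:
        raise ValueError(f"target in-plane shape must be at least (8, 8), got {(tx, ty)}")
    nx, ny, nz = v.shape
    if (tx, ty) == (nx, ny):
        return ImageVolume(data=v.data.copy(), spacing=v.spacing, side=v.side, subject_id=v.subject_id)
    factors = (tx / nx, ty / ny, 1.0)
    out = ndimage.zoom(np.asarray(v.data, dtype=np.float64), factors, order=3,
                       mode="mirror")
    # grid_mode zoom can land a voxel off on odd ratios; enforce target shape.
    out = out[:tx, :ty, :]
    sx, sy, sz = v.spacing
    new_spacing = (sx * nx / tx, sy * ny / ty, sz)
    return ImageVolume(data=out, spacing=new_spacing, side=v.side, subject_id=v.subject_id)


def resample_mask_inplane(m: LabelMask, target_xy: Tuple[int, int]) -> LabelMask:
    """Nearest-neighbour in-plane mask resampling (binarity-preserving)."""
    tx, ty = int(target_xy[0]), int(target_xy[1])
    if tx < 8 or ty < 8:
        raise ValueError(f"target in-plane shape must be at least (8, 8), got {(tx, ty)}")
    nx, ny, nz = m.shape
    if (tx, ty) == (nx, ny):
        return LabelMask(data=m.data.copy(), spacing=m.spacing, subject_id=m.subject_id)
    out = ndimage.zoom(m.data, (tx / nx, ty / ny, 1.0), order=0, grid_mode=True, mode="grid-constant")
    out = out[:tx, :ty, :]
    sx, sy, sz = m.spacing
    return LabelMask(data=out, spacing=(sx * nx / tx, sy * ny / ty, sz), subject_id=m.subject_id)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    output_dir: str = "runs"
    log_level: str = "info"
    architecture: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        import yaml

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class RunLogger:
    """Structured one-line-per-event JSON log written beside run outputs."""

    def __init__(self, path: Optional[Union[str, Path]] = None):
        self.path = Path(path) if path is not None else None
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def log(self, event: str, **fields) -> None:
        if self.path is None:
            return
        record = {"t": time.time(), "event": event, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, default=float) + "\n")
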