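"""Full-volume prediction: padded direct or unpadded via mirrored tiling,
thresholding and connected-component post-processing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core_io import ImageVolume, LabelMask, ProbabilityMap
from .nets import ArchitectureSpec, ShapeError, output_shape


# ---------------------------------------------------------------------------
# Padding helpers
# ---------------------------------------------------------------------------

def mirror_pad(x: np.ndarray, margin: Sequence[int]) -> np.ndarray:
    """Reflection-pad (edge voxel not duplicated) the leading spatial axes.

    ``margin`` gives the per-axis pad width; trailing axes (e.g. channels)
    are left alone. A 1D row ``[a, b, c]`` with margin 2 becomes
    ``[c, b, a, b, c, b, a]``.
    """
    margin = list(margin)
    for m, s in zip(margin, x.shape):
        if m >= s:
            raise ValueError(f"mirror margin {m} too large for extent {s}")
    pad = [(m, m) for m in margin] + [(0, 0)] * (x.ndim - len(margin))
    return np.pad(x, pad, mode="reflect")


def pad_to_multiple(x: np.ndarray, multiple: int, n_spatial: int):
    """Zero-pad the first ``n_spatial`` axes up to the next multiple; returns
    the padded array and the slices recovering the original region."""
    pads, sls = [], []
    for i in range(x.ndim):
        if i < n_spatial:
            s = x.shape[i]
            target = ((s + multiple - 1) // multiple) * multiple
            pads.append((0, target - s))
            sls.append(slice(0, s))
        else:
            pads.append((0, 0))
            sls.append(slice(None))
    return np.pad(x, pads), tuple(sls)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

@dataclass
class TilePlan:
    """Regular grid of tiles whose output windows exactly cover the image.

    Offsets are in mirrored-image coordinates: the mirrored image pads each
    in-plane side by ``margin = (tile_in - tile_out) // 2`` so a tile whose
    input window starts at offset ``o`` yields the output window
    ``[o, o + tile_out)`` of the original image.
    """

    image_shape: Tuple[int, int]
    tile_in: Tuple[int, int]
    tile_out: Tuple[int, int]
    counts: Tuple[int, int]
    offsets: Tuple[Tuple[int, ...], Tuple[int, ...]]

    @property
    def margin(self) -> Tuple[int, int]:
        return tuple((i - o) // 2 for i, o in zip(self.tile_in, self.tile_out))

    @property
    def n_tiles(self) -> int:
        return self.counts[0] * self.counts[1]

    def tiles(self) -> List[Tuple[Tuple[int, int], Tuple[int, int]]]:
        """(input-window offset, output-window offset) per tile; with this
        plan's coordinates the two coincide."""
        return [((ox, oy), (ox, oy))
                for ox in self.offsets[0] for oy in self.offsets[1]]


def _axis_offsets(extent: int, out: int) -> Tuple[int, ...]:
    count = max(1, -(-extent // out))  # ceil
    if count == 1:
        return (0,)
    span = extent - out
    return tuple(int(round(i * span / (count - 1))) for i in range(count))


def plan_tiles(image_shape: Sequence[int], spec: ArchitectureSpec,
               tile_input_shape: Sequence[int]) -> TilePlan:
    """Minimal regular tile grid covering the image: per-axis tile count is
    ``ceil(extent / output_extent)`` with symmetric overlaps."""
    if spec.padded:
        raise ValueError("tiled inference applies to unpadded specs only")
    image_shape = tuple(int(s) for s in image_shape)[:2]
    tile_in = tuple(int(s) for s in tile_input_shape)
    tile_out = output_shape(spec, tile_in)  # raises if inadmissible
    if any((i - o) % 2 for i, o in zip(tile_in, tile_out)):
        raise ShapeError(f"tile shrinkage must be even, got {tile_in} -> {tile_out}")
    offsets = tuple(_axis_offsets(e, o) for e, o in zip(image_shape, tile_out))
    counts = tuple(len(o) for o in offsets)
    return TilePlan(image_shape=image_shape, tile_in=tile_in, tile_out=tile_out,
                    counts=counts, offsets=offsets)


def coverage_counts(plan: TilePlan) -> np.ndarray:
    """Per-voxel visit counts of the plan's output windows."""
    grid = np.zeros(plan.image_shape, dtype=np.int32)
    for _, (ox, oy) in plan.tiles():
        grid[ox:ox + plan.tile_out[0], oy:oy + plan.tile_out[1]] += 1
    return grid


def default_tile_shape(spec: ArchitectureSpec, image_shape: Sequence[int]) -> Tuple[int, int]:
    """Largest admissible tile input shape not exceeding the mirrored image
    extent (image + 2 * margin, solved jointly per axis)."""
    out_shape = []
    for extent in tuple(image_shape)[:2]:
        best = None
        for n in range(4, 4 * extent + 64):
            try:
                (m,) = output_shape(ArchitectureSpec(
                    dims=2, feature_maps=1, layers=spec.layers, padding="unpadded",
                    dilation_rates=spec.dilation_rates, in_channels=1), (n,) * 2)[:1]
            except ShapeError:
                continue
            # mirrored image extent is extent + (n - m); tile must fit in it
            if n <= extent + (n - m):
                best = n
            else:
                break
        if best is None:
            raise ShapeError(f"no admissible tile for extent {extent}")
        out_shape.append(best)
    return tuple(out_shape)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _slice_stack(data: np.ndarray, k: int) -> np.ndarray:
    """Three-slice channels-last stack; boundary slices replicate the edge."""
    nz = data.shape[2]
    lo = max(k - 1, 0)
    hi = min(k + 1, nz - 1)
    return np.stack([data[:, :, lo], data[:, :, k], data[:, :, hi]], axis=-1)


def predict_padded(model, v: ImageVolume) -> ProbabilityMap:
    """Single forward pass per slice stack (2D) or whole volume (3D);
    output shape equals input shape. Extents not divisible by 2^L are
    zero-padded to the next multiple and the output cropped back."""
    spec: ArchitectureSpec = model.spec
    if not spec.padded:
        raise ValueError("predict_padded requires a padded model spec")
    data = np.asarray(v.data, dtype=np.float32)
    mult = 2 ** spec.layers
    if spec.dims == 3:
        x, sl = pad_to_multiple(data[..., None], mult, n_spatial=3)
        prob = model.forward_proba(x)[sl[:3]]
    else:
        nz = data.shape[2]
        prob = np.empty(data.shape, dtype=np.float32)
        for k in range(nz):
            x, sl = pad_to_multiple(_slice_stack(data, k), mult, n_spatial=2)
            prob[:, :, k] = model.forward_proba(x)[sl[:2]]
    prob = np.clip(prob, 0.0, 1.0)
    return ProbabilityMap(data=prob, spacing=v.spacing, subject_id=v.subject_id)


def predict_tiled(model, v: ImageVolume, plan: Optional[TilePlan] = None) -> ProbabilityMap:
    """Mirrored, tiled inference for unpadded 2D models: every tile's output
    window accumulates probability sums and visit counts, then divides."""
    spec: ArchitectureSpec = model.spec
    if spec.padded or spec.dims != 2:
        raise ValueError("predict_tiled requires an unpadded 2D model spec")
    data = np.asarray(v.data, dtype=np.float32)
    inplane = data.shape[:2]
    if plan is None:
        plan = plan_tiles(inplane, spec, default_tile_shape(spec, inplane))
    if plan.image_shape != inplane:
        raise ValueError(f"tile plan built for {plan.image_shape}, image is {inplane}")
    margin = plan.margin
    nz = data.shape[2]
    prob = np.zeros(data.shape, dtype=np.float64)
    counts = np.zeros(inplane, dtype=np.int32)
    first = True
    for k in range(nz):
        stack = mirror_pad(_slice_stack(data, k), margin)
        for (ix, iy), (ox, oy) in plan.tiles():
            tile = stack[ix:ix + plan.tile_in[0], iy:iy + plan.tile_in[1]]
            out = model.forward_proba(tile)
            ex = min(ox + plan.tile_out[0], inplane[0]) - ox
            ey = min(oy + plan.tile_out[1], inplane[1]) - oy
            prob[ox:ox + ex, oy:oy + ey, k] += out[:ex, :ey]
            if first:
                counts[ox:ox + ex, oy:oy + ey] += 1
        first = False
    if counts.min() < 1:
        raise RuntimeError("tile plan does not cover the image")
    prob /= counts[:, :, None]
    return ProbabilityMap(data=np.clip(prob, 0, 1).astype(np.float32),
                          spacing=v.spacing, subject_id=v.subject_id)


def binarize(p: ProbabilityMap, t: float) -> LabelMask:
    """Threshold a probability map: foreground strictly greater than ``t``."""
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    return LabelMask(data=(p.data > t).astype(np.uint8), spacing=p.spacing,
                     subject_id=p.subject_id)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(m: LabelMask, connectivity: int = 26) -> LabelMask:
    """Keep only the maximum-volume connected foreground component; ties are
    broken by the smallest lexicographic seed voxel. Idempotent."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    if m.data.sum() == 0:
        warnings.warn("largest_component called on an empty mask")
        return LabelMask(data=m.data.copy(), spacing=m.spacing, subject_id=m.subject_id)
    labeled, n = ndimage.label(m.data, structure=_STRUCTURES[connectivity])
    if n == 1:
        return LabelMask(data=m.data.copy(), spacing=m.spacing, subject_id=m.subject_id)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) == 1:
        keep = candidates[0]
    else:  # earliest voxel in C-order scan wins
        flat = labeled.ravel()
        firsts = {lab: np.flatnonzero(flat == lab)[0] for lab in candidates}
        keep = min(firsts, key=firsts.get)
    return LabelMask(data=(labeled == keep).astype(np.uint8), spacing=m.spacing,
                     subject_id=m.subject_id)


def upsample_probability(p: ProbabilityMap, target_grid: Sequence[int]) -> ProbabilityMap:
    """Bicubic in-plane upsampling of a probability map to the original grid
    (the slice axis is zoomed only if its extent differs)."""
    target = tuple(int(s) for s in target_grid)
    if target == p.shape:
        return p
    factors = tuple(t / s for t, s in zip(target, p.shape))
    out = ndimage.zoom(np.asarray(p.data, dtype=np.float64), factors, order=3,
                       mode="mirror")
    out = out[:target[0], :target[1], :target[2]]
    new_spacing = tuple(sp * s / t for sp, s, t in zip(p.spacing, p.shape, target))
    return ProbabilityMap(data=np.clip(out, 0, 1), spacing=new_spacing,
                          subject_id=p.subject_id)


def predict_subject(model, v: ImageVolume, t: float = 0.5,
                    postprocess: Optional[bool] = None,
                    original_grid: Optional[Sequence[int]] = None,
                    plan: Optional[TilePlan] = None) -> Tuple[ProbabilityMap, LabelMask]:
    """Probability map + thresholded mask for one subject.

    ``postprocess`` defaults to the model family's convention: the component
    filter for 2D models, none for 3D. When ``original_grid`` is given the
    probability map is first upsampled bicubically to that grid.
    """
    spec: ArchitectureSpec = model.spec
    if postprocess is None:
        postprocess = spec.dims == 2
    prob = predict_padded(model, v) if spec.padded else predict_tiled(model, v, plan)
    if original_grid is not None:
        prob = upsample_probability(prob, original_grid)
    mask = binarize(prob, t)
    if postprocess:
        mask = largest_component(mask)
    return prob, mask
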