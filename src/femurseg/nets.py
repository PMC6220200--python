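"""Encoder-decoder network construction and its shape algebra.

Architectures are the classic U-shape: L contracting levels of two 3^dims
convolutions (ReLU) followed by 2^dims max-pooling with stride 2, feature
maps doubling per level; a center level of two convolutions (or a dilated
pyramid — one padded convolution per dilation rate, outputs concatenated
along channels); and a mirrored expanding path of 2^dims up-convolutions
that halve the feature maps plus skip concatenation (center-cropped when
unpadded). A final 1-voxel convolution maps to 2 channels with softmax.

Weights are Xavier-initialized, biases 0.10; no normalization layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from ._nn import Conv, MaxPool, ShapeError, UpConv, center_crop, softmax2

__all__ = ["ArchitectureSpec", "build_network", "build_dilated_center",
           "output_shape", "receptive_field", "UNet", "ShapeError",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ArchitectureSpec:
    """The (dims, F, L, padding, dilation rates) tuple that fully determines
    a network.

    ``feature_maps`` (F) is the first-level width, ``layers`` (L) the number
    of contracting/expanding levels (0 = center only, a degenerate form used
    for analytic checks). ``in_channels`` defaults to 3 for 2D (three-slice
    stacks) and 1 for 3D.
    """

    dims: int = 3
    feature_maps: int = 32
    layers: int = 4
    padding: str = "padded"
    dilation_rates: Tuple[int, ...] = ()
    in_channels: Optional[int] = None
    center_reduce: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        if self.padding not in ("padded", "unpadded"):
            raise ValueError(f"padding must be 'padded' or 'unpadded', got {self.padding!r}")
        if self.padding == "unpadded" and self.dims != 2:
            raise ValueError("unpadded convolutions are only supported for dims=2")
        if self.feature_maps < 1:
            raise ValueError("feature_maps must be >= 1")
        if self.layers < 0:
            raise ValueError("layers must be >= 0")
        rates = tuple(int(r) for r in self.dilation_rates)
        object.__setattr__(self, "dilation_rates", rates)
        if rates:
            if rates[0] != 1:
                raise ValueError(f"dilation_rates must start at 1, got {rates}")
            if any(b <= a for a, b in zip(rates, rates[1:])):
                raise ValueError(f"dilation_rates must be strictly increasing, got {rates}")
        if self.in_channels is None:
            object.__setattr__(self, "in_channels", 3 if self.dims == 2 else 1)
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")

    @property
    def padded(self) -> bool:
        return self.padding == "padded"

    @property
    def center_width(self) -> int:
        """Feature-map count of one (plain or pyramid-branch) center conv."""
        return self.feature_maps * 2 ** self.layers

    def to_json(self) -> str:
        return json.dumps({"dims": self.dims, "feature_maps": self.feature_maps,
                           "layers": self.layers, "padding": self.padding,
                           "dilation_rates": list(self.dilation_rates),
                           "in_channels": self.in_channels,
                           "center_reduce": self.center_reduce})

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureSpec":
        d = json.loads(s)
        d["dilation_rates"] = tuple(d.get("dilation_rates", ()))
        return cls(**d)


# ---------------------------------------------------------------------------
# Shape algebra
# ---------------------------------------------------------------------------

def output_shape(spec: ArchitectureSpec, input_shape: Sequence[int]) -> Tuple[int, ...]:
    """Spatial output shape of a forward pass, or raise :class:`ShapeError`
    naming the level at which the shape collapses.

    Padded networks are shape-preserving (extents must be multiples of 2^L);
    unpadded ones follow the valid-convolution shrinkage recursion.
    """
    shape = tuple(int(s) for s in input_shape)
    if len(shape) != spec.dims:
        raise ShapeError(f"expected {spec.dims} spatial extents, got {shape}")
    L = spec.layers
    if spec.padded:
        for s in shape:
            if s < 2 ** L or s % (2 ** L) != 0:
                raise ShapeError(
                    f"padded net with L={L} needs extents divisible by {2 ** L}, got {shape}")
        return shape
    cur = list(shape)
    for lev in range(L):
        for ax, s in enumerate(cur):
            if s - 4 < 2 or (s - 4) % 2 != 0:
                raise ShapeError(f"axis {ax} collapses at encoder level {lev}: size {s}")
        cur = [(s - 4) // 2 for s in cur]
    if spec.dilation_rates:
        pass  # pyramid convs are padded: shape preserved
    else:
        for ax, s in enumerate(cur):
            if s - 4 < 1:
                raise ShapeError(f"axis {ax} collapses at center: size {s}")
        cur = [s - 4 for s in cur]
    for lev in reversed(range(L)):
        for ax, s in enumerate(cur):
            if 2 * s - 4 < 1:
                raise ShapeError(f"axis {ax} collapses at decoder level {lev}: size {s}")
        cur = [2 * s - 4 for s in cur]
    return tuple(cur)


def min_input_size(spec: ArchitectureSpec) -> int:
    """Smallest admissible per-axis input extent."""
    if spec.padded:
        return 2 ** spec.layers
    n = 2 ** spec.layers
    while True:
        try:
            output_shape(spec, (n,) * spec.dims)
            return n
        except ShapeError:
            n += 1


def receptive_field(spec: ArchitectureSpec) -> Tuple[int, ...]:
    """Analytic per-axis receptive field of the center-level units with
    respect to the input, accounting for dilation rates."""
    rf, jump = 1, 1
    for _ in range(spec.layers):
        rf += 2 * 2 * jump          # two 3-tap convs
        rf += 1 * jump              # 2-wide pooling window
        jump *= 2
    if spec.dilation_rates:
        rf += 2 * max(spec.dilation_rates) * jump   # widest pyramid branch
    else:
        rf += 2 * 2 * jump          # two plain center convs
    return (rf,) * spec.dims


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def build_dilated_center(spec: ArchitectureSpec, rng: Optional[np.random.Generator] = None,
                         c_in: Optional[int] = None) -> List[Conv]:
    """One padded 3^dims convolution per dilation rate, each producing the
    plain-center feature-map count; callers concatenate the outputs along the
    channel axis (spatial shape is preserved)."""
    if not spec.dilation_rates:
        raise ValueError("dilation_rates must be nonempty for a dilated center")
    rng = rng if rng is not None else np.random.default_rng(0)
    if c_in is None:
        c_in = (spec.feature_maps * 2 ** (spec.layers - 1)
                if spec.layers > 0 else spec.in_channels)
    return [Conv(spec.dims, c_in, spec.center_width, rng, k=3, dilation=r, padded=True)
            for r in spec.dilation_rates]


class UNet:
    """Parameterized encoder-decoder model built from an
    :class:`ArchitectureSpec`; deterministic given the seed."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        F, L, dims = spec.feature_maps, spec.layers, spec.dims
        padded = spec.padded

        self.enc: List[Tuple[Conv, Conv]] = []
        self.pools: List[MaxPool] = []
        c = spec.in_channels
        for lev in range(L):
            w = F * 2 ** lev
            self.enc.append((Conv(dims, c, w, rng, padded=padded),
                             Conv(dims, w, w, rng, padded=padded)))
            self.pools.append(MaxPool(dims))
            c = w

        cw = spec.center_width
        if spec.dilation_rates:
            self.center = build_dilated_center(spec, rng, c_in=c)
            center_out = cw * len(spec.dilation_rates)
            if spec.center_reduce is not None:
                self.center_reduce: Optional[Conv] = Conv(dims, center_out,
                                                          spec.center_reduce, rng, k=1)
                center_out = spec.center_reduce
            else:
                self.center_reduce = None
        else:
            self.center = [Conv(dims, c, cw, rng, padded=padded),
                           Conv(dims, cw, cw, rng, padded=padded)]
            self.center_reduce = None
            center_out = cw

        self.ups: List[UpConv] = []
        self.dec: List[Tuple[Conv, Conv]] = []
        c_below = center_out
        for lev in reversed(range(L)):
            w = F * 2 ** lev
            self.ups.append(UpConv(dims, c_below, w, rng))
            self.dec.append((Conv(dims, 2 * w, w, rng, padded=padded),
                             Conv(dims, w, w, rng, padded=padded)))
            c_below = w

        head_in = F if L > 0 else center_out
        self.head = Conv(dims, head_in, 2, rng, k=1, relu=False)

        self.layers_flat: List = []
        for c1, c2 in self.enc:
            self.layers_flat += [c1, c2]
        self.layers_flat += list(self.center)
        if self.center_reduce is not None:
            self.layers_flat.append(self.center_reduce)
        for up, (d1, d2) in zip(self.ups, self.dec):
            self.layers_flat += [up, d1, d2]
        self.layers_flat.append(self.head)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> List[np.ndarray]:
        return [layer.params[k] for layer in self.layers_flat for k in sorted(layer.params)]

    def gradients(self) -> List[np.ndarray]:
        return [layer.grads[k] for layer in self.layers_flat for k in sorted(layer.params)]

    def zero_grad(self) -> None:
        for layer in self.layers_flat:
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_state(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: List[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Input ``x``: channels-last spatial array; returns 2-channel logits."""
        if x.ndim != self.spec.dims + 1 or x.shape[-1] != self.spec.in_channels:
            raise ShapeError(f"expected shape (*spatial, {self.spec.in_channels}), got {x.shape}")
        output_shape(self.spec, x.shape[:-1])  # validate admissibility
        x = np.ascontiguousarray(x, dtype=np.float32)

        skips: List[np.ndarray] = []
        h = x
        for (c1, c2), pool in zip(self.enc, self.pools):
            h = c2.forward(c1.forward(h))
            skips.append(h)
            h = pool.forward(h)

        if self.spec.dilation_rates:
            h = np.concatenate([conv.forward(h) for conv in self.center], axis=-1)
            if self.center_reduce is not None:
                h = self.center_reduce.forward(h)
        else:
            h = self.center[1].forward(self.center[0].forward(h))

        self._skip_info = []
        for i, lev in enumerate(reversed(range(self.spec.layers))):
            h = self.ups[i].forward(h)
            s = skips[lev]
            if not self.spec.padded:
                s, sl = center_crop(s, h.shape[:-1])
                self._skip_info.append((skips[lev].shape, sl, s.shape[-1]))
            else:
                self._skip_info.append((skips[lev].shape, None, s.shape[-1]))
            h = np.concatenate([s, h], axis=-1)
            d1, d2 = self.dec[i]
            h = d2.forward(d1.forward(h))

        return self.head.forward(h)

    def forward_proba(self, x: np.ndarray) -> np.ndarray:
        """Foreground softmax probability of a forward pass."""
        return softmax2(self.forward(x))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for a single sample."""
        d = self.head.backward(dlogits)
        skip_grads = {}
        for i in reversed(range(self.spec.layers)):
            lev = self.spec.layers - 1 - i
            d1, d2 = self.dec[i]
            d = d1.backward(d2.backward(d))
            full_shape, sl, c_skip = self._skip_info[i]
            d_skip, d_up = d[..., :c_skip], d[..., c_skip:]
            if sl is not None:
                g = np.zeros(full_shape, dtype=np.float32)
                g[sl] = d_skip
                d_skip = g
            skip_grads[lev] = d_skip
            d = self.ups[i].backward(np.ascontiguousarray(d_up))

        if self.spec.dilation_rates:
            if self.center_reduce is not None:
                d = self.center_reduce.backward(d)
            cw = self.spec.center_width
            acc = None
            for j, conv in enumerate(self.center):
                dj = conv.backward(np.ascontiguousarray(d[..., j * cw:(j + 1) * cw]))
                acc = dj if acc is None else acc + dj
            d = acc
        else:
            d = self.center[0].backward(self.center[1].backward(d))

        for lev in reversed(range(self.spec.layers)):
            d = self.pools[lev].backward(d)
            d = d + skip_grads[lev]
            c1, c2 = self.enc[lev]
            d = c1.backward(c2.backward(d))


def build_network(spec: ArchitectureSpec, seed: int = 0) -> UNet:
    """Construct a seeded, Xavier-initialized network from its spec."""
    return UNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, path: Union[str, Path]) -> Path:
    """Save parameters with the spec embedded so inference rebuilds exactly."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i:04d}": p for i, p in enumerate(model.parameters())}
    np.savez(path, spec=model.spec.to_json(), **arrays)
    return path


def load_checkpoint(path: Union[str, Path]) -> UNet:
    with np.load(str(path), allow_pickle=False) as data:
        spec = ArchitectureSpec.from_json(str(data["spec"]))
        model = UNet(spec, seed=0)
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i:04d}"]
    return model
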