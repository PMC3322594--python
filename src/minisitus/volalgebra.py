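"""Volume algebra: voxel-wise map operations, projections and segmentation.

All binary operations require identical lattices (width, dims, origin) and
fail loudly on mismatch; use :func:`resample_to` for deliberate
re-registration onto a reference lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from minisitus.voldata import VolumeMap

__all__ = [
    "Image2D",
    "volaver",
    "voldiff",
    "volmult",
    "volhist_match",
    "crop_pad",
    "threshold",
    "project",
    "slice_map",
    "segment_connected",
    "resample_to",
    "imagediff",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: 6-connected structuring element shared with the Laplacian stencil.
SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


@dataclass
class Image2D:
    """A 2-D slice or projection of a map (same lattice conventions)."""

    width: float
    origin: np.ndarray
    data: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Image2D data must be 2-D")
        if self.width <= 0:
            raise ValueError("width must be positive")

    @property
    def dims(self):
        return self.data.shape


def _require_same_lattice(*maps: VolumeMap):
    first = maps[0]
    for other in maps[1:]:
        if not first.same_lattice(other):
            raise ValueError(
                f"lattice mismatch: width {first.width} vs {other.width}, dims "
                f"{first.dims} vs {other.dims}, origin {first.origin} vs {other.origin}")


def volaver(maps, mode: str = "mean") -> VolumeMap:
    """Voxel-wise mean (or sum with ``mode='sum'``) of maps on one lattice."""
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map")
    _require_same_lattice(*maps)
    stack = np.stack([m.data for m in maps])
    data = stack.sum(axis=0) if mode == "sum" else stack.mean(axis=0)
    return maps[0].with_data(data)


def voldiff(a: VolumeMap, b: VolumeMap) -> VolumeMap:
    """Difference map a - b."""
    _require_same_lattice(a, b)
    return a.with_data(a.data - b.data)


def volmult(a: VolumeMap, b: VolumeMap, binary_mask: bool = False) -> VolumeMap:
    """Voxel-wise product; with ``binary_mask`` the second map must be 0/1."""
    _require_same_lattice(a, b)
    if binary_mask and not np.all(np.isin(b.data, (0.0, 1.0))):
        raise ValueError("mask map must contain only 0 and 1")
    return a.with_data(a.data * b.data)


def volhist_match(source: VolumeMap, reference: VolumeMap):
    """Affine density matching: find alpha > 0, beta minimizing
    ||alpha * source + beta - reference||^2 (least squares).

    Returns ``(matched_map, alpha, beta)``.
    """
    _require_same_lattice(source, reference)
    s = source.data.ravel()
    r = reference.data.ravel()
    var = s.var()
    if var == 0:
        raise ValueError("source map has zero variance; affine match is degenerate")
    alpha = float(np.cov(s, r, bias=True)[0, 1] / var)
    if alpha <= 0:
        raise ValueError(f"best-fit scale alpha={alpha:.4g} is not positive")
    beta = float(r.mean() - alpha * s.mean())
    return source.with_data(alpha * source.data + beta), alpha, beta


def crop_pad(vmap: VolumeMap, lo_voxels, hi_voxels, fill: float = 0.0) -> VolumeMap:
    """Grow (positive counts) or shrink (negative) the lattice on each face.

    ``lo_voxels`` acts on the low-index faces — the origin shifts by
    ``-width * lo_voxels`` — and ``hi_voxels`` on the high-index faces.
    New voxels take the ``fill`` value.
    """
    lo = np.asarray(lo_voxels, dtype=int).reshape(3)
    hi = np.asarray(hi_voxels, dtype=int).reshape(3)
    new_dims = np.asarray(vmap.dims) + lo + hi
    if np.any(new_dims < 1):
        raise ValueError(f"resulting dims {tuple(new_dims)} must all be >= 1")
    data = np.full(tuple(new_dims), float(fill))
    src_lo = np.maximum(0, -lo)
    src_hi = np.minimum(vmap.dims, np.asarray(vmap.dims) + hi)
    dst_lo = np.maximum(0, lo)
    sl_src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    sl_dst = tuple(slice(d, d + (b - a)) for d, a, b in zip(dst_lo, src_lo, src_hi))
    data[sl_dst] = vmap.data[sl_src]
    return VolumeMap(vmap.width, vmap.origin - vmap.width * lo, data)


def threshold(vmap: VolumeMap, level: float) -> VolumeMap:
    """Zero all values below ``level``; keep values >= level."""
    return vmap.with_data(np.where(vmap.data >= level, vmap.data, 0.0))


def project(vmap: VolumeMap, axis: str = "z") -> Image2D:
    """Integrate along an axis: sum times voxel width (line-integral
    Riemann sum), returning the remaining two axes as an image."""
    ax = _axis(axis)
    keep = [i for i in range(3) if i != ax]
    data = vmap.data.sum(axis=ax) * vmap.width
    return Image2D(vmap.width, vmap.origin[keep], data)


def slice_map(vmap: VolumeMap, axis: str, index: int) -> Image2D:
    """Extract a single lattice plane perpendicular to ``axis``."""
    ax = _axis(axis)
    if not 0 <= index < vmap.dims[ax]:
        raise IndexError(f"slice index {index} out of range for axis {axis} "
                         f"with {vmap.dims[ax]} planes")
    keep = [i for i in range(3) if i != ax]
    data = np.take(vmap.data, index, axis=ax)
    return Image2D(vmap.width, vmap.origin[keep], data)


def imagediff(a: Image2D, b: Image2D) -> Image2D:
    if a.dims != b.dims or abs(a.width - b.width) > 1e-9:
        raise ValueError("image lattice mismatch")
    return Image2D(a.width, a.origin.copy(), a.data - b.data)


def segment_connected(vmap: VolumeMap, level: float):
    """6-connected components of {density >= level}.

    Returns ``(labels, n)`` where ``labels`` is an integer array on the map
    lattice with components numbered 1..n by descending total density and
    0 for background.
    """
    mask = vmap.data >= level
    raw, n = ndimage.label(mask, structure=SIX_CONNECTED)
    if n == 0:
        return raw, 0
    totals = ndimage.sum_labels(vmap.data, raw, index=np.arange(1, n + 1))
    order = np.argsort(totals)[::-1]
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[raw], n


def resample_to(vmap: VolumeMap, reference: VolumeMap, order: int = 1) -> VolumeMap:
    """Trilinearly resample a map onto the lattice of ``reference``.

    The deliberate registration step for maps on different lattices;
    values outside the source extent are zero.
    """
    ref_idx = np.indices(reference.dims, dtype=float)
    phys = reference.origin[:, None, None, None] + reference.width * ref_idx
    src = (phys - vmap.origin[:, None, None, None]) / vmap.width
    data = ndimage.map_coordinates(vmap.data, src, order=order, mode="constant")
    return VolumeMap(reference.width, reference.origin.copy(), data)


def _axis(axis: str) -> int:
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}")
    return _AXIS_INDEX[axis]
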