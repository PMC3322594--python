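"""Multi-fragment off-lattice refinement (collage).

All rigid fragments are optimized *simultaneously* against the target
map: the calculated density is the rasterized sum of every fragment, and
the score is the mean-free-less CC of :mod:`minisitus.scoring`.  Because
that CC divides by the norm of the summed density, overlapping fragments
inflate the denominator without adding matched signal — the normalization
itself penalizes steric clashes, so no explicit clash term is needed.
Optimization is derivative-free Powell over the 6K pose parameters
(translations in A, rotations in degrees about each fragment's centroid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from minisitus.convert import trilinear_project
from minisitus.scoring import ScoreConfig, _LAPLACIAN_STENCIL, cc_arrays, laplacian
from minisitus.transforms import RigidTransform
from minisitus.voldata import VolumeMap

__all__ = ["FragmentSet", "collage_refine"]


@dataclass
class FragmentSet:
    """Rigid fragments with their current poses.

    ``transforms[k]`` maps fragment k's stored coordinates to its current
    position; ``frozen[k]`` excludes a fragment from optimization while it
    still contributes density.
    """

    fragments: list
    transforms: list = None
    frozen: list = None

    def __post_init__(self):
        if not self.fragments:
            raise ValueError("need at least one fragment")
        k = len(self.fragments)
        if self.transforms is None:
            self.transforms = [RigidTransform.identity() for _ in range(k)]
        if self.frozen is None:
            self.frozen = [False] * k
        if not (len(self.transforms) == len(self.frozen) == k):
            raise ValueError("fragments, transforms and frozen must align")

    def __len__(self) -> int:
        return len(self.fragments)

    def posed_coords(self, k: int) -> np.ndarray:
        return self.transforms[k].apply(self.fragments[k].coords)

    def posed_models(self):
        return [m.transformed(t) for m, t in zip(self.fragments, self.transforms)]


def _increment_transform(params: np.ndarray, pivot: np.ndarray) -> RigidTransform:
    """Small-motion transform: rotation (deg, xyz Euler increments) about
    ``pivot`` plus translation (A)."""
    t = params[:3]
    R = Rotation.from_euler("xyz", params[3:6], degrees=True).as_matrix()
    return RigidTransform.about_pivot(R, pivot, t)


def collage_refine(target: VolumeMap, frags: FragmentSet,
                   config: ScoreConfig = None, max_steps: int = 50):
    """Jointly refine fragment poses to the nearest CC maximum.

    A single Powell direction-set pass per ``max_steps`` unit; the score
    trace (CC after each pass) is monotone non-decreasing because Powell
    never accepts a worse point.  ``max_steps=1`` performs exactly one
    pass, the granularity the symmetry-constrained loop relies on.

    Returns ``(refined FragmentSet, score trace)``.
    """
    config = config or ScoreConfig()
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    width = target.width
    kern = config.kernel.rasterize(width)
    t_data = (laplacian(target, config.mask_edges).data if config.use_laplacian
              else target.data)
    t_norm = np.linalg.norm(t_data)
    if t_norm == 0:
        raise ValueError("target map has zero norm")

    base_coords = [frags.posed_coords(k) for k in range(len(frags))]
    pivots = [c.mean(axis=0) for c in base_coords]
    active = [k for k in range(len(frags)) if not frags.frozen[k]]

    from scipy.signal import fftconvolve

    def calc_density(x: np.ndarray) -> np.ndarray:
        lattice = np.zeros(target.dims)
        for slot, k in enumerate(active):
            inc = _increment_transform(x[6 * slot:6 * slot + 6], pivots[k])
            coords = inc.apply(base_coords[k])
            lattice += trilinear_project(coords, np.ones(len(coords)), width,
                                         target.origin, target.dims)
        for k in range(len(frags)):
            if frags.frozen[k]:
                lattice += trilinear_project(
                    base_coords[k], np.ones(len(base_coords[k])), width,
                    target.origin, target.dims)
        dens = fftconvolve(lattice, kern, mode="same")
        if config.use_laplacian:
            dens = ndimage.convolve(dens, _LAPLACIAN_STENCIL,
                                    mode="nearest") / width ** 2
        return dens

    def score(x: np.ndarray) -> float:
        return cc_arrays(t_data, calc_density(x))

    def objective(x: np.ndarray) -> float:
        s = score(x)
        if not np.isfinite(s):
            raise FloatingPointError("non-finite score (degenerate rasterization)")
        return -s

    x0 = np.zeros(6 * len(active))
    trace = [score(x0)]
    if active:
        res = minimize(objective, x0, method="Powell",
                       callback=lambda xk: trace.append(score(xk)),
                       options={"maxiter": max_steps, "xtol": 0.01,
                                "ftol": 1e-7, "maxfev": 200000})
        x_final = res.x
        trace.append(float(-res.fun))
    else:
        x_final = x0

    new_transforms = list(frags.transforms)
    for slot, k in enumerate(active):
        inc = _increment_transform(x_final[6 * slot:6 * slot + 6], pivots[k])
        new_transforms[k] = inc.compose(frags.transforms[k])
    refined = FragmentSet(list(frags.fragments), new_transforms, list(frags.frozen))
    return refined, np.asarray(trace)
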