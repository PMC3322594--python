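"""Symmetry-mate generation and the symmetry-constrained refinement loop.

``pdbsymm`` generates cyclic (C), dihedral (D) or helical (H: rise +
twist) copies of a master structure about an axis that defaults to the
z direction through the target map's geometric center.

``symmetry_constrained_refine`` implements the scripted loop that couples
symmetry generation with multi-fragment refinement: (i) pick the master,
(ii) generate mates, (iii) treat the mates as independent fragments,
(iv) refine them with a *single* optimization pass, keep the refined
master, (v) loop until the master stops moving, (vi) regenerate the final
mates from the master.  Because the mates are regenerated from the master
after every pass, the output complex is exactly symmetric by construction
— the net effect is a symmetry-enforced optimization without a dedicated
constrained optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from minisitus.refine import FragmentSet, collage_refine
from minisitus.scoring import ScoreConfig
from minisitus.transforms import RigidTransform, kabsch
from minisitus.voldata import AtomicModel, VolumeMap

__all__ = ["SymmetrySpec", "pdbsymm", "pdbsymm_transforms",
           "symmetry_constrained_refine", "SymmetryFitResult", "map_center"]


@dataclass
class SymmetrySpec:
    """C/D/H symmetry description.

    ``order`` applies to C and D; helical symmetry takes ``rise`` (A),
    ``twist`` (degrees) and ``count`` copies.  ``axis`` is the symmetry
    axis direction; ``point`` a point on the axis (when None, callers
    derive it from the target map center).  ``dihedral_phase`` sets the
    in-plane direction (degrees from x) of the D-group 2-fold axes.
    """

    type: str
    order: int = 1
    rise: float = 0.0
    twist: float = 0.0
    count: int = 1
    axis: tuple = (0.0, 0.0, 1.0)
    point: tuple = None
    dihedral_phase: float = 0.0

    def __post_init__(self):
        if self.type not in ("C", "D", "H"):
            raise ValueError(f"symmetry type must be C, D or H, got {self.type!r}")
        if self.type in ("C", "D") and self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.type == "H" and self.count < 1:
            raise ValueError(f"helical count must be >= 1, got {self.count}")
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis direction must be nonzero")
        self.axis = tuple(axis / n)

    @property
    def n_copies(self) -> int:
        return {"C": self.order, "D": 2 * self.order, "H": self.count}[self.type]


def map_center(vmap: VolumeMap) -> np.ndarray:
    """Geometric center of a map's lattice — the default axis anchor."""
    return vmap.origin + vmap.width * (np.asarray(vmap.dims) - 1) / 2.0


def pdbsymm_transforms(spec: SymmetrySpec, point=None):
    """The rigid transforms producing each symmetry mate (copy 0 = identity)."""
    p = np.zeros(3) if point is None and spec.point is None else \
        np.asarray(point if point is not None else spec.point, dtype=float)
    axis = np.asarray(spec.axis)
    out = []
    if spec.type in ("C", "D"):
        for k in range(spec.order):
            out.append(RigidTransform.rotation_about_axis(axis, 360.0 * k / spec.order, p))
        if spec.type == "D":
            # 2-fold axes perpendicular to the main axis, at dihedral_phase from x
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(ref, axis)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            perp = ref - np.dot(ref, axis) * axis
            perp /= np.linalg.norm(perp)
            phase = RigidTransform.rotation_about_axis(axis, spec.dihedral_phase, p)
            flip = RigidTransform.rotation_about_axis(phase.rotation @ perp, 180.0, p)
            for k in range(spec.order):
                out.append(flip.compose(out[k]))
    else:
        for k in range(spec.count):
            rot = RigidTransform.rotation_about_axis(axis, spec.twist * k, p)
            shift = RigidTransform(np.eye(3), spec.rise * k * axis)
            out.append(shift.compose(rot))
    return out


def pdbsymm(master: AtomicModel, spec: SymmetrySpec, point=None):
    """Generate symmetry-related copies of a master structure.

    Copy 0 is the master verbatim; chains are renamed A, B, C, ... per mate.
    """
    transforms = pdbsymm_transforms(spec, point)
    mates = []
    for k, rt in enumerate(transforms):
        mate = master if k == 0 else master.transformed(rt)
        mate = AtomicModel(mate.coords, list(mate.names), list(mate.resnames),
                           [chr(ord("A") + k % 26)] * len(mate),
                           list(mate.resseqs), mate.occupancies.copy(),
                           mate.bfactors.copy())
        mates.append(mate)
    return mates


@dataclass
class SymmetryFitResult:
    """Outcome of the symmetry-constrained loop."""

    master: AtomicModel
    mates: list
    history: list = field(default_factory=list)  # (loop, shift A, rot deg, cc)
    converged: bool = False


def symmetry_constrained_refine(target: VolumeMap, master: AtomicModel,
                                spec: SymmetrySpec, loops: int = 10,
                                config: ScoreConfig = None,
                                conv_shift: float = 0.05,
                                conv_rot: float = 0.1) -> SymmetryFitResult:
    """Symmetry-enforced refinement of a master structure against a map.

    Each loop regenerates the mates from the current master, runs exactly
    one joint Powell pass of :func:`~minisitus.refine.collage_refine` over
    all mates, and keeps the refined master.  Convergence: the master's
    centroid shift drops below ``conv_shift`` (A) and its rotation below
    ``conv_rot`` (degrees) between loops.  The returned mates are
    regenerated from the final master and are therefore exactly symmetric.
    """
    if loops < 1:
        raise ValueError("loops must be >= 1")
    point = (np.asarray(spec.point, dtype=float) if spec.point is not None
             else map_center(target))
    history = []
    converged = False
    for loop in range(1, loops + 1):
        mates = pdbsymm(master, spec, point)
        refined, trace = collage_refine(target, FragmentSet(mates),
                                        config=config, max_steps=1)
        new_master = refined.posed_models()[0]
        move = kabsch(master.coords, new_master.coords)
        shift = float(np.linalg.norm(new_master.centroid - master.centroid))
        rot = move.rotation_angle_deg()
        master = new_master
        history.append((loop, shift, rot, float(trace[-1])))
        if shift < conv_shift and rot < conv_rot:
            converged = True
            break
    return SymmetryFitResult(master, pdbsymm(master, spec, point), history, converged)
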