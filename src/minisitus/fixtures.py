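"""Synthetic fixtures: reproducible pseudo-atomic blobs and simulated maps.

These generators stand in for experimental assemblies in tests and
examples: an asymmetric pseudo-atom monomer (no accidental self-symmetry)
is replicated by a symmetry operation into an oligomer and rasterized
into a simulated density map at a stated resolution, with the planted
per-protomer transforms returned as ground truth.

Default conditions mirror a typical low-resolution fitting problem: a
hexameric ring, a 15 A (Situs-convention) map sampled at 3 A voxels
(two voxels per sigma = 7.5 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from minisitus.convert import Kernel, pdb2vol
from minisitus.symmetry import SymmetrySpec, pdbsymm_transforms
from minisitus.transforms import RigidTransform
from minisitus.voldata import AtomicModel, VolumeMap

__all__ = ["FixtureSpec", "AssemblyFixture", "make_monomer", "make_assembly",
           "make_hexamer_map"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic assembly fixture (same seed, same bytes).

    Defaults emulate a RecA-like hexameric ring: protomers of ~12 A radius
    of gyration in contact at a 35 A ring radius, imaged at 15 A
    resolution on a 3 A lattice.
    """

    seed: int = 0
    n_atoms: int = 150
    n_lobes: int = 6
    lobe_sigma: float = 3.5
    radius_gyration: float = 12.0
    ring_radius: float = 35.0
    symmetry: SymmetrySpec = field(
        default_factory=lambda: SymmetrySpec("C", order=6, point=(0.0, 0.0, 0.0)))
    resolution: float = 15.0
    width: float = 3.0


@dataclass
class AssemblyFixture:
    """A simulated map with its planted ground truth."""

    map: VolumeMap
    monomer: AtomicModel          # the placed master protomer
    transforms: list              # RigidTransform per protomer (copy 0 = identity)
    spec: FixtureSpec


def make_monomer(spec: FixtureSpec = None) -> AtomicModel:
    """Reproducible asymmetric, lumpy blob of pseudo-atoms.

    Atoms are drawn around ``n_lobes`` sub-domain centers (Gaussian lobes
    of spread ``lobe_sigma``) scattered in an anisotropic ellipsoid (axis
    scales 1 : 0.75 : 0.55) — the lobes give the monomer interior density
    features like a protein's domains, and the anisotropy keeps the
    principal moments of inertia distinct by well over 10% so no
    accidental self-symmetry can alias planted poses.  The cloud is
    rescaled to the requested radius of gyration.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    lobe_centers = rng.standard_normal((spec.n_lobes, 3)) * np.array([1.0, 0.75, 0.55])
    lobe_of = rng.integers(spec.n_lobes, size=spec.n_atoms)
    pts = lobe_centers[lobe_of] + rng.standard_normal((spec.n_atoms, 3)) \
        * spec.lobe_sigma / spec.radius_gyration
    pts -= pts.mean(axis=0)
    rg = np.sqrt(np.mean(np.sum(pts ** 2, axis=1)))
    pts *= spec.radius_gyration / rg
    return AtomicModel(pts)


def make_assembly(spec: FixtureSpec = None) -> AssemblyFixture:
    """Simulated symmetric-assembly map plus planted protomer transforms.

    The monomer is placed with its centroid at ``ring_radius`` from the
    symmetry axis, replicated by the symmetry spec, and rasterized with a
    Gaussian kernel at ``resolution`` on a ``width`` lattice.
    """
    spec = spec or FixtureSpec()
    monomer = make_monomer(spec)
    placed = monomer.with_coords(monomer.coords
                                 + np.array([spec.ring_radius, 0.0, 0.0]))
    transforms = pdbsymm_transforms(spec.symmetry,
                                    point=spec.symmetry.point or (0, 0, 0))
    all_coords = np.concatenate([rt.apply(placed.coords) for rt in transforms])
    assembly = AtomicModel(all_coords)
    kernel = Kernel("gaussian", resolution=spec.resolution)
    vmap = pdb2vol(assembly, spec.width, kernel)
    return AssemblyFixture(vmap, placed, transforms, spec)


def make_hexamer_map(seed: int = 0, **overrides) -> AssemblyFixture:
    """The standard C6 hexamer fixture at 15 A resolution, 3 A voxels."""
    spec = FixtureSpec(seed=seed, **overrides)
    return make_assembly(spec)
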