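"""Structure-type conversion: atoms <-> volumes <-> SAXS bead models.

``pdb2vol`` lowers the resolution of an atomic model by projecting atoms
onto a cubic lattice with trilinear interpolation and convolving the
lattice with a point-spread kernel (Gaussian, triangular or hard-sphere).
``vol2pdb`` encodes positive densities as pseudo-atoms so that volume data
can enter rigid-body docking free of the lattice.  ``pdb2sax`` coarse-grains
an atomic structure into equal spheres on a hexagonal close-packed (HCP)
lattice, the standard representation of SAXS-derived shapes; bead radii
travel in the PDB occupancy field.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from minisitus.voldata import AtomicModel, VolumeMap

log = logging.getLogger(__name__)

__all__ = [
    "Kernel",
    "BeadModel",
    "pdb2vol",
    "vol2pdb",
    "pdb2sax",
    "beads2vol",
    "recommended_isolevel",
    "ATOMIC_MASSES",
]

#: Monoisotopic-ish masses for mass weighting, keyed by element symbol.
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "P": 30.974, "S": 32.06, "FE": 55.845, "ZN": 65.38, "MG": 24.305}

_GAUSSIAN_TRUNCATION_SIGMAS = 3.0  # amplitude exp(-13.5) ~ 1.4e-6 at the cut


@dataclass(frozen=True)
class Kernel:
    """Point-spread kernel for resolution lowering.

    For the Gaussian family the width is set by the Situs resolution
    convention: ``resolution`` r_s = 2 sigma and the kernel value at
    distance r is ``exp(-3 r^2 / (2 sigma^2))``.  Triangular kernels fall
    linearly to zero at ``radius``; hard spheres are 1 inside ``radius``.
    Amplitudes are not normalized — total density scales with the kernel's
    lattice sum, which :meth:`lattice_sum` reports.
    """

    family: str = "gaussian"
    resolution: float = None
    radius: float = None

    def __post_init__(self):
        if self.family not in ("gaussian", "triangular", "hard_sphere"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian":
            if self.resolution is None or self.resolution <= 0:
                raise ValueError("gaussian kernel needs a positive resolution (A)")
        else:
            if self.radius is None or self.radius < 0:
                raise ValueError(f"{self.family} kernel needs a nonnegative radius (A)")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation, sigma = r_s / 2."""
        if self.family != "gaussian":
            raise AttributeError("sigma is defined for gaussian kernels only")
        return self.resolution / 2.0

    @property
    def truncation_radius(self) -> float:
        """Finite support radius (A) after truncation."""
        if self.family == "gaussian":
            return _GAUSSIAN_TRUNCATION_SIGMAS * self.sigma
        return self.radius

    def evaluate(self, r) -> np.ndarray:
        """Kernel amplitude at distance(s) ``r`` (A), zero beyond support."""
        r = np.asarray(r, dtype=float)
        if self.family == "gaussian":
            out = np.exp(-3.0 * r ** 2 / (2.0 * self.sigma ** 2))
            return np.where(r <= self.truncation_radius, out, 0.0)
        if self.family == "triangular":
            if self.radius == 0:
                return np.where(r <= 0, 1.0, 0.0)
            return np.maximum(0.0, 1.0 - r / self.radius)
        return np.where(r <= self.radius, 1.0, 0.0)

    def rasterize(self, width: float) -> np.ndarray:
        """Sample the kernel on a cubic lattice of spacing ``width`` (odd cube)."""
        m = int(math.ceil(self.truncation_radius / width - 1e-9))
        ax = np.arange(-m, m + 1) * width
        r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                    + ax[None, None, :] ** 2)
        return self.evaluate(r)

    def lattice_sum(self, width: float) -> float:
        """Sum of the rasterized kernel; total map density is
        (total projected weight) * lattice_sum."""
        return float(self.rasterize(width).sum())


@dataclass
class BeadModel:
    """Equal spheres on a hexagonal close-packed lattice (SAXS shape model)."""

    centers: np.ndarray
    bead_radius: float

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.bead_radius <= 0:
            raise ValueError("bead radius must be positive")

    def __len__(self) -> int:
        return len(self.centers)

    def to_atomic_model(self) -> AtomicModel:
        """Beads as pseudo-atoms with the radius in the occupancy field."""
        n = len(self.centers)
        return AtomicModel(self.centers, names=["C"] * n, resnames=["BED"] * n,
                           occupancies=np.full(n, self.bead_radius))


def _atom_weights(model: AtomicModel, mass_weighting: bool,
                  occupancy_weighting: bool = False) -> np.ndarray:
    if mass_weighting and occupancy_weighting:
        raise ValueError("choose at most one of mass/occupancy weighting")
    if occupancy_weighting:
        return model.occupancies.astype(float)
    if not mass_weighting:
        return np.ones(len(model))
    weights = np.empty(len(model))
    for i, name in enumerate(model.names):
        key = name.strip().upper()
        elem = key[:2] if key[:2] in ATOMIC_MASSES else key[:1]
        weights[i] = ATOMIC_MASSES.get(elem, ATOMIC_MASSES["C"])
    return weights


def trilinear_project(coords: np.ndarray, weights: np.ndarray, width: float,
                      origin: np.ndarray, dims) -> np.ndarray:
    """Scatter point weights onto a lattice by trilinear interpolation.

    Each point's weight is distributed over the 8 voxels surrounding it;
    the lattice sum equals the total input weight whenever all points lie
    strictly inside the lattice.
    """
    lattice = np.zeros(dims)
    g = (coords - origin) / width
    base = np.floor(g).astype(int)
    frac = g - base
    nx, ny, nz = dims
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (weights
                     * (frac[:, 0] if dx else 1 - frac[:, 0])
                     * (frac[:, 1] if dy else 1 - frac[:, 1])
                     * (frac[:, 2] if dz else 1 - frac[:, 2]))
                ii = base[:, 0] + dx
                jj = base[:, 1] + dy
                kk = base[:, 2] + dz
                ok = ((ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny)
                      & (kk >= 0) & (kk < nz))
                np.add.at(lattice, (ii[ok], jj[ok], kk[ok]), w[ok])
    return lattice


def pdb2vol(model: AtomicModel, width: float, kernel: Kernel,
            mass_weighting: bool = False, occupancy_weighting: bool = False,
            lattice_phase=None) -> VolumeMap:
    """Simulate a density map from an atomic model.

    Two stages: (1) trilinear projection of unit (or mass) weights onto a
    cubic lattice of spacing ``width``; (2) convolution with the rasterized
    kernel.  The lattice is padded by the kernel support so the convolution
    never clips; the origin shifts accordingly.

    Parameters
    ----------
    lattice_phase : array-like (3,), optional
        When given, the lattice is phase-locked so that ``lattice_phase``
        falls exactly on a lattice point — required when the result must
        share integer-voxel translations with an existing map.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if width <= 0:
        raise ValueError("voxel width must be positive")
    if kernel.family == "gaussian" and kernel.resolution < 2.0 * width:
        warnings.warn(
            f"gaussian resolution {kernel.resolution} A below 2x voxel width "
            f"{width} A: kernel undersampled", stacklevel=2)

    margin = int(math.ceil(kernel.truncation_radius / width)) + 1
    lo = model.coords.min(axis=0)
    hi = model.coords.max(axis=0)
    phase = np.zeros(3) if lattice_phase is None else np.asarray(lattice_phase, float)
    origin = phase + width * np.floor((lo - phase) / width) - margin * width
    dims = tuple(np.ceil((hi - origin) / width).astype(int) + margin + 1)

    weights = _atom_weights(model, mass_weighting, occupancy_weighting)
    lattice = trilinear_project(model.coords, weights, width, origin, dims)
    kern = kernel.rasterize(width)
    data = fftconvolve(lattice, kern, mode="same")
    log.debug("pdb2vol: projected weight %.6g, kernel lattice sum %.6g, "
              "total density %.6g", weights.sum(), kern.sum(), data.sum())
    return VolumeMap(width, origin, data)


def vol2pdb(vmap: VolumeMap, threshold: float = 0.0) -> AtomicModel:
    """Encode positive densities above ``threshold`` as pseudo-atoms.

    One atom per voxel with density > max(0, threshold), placed at the
    voxel's physical coordinate, density in the occupancy field, ordered
    x-fastest like the map storage.
    """
    cut = max(0.0, threshold)
    flat = vmap.data.ravel(order="F")
    keep = flat > cut
    if not keep.any():
        raise ValueError(f"no voxel with density above {cut}")
    positions = vmap.voxel_positions()[keep]
    dens = flat[keep]
    n = len(dens)
    return AtomicModel(positions, names=["QV"] * n, resnames=["VOL"] * n,
                       occupancies=dens)


def hcp_lattice(lo: np.ndarray, hi: np.ndarray, spacing: float,
                anchor: np.ndarray) -> np.ndarray:
    """Hexagonal close-packed sites covering the box [lo, hi].

    Close-packed planes are normal to z with ABAB stacking; every
    nearest-neighbor distance equals ``spacing``.  The lattice is phased so
    that ``anchor`` coincides with a site of an A layer.
    """
    a = spacing
    row = a * math.sqrt(3.0) / 2.0          # in-plane row spacing
    layer = a * math.sqrt(2.0 / 3.0)        # inter-layer spacing
    b_shift = np.array([a / 2.0, a / (2.0 * math.sqrt(3.0)), 0.0])

    k0 = int(math.floor((lo[2] - anchor[2]) / layer)) - 1
    k1 = int(math.ceil((hi[2] - anchor[2]) / layer)) + 1
    sites = []
    for k in range(k0, k1 + 1):
        z = anchor[2] + k * layer
        off = b_shift if (k % 2) else np.zeros(3)
        j0 = int(math.floor((lo[1] - anchor[1] - off[1]) / row)) - 1
        j1 = int(math.ceil((hi[1] - anchor[1] - off[1]) / row)) + 1
        for j in range(j0, j1 + 1):
            y = anchor[1] + off[1] + j * row
            xshift = anchor[0] + off[0] + (j % 2) * (a / 2.0)
            i0 = int(math.floor((lo[0] - xshift) / a)) - 1
            i1 = int(math.ceil((hi[0] - xshift) / a)) + 1
            xs = xshift + np.arange(i0, i1 + 1) * a
            layer_sites = np.column_stack(
                [xs, np.full(len(xs), y), np.full(len(xs), z)])
            sites.append(layer_sites)
    return np.concatenate(sites, axis=0)


def pdb2sax(model: AtomicModel, bead_radius: float) -> BeadModel:
    """Coarse-grain an atomic model into an HCP bead model.

    An HCP lattice with center spacing ``2 * bead_radius`` (contact
    packing) is overlaid on the structure, phased so one site coincides
    with the atom centroid; a bead is kept iff at least one atom lies
    within ``bead_radius`` of its center.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if bead_radius <= 0:
        raise ValueError("bead radius must be positive")
    pad = bead_radius
    lo = model.coords.min(axis=0) - pad
    hi = model.coords.max(axis=0) + pad
    sites = hcp_lattice(lo, hi, 2.0 * bead_radius, model.centroid)
    tree = cKDTree(model.coords)
    dist, _ = tree.query(sites, k=1, distance_upper_bound=bead_radius * (1 + 1e-12))
    keep = np.isfinite(dist)
    if not keep.any():
        raise ValueError("no lattice site within the bead radius of any atom")
    return BeadModel(sites[keep], bead_radius)


def beads2vol(beads: BeadModel, width: float, kernel: Kernel = None,
              preset: str = "docking") -> VolumeMap:
    """Rasterize a bead model into a density map.

    Presets when no kernel is given: ``docking`` uses a hard-sphere kernel
    with radius = bead radius; ``envelope`` uses a Gaussian whose
    half-maximum radius equals the bead radius (for rendering the shape as
    a smooth isosurface at half maximum).
    """
    if len(beads) == 0:
        raise ValueError("empty bead model")
    if kernel is None:
        if preset == "docking":
            kernel = Kernel("hard_sphere", radius=beads.bead_radius)
        elif preset == "envelope":
            # exp(-3 r^2 / 2 sigma^2) = 1/2 at r = sigma sqrt(2 ln 2 / 3)
            sigma = beads.bead_radius / math.sqrt(2.0 * math.log(2.0) / 3.0)
            kernel = Kernel("gaussian", resolution=2.0 * sigma)
        else:
            raise ValueError(f"unknown preset {preset!r}")
    return pdb2vol(beads.to_atomic_model(), width, kernel)


def recommended_isolevel(vmap: VolumeMap, molecular_volume: float,
                         fraction: float = 1.35) -> float:
    """Isolevel enclosing ``fraction`` times the molecular volume.

    Resolution lowering erodes convex and fills concave features, so the
    rendering threshold is conventionally set to enclose 120-150% of the
    molecular volume.  Returns the density t such that the volume of
    voxels >= t is nearest to ``fraction * molecular_volume``.
    """
    if molecular_volume <= 0:
        raise ValueError("molecular volume must be positive")
    voxel_vol = vmap.width ** 3
    target = int(round(fraction * molecular_volume / voxel_vol))
    target = max(target, 1)
    flat = np.sort(vmap.data.ravel())[::-1]
    n_positive = int((flat > 0).sum())
    if target > n_positive:
        raise ValueError(
            f"requested volume ({target} voxels) exceeds the map's "
            f"positive-density volume ({n_positive} voxels)")
    return float(flat[target - 1])
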