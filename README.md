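# minisitus

A Python toolkit for multi-resolution structural modeling: docking atomic
structures into low-resolution density maps from cryo-electron microscopy,
tomography or small-angle X-ray scattering (SAXS), with explicit, testable
implementations of the conventions this kind of hybrid modeling depends on —
map coordinate systems, Gaussian-kernel resolution definitions, the
cross-correlation normalization, coarse-graining rules and symmetry
constructions.

It is aimed at structural bioinformaticians who need these conventions as a
scriptable library (plus a thin `minisitus` command-line interface) rather
than as a collection of opaque binaries: every convention is a documented,
unit-tested function.

## What it implements

**Map model and formats.** A density map is a cubic lattice with voxel
spacing *w* (Å) whose origin is the physical coordinate of voxel (0,0,0);
voxel (i,j,k) sits at `origin + w·(i,j,k)`, with the x index varying fastest
in storage. I/O for the Situs ASCII format (header `WIDTH ORIGX ORIGY ORIGZ
NX NY NZ`), a modern MRC/CCP4 binary subset (32-bit float, axes x,y,z,
orthogonal cells, endianness auto-detected), and fixed-column PDB.

**Structure-type conversion.** `pdb2vol` lowers the resolution of an atomic
model by trilinear projection onto the lattice followed by convolution with
a Gaussian, triangular or hard-sphere kernel; `vol2pdb` encodes positive
densities as pseudo-atoms (density → occupancy) so maps can be docked free
of the lattice; `pdb2sax` coarse-grains a structure into equal spheres on a
hexagonal close-packed lattice (bead radius → occupancy).

**Resolution calculus.** The Gaussian kernel is
`exp(−3r²/2σ²)`, and the package interconverts the field's resolution
conventions — crystallographic r_c (inverse Fourier cutoff), Rayleigh point
r_p, Situs r_s = 2σ, EMAN r_e, FWHM and σ — by matching each kernel to the
Airy disk `[J₁(x)/x]²` of equal FWHM. All factors (r_p = 0.610 r_c,
FWHM = 0.514 r_c, r_s = 1.471 FWHM = 0.756 r_c, r_e = 1.282 r_s, …) are
derived at runtime from the Bessel root and half-maximum conditions; none
is hard-coded.

**Correlation fitting.** The cross-correlation of a map ρ_vol and a
simulated density ρ_calc is the cosine form

    CC = Σ ρ_vol·ρ_calc / (‖ρ_vol‖·‖ρ_calc‖)

*without* mean subtraction, so CC ∈ [0,1] for nonnegative densities.
`colores_search` samples rotations exhaustively on a quasi-uniform Euler
grid and scans all translations per orientation by FFT; an optional
6-neighbor Laplacian (with edge masking) adds contour information,
extending usable discrimination to ~30 Å resolution. `collage_refine`
optimizes many rigid fragments *simultaneously* with derivative-free Powell
search — the shared normalization penalizes steric clashes without an
explicit clash term.

**Feature points.** `vq` encodes a structure or map as N codebook vectors
(weighted k-means, best of restarts, with cross-restart variability);
`matchpt` registers N probe points into M ≥ N target points by
anchor-triangle seeding plus greedy extension, ranked by RMSD; N is chosen
from the volume per resolution element r_s³ (30–50% of the upper bound).

**Symmetry and volume algebra.** C/D/H (helical) symmetry-mate generation;
a symmetry-constrained refinement loop (regenerate mates → one joint
optimization pass → keep master) whose output is exactly symmetric by
construction; voxel-wise average/difference/product, affine density
matching, crop/pad, threshold, 6-connected segmentation, slices and
projections (with the identity `project(a−b) = project(a) − project(b)`).

## Worked example

Dock a monomer into a simulated hexamer map with known ground truth
(`python examples/05_exhaustive_fitting.py`):

```
target: (57, 51, 27) voxels at 3.0 A; probe: 150 pseudo-atoms
rank       CC    (psi,theta,phi)  err vs nearest protomer
   1   0.4040   (60.0, 0.0, 0.0)   0.59 A,   0.0 deg
   2   0.4035    (0.0, 0.0, 0.0)   0.00 A,   0.0 deg
   3   0.4031  (300.0, 0.0, 0.0)   0.59 A,   0.0 deg
```

The top poses are the planted, symmetry-related protomer positions: each is
within one voxel (3 Å) and well inside half the 30° angular step of a true
pose. Refining all six protomers jointly from perturbed starts
(`python examples/06_multi_fragment_refinement.py`) drives the correlation
monotonically from 0.9375 to 1.0000 and returns every fragment to within
0.003 Å / 0.03° of its planted pose. The other examples cover formats,
resolution conversion (`minisitus resconv 10 --from situs --to eman` →
12.82 Å), bead models, feature-point docking, the symmetry loop and volume
algebra.

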