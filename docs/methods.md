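# Methods

This note records the models, conventions and numerical choices behind
minisitus, and what the synthetic test conditions do and do not establish
about real data.

## Coordinate model

A `VolumeMap` is a cubic lattice: scalar voxel width *w* (Å), an origin
that is the physical position of voxel (0,0,0), and densities stored with
the x index fastest. Voxel (i,j,k) sits at `origin + w·(i,j,k)`. This is
the invariant that lets atomic models and maps share one docking frame;
both map writers (Situs ASCII and the MRC subset) and the PDB writer
round-trip it exactly, and the format tests assert the voxel-position
formula on file corners.

The MRC/CCP4 reader accepts a deliberately narrow modern subset: 32-bit
float mode, axis order x,y,z, 90° cells, voxel widths equal on all axes
within 0.1%. Everything else errors loudly rather than guessing among the
historical dialect variants. Endianness is auto-detected by header
plausibility (dims in [1, 10⁵], known mode code). Origin precedence: the
ORIGIN record when any component is nonzero, otherwise start indices ×
voxel width.

## Kernels and the resolution calculus

`pdb2vol` is a two-stage rasterizer: trilinear scatter of unit (or mass,
or occupancy) weights, then convolution with a sampled kernel. The
Gaussian kernel is `exp(−3r²/2σ²)` with the convention r_s = 2σ;
truncation at 3σ (amplitude ≈ 1.4·10⁻⁶) with the lattice padded by the
truncation radius so convolution never clips — total density is exactly
(total weight) × (kernel lattice sum), which the tests assert. Triangular
kernels are `max(0, 1 − r/R)`; hard spheres are indicator functions.

Conversions among resolution conventions reduce every convention to the
FWHM of its point-spread function and match Gaussians to the Airy disk
`[J₁(x)/x]²` of equal FWHM:

* r_p/r_c = x₁/2π from the first root x₁ of J₁ (Rayleigh criterion);
* FWHM/r_c from `[J₁(x)/x]² = 1/8` (half the central value 1/4);
* r_s/FWHM = √(3/2 ln 2) from the Situs kernel's half maximum;
* r_e/FWHM = π/2√(ln 2) from the EMAN kernel `exp(−π²r²/r_e²)`.

All factors are computed at runtime by `scipy` root-finding (tolerance
1e−14); nothing is transcribed. Compound reference factors quoted in the
literature (e.g. r_s = 1.239 r_p) were historically composed from
3-decimal intermediates; our exact chain gives 1.2411, and the tests check
both the exact values and the 3-decimal composition. Note the ordering
r_p < r_s < r_e < r_c holds for every positive input (property-tested).

## Correlation scoring

The CC is the cosine similarity of densities — no mean subtraction. This
is cheaper than Pearson, bounded in [0,1] for nonnegative maps, and
argmax-equivalent to Pearson for translation scans of a fixed probe
(tested). Normalization under partial overlap: probe norm over its own
support, target norm over the full volume; the FFT translational scan is
zero-padded (linear, not circular correlation) and equals the brute-force
overlap loop to better than 1e−8.

The Laplacian filter is the 6-neighbor stencil scaled by 1/w². Edge
masking zeroes output voxels adjacent to the lattice boundary or to
zero-density regions, suppressing the singular shells that thresholding or
segmentation would otherwise inject into contour scores.

`colores_search` enumerates z-y-z Euler angles with ψ, φ uniform at the
angular step and cos θ uniform (equal-area); poles keep a single φ. The
probe is rasterized per orientation into a fixed cube phase-locked to the
target lattice, so integer-voxel offsets translate exactly into physical
shifts. Near-duplicate peaks are pruned by a minimum translation
separation (default two voxels) — a minimal stand-in for peak clustering,
chosen for determinism. Ties are broken lexicographically on (translation,
Euler triple).

Plain density CC discriminates poses reliably only when interior density
variation survives the resolution lowering; at the 15 Å study conditions
it is marginal (it recovers most planted poses but can prefer a flipped
pose), and the Laplacian mode is the appropriate default — the exhaustive
search tests and examples therefore use contour scoring, and a dedicated
test shows a 25 Å fixture where plain CC misranks and the Laplacian does
not.

## Multi-fragment refinement

`collage_refine` maximizes the CC of the target against the rasterized
*sum* of all fragments over the 6K pose parameters jointly, using
derivative-free Powell search (no analytic gradient exists through the
trilinear rasterization; Powell's quadratic line searches handle the
smooth Gaussian-convolved landscape well). Parameters are translations in
Å and small-angle rotations in degrees composed about each fragment's
centroid — comparable scales, no gimbal issues near poles. Convergence:
relative score change below 1e−7 or parameter steps below 0.01; one
"step" of the public interface is one Powell pass, the granularity the
symmetry loop requires. The score trace is monotone because Powell never
accepts a worse point; this is asserted, not enforced.

Because the joint norm ‖Σ fragments‖ grows when fragments overlap without
adding matched signal, overlapping configurations score lower — the
normalization is itself the steric-clash penalty (for two identical
overlapping fragments the score drops to ≈ 1/√2 of the separated
optimum, which a test confirms).

## Feature points and matching

`vq` is best-of-restarts weighted k-means (k-means++ seeding, density
weights for maps). The reported per-point variability is the mean
distance, over restarts, to the Hungarian-matched counterpart of the
winning codebook — an empirical reproducibility estimate used to select
the level of detail. The classic estimate for N divides the structure
volume by r_s³ and takes 30–50% of that bound; M = units × N scales with
the number of structure copies filling the target.

`matchpt` seeds rigid candidates from probe/target anchor triangles
(side lengths compatible within 1.5× the target's mean nearest-neighbor
spacing; pruning is skipped below 20 000 seeds, which makes small
instances effectively exhaustive), extends each seed to a full injective
assignment — by enumeration when ≤ 3 probe points remain and few targets
are free, greedily by nearest unused target otherwise — then refits by
SVD superposition (reflection-guarded) and re-extends only while the RMSD
improves. On random N=4, M=6 instances it returns the same optimum as
exhaustive enumeration over all injections (100/100 seeds in the
acceptance run).

## Symmetry

`pdbsymm` generates C_n (n rotations), D_n (2n: C_n plus 2-fold flips
about a perpendicular axis at a configurable phase, default along x) and
helical copies (k·twist rotation + k·rise translation). The default axis
is z through the target map's geometric center.

The symmetry-constrained loop alternates mate regeneration with a single
joint refinement pass and keeps only the refined master; convergence when
the master moves < 0.05 Å and < 0.1° between loops. The mates returned
are regenerated from the final master, so the result is *exactly*
symmetric — symmetry is enforced by construction, not approximated by the
optimizer.

## Volume algebra

Voxel-wise operations require identical lattices and error on mismatch;
`resample_to` is the explicit trilinear registration step. Projections
multiply the along-axis sum by the voxel width (Riemann sum of the line
integral); the projection-difference identity is invariant to that choice
and holds to 1e−10 on random maps. Affine density matching solves the
least-squares normal equations for α·source + β and rejects non-positive
α. Segmentation uses 6-connectivity, matching the Laplacian stencil;
components are labeled by descending total density. The recommended
rendering isolevel encloses 120–150% of the molecular volume (resolved by
sorting voxel values to the nearest achievable volume), compensating the
erosion of convex features at low resolution.

## Synthetic study conditions

The fixture generator emulates a RecA-like hexameric ring: a monomer of
150 pseudo-atoms with radius of gyration 12 Å, built from 6 Gaussian
sub-domain lobes (σ ≈ 3.5 Å) inside an anisotropic ellipsoid (axis scales
1 : 0.75 : 0.55, principal moments distinct by > 10% so planted poses
cannot alias), placed at a 35 Å ring radius — protomers in contact, as in
a real oligomer — and rasterized at 15 Å resolution on a 3 Å lattice
(two voxels per σ). The same generator produces C2/C3 variants for the
refinement and symmetry tests. All fixtures are deterministic functions
of a seed.

What these conditions do show: exact-arithmetic contracts (formats,
algebra, conversion factors), and planted-truth recovery — exhaustive
search to within a voxel and half the angular step, joint refinement from
≤ 5 Å / 10° perturbations to ≤ 1 Å / 2°, symmetry-loop recovery from 3 Å
displacement to < 0.5 Å. What they do not show: robustness to
experimental noise, CTF effects, missing-wedge artifacts, map scaling
errors, or flexibility between conformations — the maps here are noise-free
and generated by the same forward model used in fitting. Real-data
performance therefore depends on conditions these tests deliberately hold
fixed.

Problem sizes were chosen so the full suite and the acceptance script
each run in minutes on one CPU: maps of ~50³–60³ voxels, 150-atom
monomers, 100-seed oracle comparisons at N=4, M=6.

## Known limitations

* SPIDER/X-PLOR formats, axis permutation and non-orthogonal cells are
  out of scope; the MRC subset is modern and strict by design.
* No electron scattering factors or B-factor-dependent blurring; all
  atoms are point scatterers (optionally mass- or occupancy-weighted).
* The colores peak pruning is a minimal distance criterion, not the full
  peak-clustering of mature search tools.
* `matchpt`'s completeness guarantee is empirical at small N, M; for
  large clouds the triangle tolerance and seed cap trade recall for time.
* The HCP bead count for a given structure depends on the lattice phase
  (anchored at the atom centroid here); counts for published examples are
  reproducible only up to that convention.
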