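"""Vector-quantization feature points and unequal-size point matching.

At resolutions where interior density variation is absent, a molecule's
shape can still be encoded reproducibly by a small set of feature points
(codebook vectors) minimizing the quantization distortion.  ``matchpt``
registers a smaller feature set (N points) onto a larger one (M >= N
points, e.g. from an oligomeric map) by seeding rigid transforms from
distance-compatible anchor triangles and extending greedily, ranking
solutions by RMSD after least-squares superposition.

The level of detail follows the resolution of the data: the number of
features N in a structure is bounded above by volume / r_s^3 (one feature
per resolution element) and in practice bracketed at 30-50% of that bound;
M scales with the number of structure copies the target volume holds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from minisitus.scoring import cc_arrays, rasterize_on_lattice
from minisitus.transforms import RigidTransform, kabsch, rmsd
from minisitus.voldata import AtomicModel, VolumeMap

__all__ = [
    "PointCloud",
    "MatchResult",
    "vq",
    "estimate_n",
    "units_to_m",
    "matchpt",
    "matchpt_exhaustive",
    "match_quality",
]


@dataclass
class PointCloud:
    """Coarse-grained feature points with optional weights and variability.

    ``variability`` is the per-point positional spread (A) across repeated
    quantization runs — an empirical estimator of how reliably the point
    encodes a feature of the shape.
    """

    points: np.ndarray
    weights: np.ndarray = None
    variability: np.ndarray = None
    distortion: float = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 1:
            raise ValueError("need at least one point")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.sum() <= 0:
                raise ValueError("weights must have positive sum")
        if self.variability is not None:
            self.variability = np.asarray(self.variability, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MatchResult:
    """An injective assignment of probe points to target points."""

    correspondence: np.ndarray  # target index for each probe point
    transform: RigidTransform
    rmsd: float
    cc_at_pose: float = None

    def __post_init__(self):
        self.correspondence = np.asarray(self.correspondence, dtype=int)
        if len(set(self.correspondence.tolist())) != len(self.correspondence):
            raise ValueError("correspondence must be injective")


# ---------------------------------------------------------------------------
# Vector quantization
# ---------------------------------------------------------------------------

def _as_weighted_points(source):
    if isinstance(source, AtomicModel):
        return source.coords, np.ones(len(source))
    if isinstance(source, VolumeMap):
        flat = source.data.ravel(order="F")
        keep = flat > 0
        if not keep.any():
            raise ValueError("map has no positive density to quantize")
        return source.voxel_positions()[keep], flat[keep]
    if isinstance(source, PointCloud):
        w = source.weights if source.weights is not None else np.ones(len(source))
        return source.points, w
    raise TypeError(f"cannot quantize {type(source).__name__}")


def vq(source, n: int, seed: int = 0, restarts: int = 8) -> PointCloud:
    """Quantize a structure or map into ``n`` feature points.

    Best-of-``restarts`` weighted k-means (density values weight map
    voxels).  The returned cloud carries the winning codebook, per-point
    total weights, the distortion (weighted squared quantization error)
    and the per-point variability: the mean distance, over all restarts,
    between each winning point and its Hungarian-matched counterpart in
    the other runs.
    """
    points, weights = _as_weighted_points(source)
    if not 1 <= n <= len(points):
        raise ValueError(f"n={n} must be in [1, {len(points)}]")
    if np.allclose(points, points[0], atol=1e-12):
        raise ValueError("degenerate input: all points identical")
    if n == 1:
        centroid = (weights[:, None] * points).sum(axis=0) / weights.sum()
        distortion = float(
            (weights * np.sum((points - centroid) ** 2, axis=1)).sum())
        return PointCloud(centroid[None, :], np.array([weights.sum()]),
                          np.zeros(1), distortion)

    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(max(1, restarts)):
        km = KMeans(n_clusters=n, n_init=1, init="k-means++",
                    random_state=int(rng.integers(2 ** 31 - 1)))
        km.fit(points, sample_weight=weights)
        runs.append((float(km.inertia_), km.cluster_centers_, km.labels_))
    runs.sort(key=lambda r: r[0])
    best_inertia, best_centers, best_labels = runs[0]

    variability = np.zeros(n)
    if len(runs) > 1:
        for _, centers, _ in runs[1:]:
            d = np.linalg.norm(best_centers[:, None, :] - centers[None, :, :], axis=2)
            rows, cols = linear_sum_assignment(d)
            variability[rows] += d[rows, cols]
        variability /= (len(runs) - 1)

    cluster_w = np.array([weights[best_labels == i].sum() for i in range(n)])
    return PointCloud(best_centers, cluster_w, variability, best_inertia)


def estimate_n(structure_volume: float, r_s: float, level: float = 0.4) -> int:
    """Number of feature points for a structure at map resolution ``r_s``.

    volume / r_s^3 bounds the number of resolution elements; ``level``
    (conventionally 0.3-0.5) brackets N below that bound to avoid
    overfitting.  Never less than 1.
    """
    if structure_volume <= 0 or r_s <= 0:
        raise ValueError("volume and resolution must be positive")
    return max(1, int(round(level * structure_volume / r_s ** 3)))


def units_to_m(n: int, units: float) -> int:
    """Target feature count M = units * N, where ``units`` estimates how
    many copies of the structure fill the occupied target volume."""
    if units < 1:
        raise ValueError("units must be >= 1 (target at least as large as probe)")
    return int(round(units * n))


# ---------------------------------------------------------------------------
# Point matching
# ---------------------------------------------------------------------------

def _fit_and_score(probe_pts, target_pts, assignment):
    tpts = target_pts[assignment]
    rt = kabsch(probe_pts, tpts)
    return rt, rmsd(rt.apply(probe_pts), tpts)


def matchpt_exhaustive(probe: PointCloud, target: PointCloud,
                       max_results: int = 10):
    """Rank every injective assignment of probe points to target points.

    Exact but factorial in size — intended for small instances (N, M <= 7)
    and as the reference for the heuristic search.
    """
    N, M = len(probe), len(target)
    _check_sizes(N, M)
    results = []
    for combo in itertools.combinations(range(M), N):
        for perm in itertools.permutations(combo):
            rt, r = _fit_and_score(probe.points, target.points, np.array(perm))
            results.append(MatchResult(np.array(perm), rt, r))
    results.sort(key=lambda m: (m.rmsd, tuple(m.correspondence)))
    return _dedupe(results)[:max_results]


def matchpt(probe: PointCloud, target: PointCloud, max_results: int = 10,
            triangle_tolerance: float = None, max_seeds: int = 20000):
    """Heuristic unequal-size point matching (N probe points into M >= N).

    Rigid candidates are seeded from anchor triangles: each probe triple
    is paired with every ordered target triple whose side lengths agree
    within ``triangle_tolerance`` (default 1.5x the target's mean
    nearest-neighbor spacing; pruning is skipped entirely while the seed
    count stays under ``max_seeds``, which makes small instances
    effectively exhaustive).  Each seed transform is extended to a full
    injective assignment — greedily by nearest unused target point, or by
    enumeration when three or fewer probe points remain — then re-fitted
    by least-squares superposition and re-extended once.  Results are
    ranked by RMSD over all N corresponded pairs.
    """
    N, M = len(probe), len(target)
    _check_sizes(N, M)
    P, T = probe.points, target.points

    if triangle_tolerance is None:
        tree = cKDTree(T)
        nn_dist, _ = tree.query(T, k=2)
        triangle_tolerance = 1.5 * float(nn_dist[:, 1].mean())

    probe_triples = list(itertools.combinations(range(N), 3))
    target_triples = list(itertools.permutations(range(M), 3))
    n_seeds = len(probe_triples) * len(target_triples)
    prune = n_seeds > max_seeds

    def sides(pts, trip):
        a, b, c = trip
        return np.array([np.linalg.norm(pts[a] - pts[b]),
                         np.linalg.norm(pts[a] - pts[c]),
                         np.linalg.norm(pts[b] - pts[c])])

    results = []
    seen = set()
    for pt in probe_triples:
        ps = sides(P, pt)
        for tt in target_triples:
            if prune and np.any(np.abs(ps - sides(T, tt)) > triangle_tolerance):
                continue
            rt = kabsch(P[list(pt)], T[list(tt)])
            assignment = _extend(P, T, rt, pt, tt)
            if assignment is None:
                continue
            rt, r = _fit_and_score(P, T, assignment)
            for _ in range(2):  # re-extend after refit, keep only improvements
                assignment2 = _extend(P, T, rt, (), ())
                if assignment2 is None or np.array_equal(assignment2, assignment):
                    break
                rt2, r2 = _fit_and_score(P, T, assignment2)
                if r2 >= r - 1e-12:
                    break
                assignment, rt, r = assignment2, rt2, r2
            key = tuple(assignment)
            if key not in seen:
                seen.add(key)
                results.append(MatchResult(assignment, rt, r))
    if not results:
        raise ValueError("no anchor triangle within the distance tolerance; "
                         "increase triangle_tolerance")
    results.sort(key=lambda m: (m.rmsd, tuple(m.correspondence)))
    return results[:max_results]


def _extend(P, T, rt, probe_triple, target_triple):
    """Complete a partial correspondence into a full injective assignment."""
    N, M = len(P), len(T)
    assignment = np.full(N, -1)
    for p, t in zip(probe_triple, target_triple):
        assignment[p] = t
    remaining = [i for i in range(N) if assignment[i] < 0]
    used = set(int(t) for t in assignment if t >= 0)
    free = [j for j in range(M) if j not in used]
    moved = rt.apply(P)
    if len(remaining) <= 3 and len(free) <= 8:
        # enumerate all injective completions; pick minimum squared error
        best, best_err = None, np.inf
        for perm in itertools.permutations(free, len(remaining)):
            err = sum(float(np.sum((moved[i] - T[j]) ** 2))
                      for i, j in zip(remaining, perm))
            if err < best_err:
                best_err, best = err, perm
        for i, j in zip(remaining, best):
            assignment[i] = j
        return assignment
    # greedy nearest unused target, most-confident (closest) pair first
    free = set(free)
    pairs = sorted(
        ((float(np.linalg.norm(moved[i] - T[j])), i, j)
         for i in remaining for j in free))
    done = set()
    for d, i, j in pairs:
        if i in done or j not in free:
            continue
        assignment[i] = j
        free.discard(j)
        done.add(i)
    if np.any(assignment < 0):
        return None
    return assignment


def _dedupe(results):
    seen, out = set(), []
    for m in results:
        key = tuple(m.correspondence)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def _check_sizes(N, M):
    if N < 3:
        raise ValueError("need at least 3 probe points for a unique rigid fit")
    if N > M:
        raise ValueError(f"probe ({N}) may not exceed target ({M})")


# ---------------------------------------------------------------------------
# Match quality report
# ---------------------------------------------------------------------------

@dataclass
class MatchQualityReport:
    rmsd: float
    variability_sum: float = None
    cc_at_pose: float = None
    unavailable: list = field(default_factory=list)


def match_quality(result: MatchResult, probe: PointCloud = None,
                  target: PointCloud = None, target_map: VolumeMap = None,
                  probe_model: AtomicModel = None,
                  kernel=None) -> MatchQualityReport:
    """Report RMSD, summed average variability and CC at the matched pose.

    The variability sum (average probe variability + average target
    variability) estimates docking accuracy and can select an optimal
    level of detail; the CC is sampled discretely at the matched pose by
    rasterizing the posed model on the target lattice.  Missing inputs are
    flagged rather than fatal.
    """
    report = MatchQualityReport(rmsd=result.rmsd)
    if (probe is not None and probe.variability is not None
            and target is not None and target.variability is not None):
        report.variability_sum = float(probe.variability.mean()
                                       + target.variability.mean())
    else:
        report.unavailable.append("variability_sum")
    if target_map is not None and probe_model is not None and kernel is not None:
        posed = result.transform.apply(probe_model.coords)
        calc = rasterize_on_lattice(posed, target_map.width, target_map.origin,
                                    target_map.dims, kernel.rasterize(target_map.width))
        report.cc_at_pose = cc_arrays(target_map.data, calc)
    else:
        report.unavailable.append("cc_at_pose")
    return report
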