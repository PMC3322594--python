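"""Rigid-body transforms: rotation + translation in Angstroms.

Rotations follow the intrinsic z-y-z Euler convention throughout the
package (psi, theta, phi in degrees).  A transform acts on coordinates as
``x -> R x + t``; helpers are provided to rotate about an arbitrary pivot,
which the fitting modules use to rotate fragments about their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t.reshape(3))

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler_zyz(cls, psi: float, theta: float, phi: float,
                       translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from intrinsic z-y-z Euler angles in degrees."""
        R = Rotation.from_euler("ZYZ", [psi, theta, phi], degrees=True).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def rotation_about_axis(cls, axis, angle_deg: float, point=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a line through ``point`` along ``axis``."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n).as_matrix()
        p = np.asarray(point, dtype=float)
        return cls(R, p - R @ p)

    @classmethod
    def about_pivot(cls, rotation: np.ndarray, pivot, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Transform ``x -> R (x - pivot) + pivot + translation``."""
        p = np.asarray(pivot, dtype=float)
        R = np.asarray(rotation, dtype=float)
        return cls(R, p - R @ p + np.asarray(translation, dtype=float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self after other`` (apply other first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def euler_zyz(self) -> np.ndarray:
        """Intrinsic z-y-z Euler angles (degrees)."""
        return Rotation.from_matrix(self.rotation).as_euler("ZYZ", degrees=True)

    def rotation_angle_deg(self, other: "RigidTransform" = None) -> float:
        """Geodesic rotation distance to ``other`` (identity by default), degrees."""
        R = self.rotation if other is None else self.rotation @ other.rotation.T
        return float(np.rad2deg(np.abs(Rotation.from_matrix(R).magnitude())))


def kabsch(mobile: np.ndarray, target: np.ndarray, weights=None) -> RigidTransform:
    """Least-squares superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns the rigid transform minimizing the (weighted) RMSD between
    corresponding rows.  Reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("need two equal point sets with at least 3 points")
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    cm = w @ mobile
    ct = w @ target
    R, _ = Rotation.align_vectors(target - ct, mobile - cm, weights=w)
    Rm = R.as_matrix()
    return RigidTransform(Rm, ct - Rm @ cm)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
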