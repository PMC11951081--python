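"""Rigid-body geometric primitives: superposition, RMSD, rotations, reflections.

Superposition uses the SVD-based least-squares rigid fit (Kabsch) with the
determinant correction that forces a proper rotation: a reflection is never
returned, because silently inverting chirality would defeat the purpose of
a stereoselectivity screen.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .chem import Conformer
from .errors import GeometryError, UsageError


class SuperposeResult(NamedTuple):
    rotation: np.ndarray     # 3x3 proper rotation, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float              # Å, after the fit

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def superpose(P: np.ndarray, Q: np.ndarray,
              weights: Optional[np.ndarray] = None) -> SuperposeResult:
    """Least-squares rigid superposition of point set P onto Q.

    Returns (R, t, rmsd) with R a proper rotation such that P @ R.T + t
    best fits Q in the (weighted) least-squares sense.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape != Q.shape or P.shape[1] != 3 or P.shape[0] < 1:
        raise UsageError(
            f"point sets must be equal-size Nx3 arrays, got {P.shape} and {Q.shape}")
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(P),):
            raise UsageError("weights must be one scalar per point")
        if np.any(w < 0) or w.sum() <= 0:
            raise UsageError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cp = (w[:, None] * P).sum(axis=0) / wsum
    cq = (w[:, None] * Q).sum(axis=0) / wsum
    Pc = P - cp
    Qc = Q - cq
    H = (w[:, None] * Pc).T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P @ R.T + t - Q
    rmsd = math.sqrt(float((w * (diff ** 2).sum(axis=1)).sum() / wsum))
    return SuperposeResult(R, t, rmsd)


def rmsd_heavy(a: Conformer, b: Conformer, align: bool = True) -> float:
    """Heavy-atom RMSD between two conformers of the same molecule (Å).

    Uses the identity atom correspondence (no symmetry/automorphism
    matching). With align=True the RMSD is minimized over rigid motions.
    """
    if len(a.molecule) != len(b.molecule):
        raise UsageError("conformers must have the same atom count")
    if a.molecule.elements != b.molecule.elements:
        raise UsageError("conformers must share the same molecule (element order)")
    idx = a.molecule.heavy_indices
    if len(idx) == 0:
        idx = np.arange(len(a.molecule))
    pa = a.coordinates[idx]
    pb = b.coordinates[idx]
    if align:
        return superpose(pa, pb).rmsd
    return math.sqrt(float(((pa - pb) ** 2).sum(axis=1).mean()))


def rotation_about_axis(point: np.ndarray, direction: np.ndarray,
                        angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation by angle_deg about the axis through `point` along `direction`.

    Returns (R, t) acting as x -> R @ x + t.
    """
    point = np.asarray(point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise GeometryError("rotation axis direction has zero length")
    u = direction / norm
    R = Rotation.from_rotvec(np.radians(angle_deg) * u).as_matrix()
    t = point - R @ point
    return R, t


def reflect_across_plane(points: np.ndarray, plane_point: np.ndarray,
                         normal: np.ndarray) -> np.ndarray:
    """Mirror points across the plane through plane_point with the given normal."""
    points = np.asarray(points, dtype=float)
    plane_point = np.asarray(plane_point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise GeometryError("plane normal has zero length")
    n = normal / nn
    d = (points - plane_point) @ n
    return points - 2.0 * d[:, None] * n


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    from .chem import _dihedral
    return math.degrees(_dihedral(np.asarray(p0, float), np.asarray(p1, float),
                                  np.asarray(p2, float), np.asarray(p3, float)))
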