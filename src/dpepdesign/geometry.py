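"""Rigid-body geometry primitives: internal-coordinate atom placement and
least-squares superposition restricted to proper rotations.

The superposition solver is the Kabsch algorithm with the usual determinant
correction so that reflections are never returned: searching a mirror-image
fragment library is only meaningful if the fit itself cannot undo the mirror.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["Superposition", "superpose", "apply_transform", "nerf", "rmsd_between"]


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid fit of a moving point set onto a fixed one.

    ``rotation`` is a proper rotation (det = +1); the fitted coordinates are
    ``rotation @ x + translation`` for each moving point ``x``.
    """

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return apply_transform(coords, self.rotation, self.translation)


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``R x + t`` to an (n, 3) coordinate array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def _check_well_posed(pts: np.ndarray, label: str) -> None:
    centered = pts - pts.mean(axis=0)
    # rank < 2 (all points on a line) leaves a free rotation about that line
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-8:
        raise DegenerateGeometryError(f"{label} point set is collinear; superposition is ill-posed")


def superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares superposition of ``moving`` onto ``fixed`` over proper
    rotations and translations (Kabsch/SVD).

    Correspondence is positional: row i of ``moving`` is fitted to row i of
    ``fixed``. Requires n >= 3 non-collinear points on both sides.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateGeometryError(
            f"point sets must be matching (n, 3) arrays, got {P.shape} and {Q.shape}"
        )
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points for superposition, got {n}")
    _check_well_posed(P, "moving")
    _check_well_posed(Q, "fixed")

    cm, cf = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cm).T @ (Q - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((Q - fitted) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (un-fitted) RMSD between corresponding points."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from three reference atoms and internal coordinates.

    Natural extension reference frame: ``|c-d| = bond``, angle b-c-d =
    ``angle_deg``, torsion a-b-c-d = ``torsion_deg``.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.deg2rad(angle_deg)
    tau = np.deg2rad(torsion_deg)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)

    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(tau),
            bond * np.sin(theta) * np.sin(tau),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
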