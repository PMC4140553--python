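"""Vector geometry primitives: torsions, internal-coordinate placement,
rigid superposition and screw-transform fitting.

All coordinates are in Å, angles in degrees unless noted.  The torsion
a–b–c–d is signed right-handedly about the b→c axis (the convention of the
common trajectory-analysis packages) and is symmetric under sequence
reversal: torsion(d, c, b, a) = torsion(a, b, c, d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "kabsch",
    "RigidTransform",
    "ScrewFit",
    "fit_screw",
    "screw_transform",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle a–b–c–d in degrees, in (−180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 (degrees)."""
    u = _unit(np.asarray(p0, float) - np.asarray(p1, float))
    v = _unit(np.asarray(p2, float) - np.asarray(p1, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that |d−c| = bond, ∠(d,c,b) = angle and the torsion
    a–b–c–d equals ``torsion`` (NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    th = np.radians(angle)
    chi = np.radians(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(chi),
            bond * np.sin(th) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Returns the transform and the post-fit RMSD.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    sc = src.mean(axis=0)
    tc = tgt.mean(axis=0)
    h = (src - sc).T @ (tgt - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - r @ sc
    tr = RigidTransform(rotation=r, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(src) - tgt) ** 2, axis=1))))
    return tr, rmsd


@dataclass(frozen=True)
class ScrewFit:
    """A rigid transform decomposed as a screw motion.

    ``angle`` is signed (degrees) about the unit ``axis`` chosen so the
    translation component along the axis (``rise``) is non-negative; a
    positive angle therefore means a right-handed screw.  ``point`` is a
    point on the screw axis.  ``rmsd`` is the fit residual.
    """

    axis: np.ndarray
    angle: float
    rise: float
    point: np.ndarray
    rmsd: float
    transform: RigidTransform


def _rotation_axis_angle(r: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit axis and signed angle (radians, in (−pi, pi]) of a rotation matrix."""
    w = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]]) / 2.0
    cos_t = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    sin_t = np.linalg.norm(w)
    if sin_t > 1e-9:
        axis = w / sin_t
        return axis, float(np.arctan2(sin_t, cos_t))
    if cos_t > 0:  # identity
        return np.array([0.0, 0.0, 1.0]), 0.0
    # 180° rotation: axis from eigenvector of R with eigenvalue +1
    vals, vecs = np.linalg.eigh((r + r.T) / 2.0)
    axis = vecs[:, np.argmax(vals)]
    return axis / np.linalg.norm(axis), float(np.pi)


def fit_screw(source: np.ndarray, target: np.ndarray) -> ScrewFit:
    """Best-fit screw motion mapping paired coordinates source -> target."""
    tr, rmsd = kabsch(source, target)
    axis, theta = _rotation_axis_angle(tr.rotation)
    rise = float(np.dot(tr.translation, axis))
    if rise < 0:
        axis, theta, rise = -axis, -theta, -rise
    # point on axis: solve (I − R) p = t_perp in the plane normal to axis
    t_perp = tr.translation - rise * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - tr.rotation, t_perp, rcond=None)
    # remove any component along the axis (underdetermined direction)
    p = p - np.dot(p, axis) * axis
    return ScrewFit(
        axis=axis,
        angle=float(np.degrees(theta)),
        rise=rise,
        point=p,
        rmsd=rmsd,
        transform=tr,
    )


def screw_transform(axis: np.ndarray, angle: float, rise: float, point: np.ndarray) -> RigidTransform:
    """Build the rigid transform of an explicit screw motion."""
    axis = _unit(np.asarray(axis, float))
    th = np.radians(angle)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    r = np.eye(3) + np.sin(th) * k + (1.0 - np.cos(th)) * (k @ k)
    point = np.asarray(point, float)
    t = point - r @ point + rise * axis
    return RigidTransform(rotation=r, translation=t)
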