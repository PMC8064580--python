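"""Geometric primitives shared by the simulation engine and the analysis layer.

All lengths are in ångström and all angles in degrees unless stated
otherwise.  Boxes are orthorhombic with per-axis periodic flags; the
membrane normal is conventionally the z axis, with the extracellular
half-space at z > 0.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "GeometryError",
    "NonFiniteCoordinateError",
    "DegenerateGeometryError",
    "PeriodicBox",
    "RigidTransform",
    "minimum_image_displacement",
    "minimum_image_distance",
    "dihedral_angle",
    "place_fourth_atom",
    "kabsch_rmsd",
]


class GeometryError(ValueError):
    """Base class for geometric precondition failures."""


class NonFiniteCoordinateError(GeometryError):
    """A coordinate was NaN or infinite."""


class DegenerateGeometryError(GeometryError):
    """Input points are collinear/coincident where a well-defined frame is required."""


def _as_vec(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape[-1] != 3:
        raise GeometryError(f"{name} must have 3 components, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise NonFiniteCoordinateError(f"{name} contains non-finite coordinates")
    return a


@dataclasses.dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic simulation cell.

    Parameters
    ----------
    lengths : tuple of 3 floats
        Edge lengths (Lx, Ly, Lz) in Å, all positive.
    periodic : tuple of 3 bools
        Whether each axis is treated with minimum-image wrapping.  The
        default matches a membrane system: periodic in x and y, bounded
        in z.
    """

    lengths: tuple[float, float, float] = (120.0, 120.0, 100.0)
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self) -> None:
        ls = tuple(float(v) for v in self.lengths)
        if len(ls) != 3 or any(not math.isfinite(v) or v <= 0 for v in ls):
            raise GeometryError(f"box lengths must be three positive finite values, got {self.lengths}")
        object.__setattr__(self, "lengths", ls)
        object.__setattr__(self, "periodic", tuple(bool(v) for v in self.periodic))

    @property
    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def periodic_array(self) -> np.ndarray:
        return np.asarray(self.periodic, dtype=bool)

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        lx, ly, lz = self.lengths
        return lx * ly * lz

    def minimum_image(self, dvec: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to a displacement (... , 3)."""
        d = np.array(dvec, dtype=float, copy=True)
        L = self.lengths_array
        for ax in range(3):
            if self.periodic[ax]:
                d[..., ax] -= L[ax] * np.round(d[..., ax] / L[ax])
        return d

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap positions into the origin-centred cell [-L/2, L/2) on periodic axes."""
        p = np.array(pos, dtype=float, copy=True)
        L = self.lengths_array
        for ax in range(3):
            if self.periodic[ax]:
                p[..., ax] = (p[..., ax] + L[ax] / 2.0) % L[ax] - L[ax] / 2.0
        return p


def minimum_image_displacement(p, q, box: PeriodicBox | None = None) -> np.ndarray:
    """Displacement q - p under the minimum-image convention (supports broadcasting)."""
    pv = _as_vec(p, "p")
    qv = _as_vec(q, "q")
    d = qv - pv
    if box is not None:
        d = box.minimum_image(d)
    return d


def minimum_image_distance(p, q, box: PeriodicBox | None = None):
    """Minimum-image distance |q - p| in Å.

    On non-periodic axes this is the plain Euclidean component; with no
    box it reduces to the Euclidean distance.  Symmetric in p and q and
    never larger than the unwrapped distance.
    """
    d = minimum_image_displacement(p, q, box)
    return np.linalg.norm(d, axis=-1)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Sign follows the IUPAC convention (positive for a clockwise rotation
    of the p1 side relative to the p4 side when viewed from p2 toward
    p3), the convention used by common trajectory-analysis tools.

    Raises
    ------
    DegenerateGeometryError
        If consecutive bond vectors are collinear or zero, so the
        torsion plane is undefined.
    """
    a1, a2, a3, a4 = (_as_vec(p, f"p{i}") for i, p in enumerate((p1, p2, p3, p4), 1))
    b1 = a2 - a1
    b2 = a3 - a2
    b3 = a4 - a3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    scale = max(np.linalg.norm(b1), b2n, np.linalg.norm(b3), 1e-30)
    if b2n < 1e-12 * scale or np.linalg.norm(n1) < 1e-9 * scale**2 or np.linalg.norm(n2) < 1e-9 * scale**2:
        raise DegenerateGeometryError("collinear or coincident points: torsion undefined")
    m1 = np.cross(n1, b2 / b2n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (non-zero) axis."""
    u = np.asarray(axis, dtype=float)
    n = np.linalg.norm(u)
    if n < 1e-12:
        raise DegenerateGeometryError("zero rotation axis")
    u = u / n
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def place_fourth_atom(p1, p2, p3, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place p4 so that |p4-p3| = bond, angle(p2,p3,p4) = angle_deg and
    dihedral_angle(p1,p2,p3,p4) = torsion_deg (same sign convention).

    Used to build ligand bead templates with a prescribed side-chain
    torsion, and as an independent construction oracle for the torsion
    computation.
    """
    a1, a2, a3 = _as_vec(p1, "p1"), _as_vec(p2, "p2"), _as_vec(p3, "p3")
    b2 = a3 - a2
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12:
        raise DegenerateGeometryError("p2 and p3 coincide")
    u = b2 / b2n
    w = (a1 - a2) - np.dot(a1 - a2, u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-12:
        raise DegenerateGeometryError("p1, p2, p3 are collinear")
    w = w / wn
    theta = math.radians(angle_deg)
    # direction giving torsion 0 (cis: p4 on the p1 side of the p2-p3 axis)
    d0 = -math.cos(theta) * u + math.sin(theta) * w
    # right-handed rotation about u by +delta decreases the torsion by delta
    d = _rotation_about_axis(u, -torsion_deg) @ d0
    return a3 + bond * d


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise GeometryError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords) -> np.ndarray:
        c = _as_vec(coords, "coords")
        return c @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def kabsch_rmsd(ref, mov, fit: bool = True) -> tuple[float, RigidTransform]:
    """RMSD between two equally sized coordinate sets, optionally after
    optimal rigid superposition (Kabsch algorithm).

    Returns the RMSD in Å and the transform that maps ``mov`` onto
    ``ref`` (the identity when ``fit`` is off).  With ``fit`` the RMSD is
    minimised over all proper rotations and translations, and is never
    larger than the unfitted value.
    """
    r = _as_vec(ref, "ref")
    m = _as_vec(mov, "mov")
    if r.ndim != 2 or m.ndim != 2:
        raise GeometryError("coordinate sets must be (n, 3) arrays")
    if r.shape != m.shape:
        raise GeometryError(f"size mismatch: ref has {r.shape[0]} points, mov has {m.shape[0]}")
    if not fit:
        rmsd = float(np.sqrt(np.mean(np.sum((m - r) ** 2, axis=1))))
        return rmsd, RigidTransform.identity()
    n = r.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    cr = r.mean(axis=0)
    cm = m.mean(axis=0)
    rc = r - cr
    mc = m - cm
    # collinear point sets leave a rotation axis undetermined
    if np.linalg.matrix_rank(rc, tol=1e-8 * max(1.0, np.abs(rc).max())) < 2:
        raise DegenerateGeometryError("reference points are collinear: fit ill-defined")
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    moved = m @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - r) ** 2, axis=1))))
    return rmsd, RigidTransform(R, t)
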