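"""Small rigid-body geometry helpers shared across modules.

Everything works on plain numpy arrays: points are (n, 3) float64 in
Angstroms, rotations are proper 3x3 matrices.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RigidTransform",
    "rotation_about_z",
    "kabsch",
    "rotation_angle_axis",
    "random_rotation_matrix",
    "axis_angle_matrix",
]


class RigidTransform:
    """A proper rigid-body transform ``x -> R @ x + t``."""

    __slots__ = ("rot", "trans")

    def __init__(self, rot: np.ndarray, trans: np.ndarray):
        rot = np.asarray(rot, dtype=float)
        trans = np.asarray(trans, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValueError("rot must be (3,3) and trans (3,)")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1)")
        self.rot = rot
        self.trans = trans

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rot.T + self.trans

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rot @ other.rot,
                              self.rot @ other.trans + self.trans)

    def inverse(self) -> "RigidTransform":
        rinv = self.rot.T
        return RigidTransform(rinv, -rinv @ self.trans)

    def almost_equals(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (np.allclose(self.rot, other.rot, atol=tol)
                and np.allclose(self.trans, other.trans, atol=tol))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RigidTransform(rot={self.rot!r}, trans={self.trans!r})"


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("axis must be non-zero")
    u = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    ux, uy, uz = u
    cross = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(u, u)


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst``.

    Returns T with ``T.apply(src) ~ dst`` (proper rotation enforced).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n,3) arrays")
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cd - rot @ cs)


def rotation_angle_axis(rot: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, in [0, 180]) and unit axis of a rotation matrix.

    For the identity the axis is arbitrary (+z returned).
    """
    rot = np.asarray(rot, dtype=float)
    cos_a = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_a))
    if angle < 1e-10:
        return 0.0, np.array([0.0, 0.0, 1.0])
    if angle > 180.0 - 1e-8:
        # axis from the symmetric part: R + I = 2 uu^T for angle pi
        m = rot + np.eye(3)
        col = m[:, np.argmax(np.diag(m))]
        axis = col / np.linalg.norm(col)
        return 180.0, axis
    vec = np.array([rot[2, 1] - rot[1, 2],
                    rot[0, 2] - rot[2, 0],
                    rot[1, 0] - rot[0, 1]])
    axis = vec / np.linalg.norm(vec)
    return float(angle), axis


def random_rotation_matrix(rng: np.random.Generator,
                           max_angle_deg: float | None = None,
                           angle_deg: float | None = None) -> np.ndarray:
    """Random rotation: uniform axis, with either a fixed angle or a
    uniform angle in [0, max_angle_deg]."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    if angle_deg is None:
        if max_angle_deg is None:
            raise ValueError("either angle_deg or max_angle_deg required")
        angle_deg = rng.uniform(0.0, max_angle_deg)
    return axis_angle_matrix(v, angle_deg)
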