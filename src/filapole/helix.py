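"""Helical filament construction and helical-parameter fitting.

A filament lattice is described by a twist (azimuthal rotation per subunit
along the 1-start helix, degrees, right-handed positive about +z), a rise
(axial translation per subunit, Angstrom) and a cyclic symmetry order Cn.
Placement ``(level k, copy c)`` applies ``Rz(k*twist + c*360/cn)`` followed by
translation ``(0, 0, k*rise)``; "top" is +z.

Fitting goes the other way: given placed subunits, the consensus screw
transform between axially consecutive subunits is estimated by least squares
(Kabsch per pair), and its rotation angle/axial component recover the twist
and rise. The helical axis is taken from the rotation matrix's eigenvector,
which is exact for noiseless helices; PCA of centroids is only a fallback for
the degenerate twist-free case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._geom import RigidTransform, kabsch, rotation_about_z, rotation_angle_axis

logger = logging.getLogger("filapole")

__all__ = [
    "HelicalParams",
    "Placement",
    "FilamentModel",
    "build_filament",
    "fit_helical_params",
    "align_axis",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Not enough subunits for the requested operation."""


@dataclass(frozen=True)
class HelicalParams:
    """Twist/rise/cyclic-symmetry descriptor of a filament lattice."""

    twist_deg: float
    rise: float
    cn: int = 1
    n_levels: int = 1

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be > 0")
        if not (0 <= abs(self.twist_deg) <= 180):
            raise ValueError("|twist_deg| must be <= 180")
        if self.cn < 1 or self.n_levels < 1:
            raise ValueError("cn and n_levels must be >= 1")

    @property
    def subunits_per_turn(self) -> float:
        """360/|twist|; informational (about 6.75 at twist 53.3 deg)."""
        if self.twist_deg == 0:
            return float("inf")
        return 360.0 / abs(self.twist_deg)


@dataclass(frozen=True)
class Placement:
    level: int
    copy: int
    transform: RigidTransform

    @property
    def key(self) -> tuple[int, int]:
        return (self.level, self.copy)


@dataclass
class FilamentModel:
    """A protomer replicated by rigid transforms onto a helical lattice."""

    protomer: "Protomer"
    placements: list[Placement]
    params: HelicalParams | None = None
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        keys = [p.key for p in self.placements]
        if len(set(keys)) != len(keys):
            raise ValueError("placements must be unique by (level, copy)")

    def __len__(self) -> int:
        return len(self.placements)

    def ca(self, i: int) -> np.ndarray:
        return self.placements[i].transform.apply(self.protomer.ca)

    def cb(self, i: int) -> np.ndarray:
        return self.placements[i].transform.apply(self.protomer.cb)

    def centroid(self, i: int) -> np.ndarray:
        return self.placements[i].transform.apply(self.protomer.ca).mean(axis=0)

    def index_of(self, level: int, copy: int) -> int | None:
        for i, p in enumerate(self.placements):
            if p.key == (level, copy):
                return i
        return None

    def transformed(self, extra: RigidTransform) -> "FilamentModel":
        placements = [Placement(p.level, p.copy, extra.compose(p.transform))
                      for p in self.placements]
        return FilamentModel(self.protomer, placements, self.params,
                             extra.rot @ self.axis)


def lattice_transform(params: HelicalParams, level: int, copy: int
                      ) -> RigidTransform:
    """The rigid transform of lattice site ``(level, copy)``."""
    angle = level * params.twist_deg + copy * 360.0 / params.cn
    return RigidTransform(rotation_about_z(angle),
                          np.array([0.0, 0.0, level * params.rise]))


def build_filament(protomer, params: HelicalParams) -> FilamentModel:
    """Place ``cn * n_levels`` rigid copies of the protomer on the lattice."""
    if len(protomer) == 0:
        raise ValueError("protomer must be non-empty")
    placements = [
        Placement(k, c, lattice_transform(params, k, c))
        for k in range(params.n_levels)
        for c in range(params.cn)
    ]
    return FilamentModel(protomer, placements, params)


def _consecutive_pairs(filament: FilamentModel) -> list[tuple[int, int]]:
    by_key = {p.key: i for i, p in enumerate(filament.placements)}
    pairs = []
    for (level, copy), i in by_key.items():
        j = by_key.get((level + 1, copy))
        if j is not None:
            pairs.append((i, j))
    return pairs


def _screw_from_transform(t: RigidTransform) -> tuple[float, float, np.ndarray]:
    """(twist_deg signed, rise, unit axis with positive rise) of a screw."""
    angle, axis = rotation_angle_axis(t.rot)
    if angle < 1e-4:
        # (near-)pure translation: below this angle the rotation axis is
        # numerically undetermined, so use the translation direction
        norm = np.linalg.norm(t.trans)
        if norm == 0:
            raise InsufficientDataError("identity transform between subunits")
        return 0.0, norm, t.trans / norm
    rise = float(t.trans @ axis)
    if rise < 0:
        axis = -axis
        rise = -rise
        angle = -angle
    return float(angle), rise, axis


def fit_helical_params(filament_or_coords) -> tuple[HelicalParams, float]:
    """Estimate (twist, rise) from a filament and report a residual.

    Accepts a :class:`FilamentModel` (pairs are taken along the 1-start helix,
    same copy index, consecutive levels) or a bare list of (n, 3) coordinate
    arrays of identical composition, taken as consecutive subunits in helical
    order. The residual is the RMS deviation of per-pair (twist, rise)
    estimates from their consensus (degrees and Angstroms mixed 1:1).
    """
    if isinstance(filament_or_coords, FilamentModel):
        fil = filament_or_coords
        coords = [fil.ca(i) for i in range(len(fil))]
        pairs = _consecutive_pairs(fil)
        cn = fil.params.cn if fil.params is not None else 1
    else:
        coords = [np.asarray(c, dtype=float) for c in filament_or_coords]
        pairs = [(i, i + 1) for i in range(len(coords) - 1)]
        cn = 1
    if len(coords) < 2 or not pairs:
        raise InsufficientDataError("need at least 2 axially consecutive "
                                    "subunits")
    sizes = {c.shape for c in coords}
    if len(sizes) != 1:
        raise ValueError("inconsistent subunit compositions")

    twists, rises, axes = [], [], []
    for i, j in pairs:
        t = kabsch(coords[i], coords[j])
        tw, rs, ax = _screw_from_transform(t)
        twists.append(tw)
        rises.append(rs)
        axes.append(ax)
    twists = np.array(twists)
    rises = np.array(rises)
    # circular mean for the twist (handles +-180 wrap)
    rad = np.deg2rad(twists)
    twist = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
    rise = float(rises.mean())
    dev = np.concatenate([
        np.degrees(np.angle(np.exp(1j * (rad - np.deg2rad(twist))))),
        rises - rise,
    ])
    residual = float(np.sqrt(np.mean(dev ** 2)))
    n_levels = (max(len(coords) // max(cn, 1), 1))
    params = HelicalParams(twist_deg=twist, rise=rise, cn=cn,
                           n_levels=n_levels)
    return params, residual


def _axis_point(rot: np.ndarray, trans: np.ndarray, axis: np.ndarray
                ) -> np.ndarray:
    """A point on the screw axis of ``x -> rot x + trans``."""
    # component of the translation perpendicular to the axis must be
    # produced by the rotation about a displaced axis: (I - R) p = t_perp
    t_perp = trans - (trans @ axis) * axis
    a = np.eye(3) - rot
    # (I - R) is singular along the axis; solve in the perpendicular space
    p, *_ = np.linalg.lstsq(a, t_perp, rcond=None)
    return p - (p @ axis) * axis


def align_axis(filament: FilamentModel) -> FilamentModel:
    """Rigidly move the filament so its fitted helical axis is +z, the axis
    passes through the origin, and the lowest subunit centroid has z = 0."""
    if len(filament) < 3:
        raise InsufficientDataError("need at least 3 subunits to align")
    pairs = _consecutive_pairs(filament)
    centroids = np.array([filament.centroid(i) for i in range(len(filament))])
    if pairs:
        mats, axes = [], []
        for i, j in pairs:
            t = kabsch(filament.ca(i), filament.ca(j))
            tw, rs, ax = _screw_from_transform(t)
            axes.append(ax)
            mats.append((t, tw))
        axis = np.mean(axes, axis=0)
        axis /= np.linalg.norm(axis)
        t0, tw0 = mats[0]
        if abs(tw0) > 1e-8:
            point = _axis_point(t0.rot, t0.trans, axis)
        else:
            point = centroids.mean(axis=0)
    else:
        # degenerate fallback: principal axis of the centroids
        logger.warning("align_axis: no consecutive pairs; falling back to "
                       "centroid principal axis")
        c = centroids - centroids.mean(axis=0)
        _, _, vt = np.linalg.svd(c)
        axis = vt[0]
        point = centroids.mean(axis=0)
    if axis[2] < 0:
        axis = -axis
    # rotation taking the fitted axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    moved = RigidTransform(rot, -rot @ point)
    out = filament.transformed(moved)
    zmin = min(out.centroid(i)[2] for i in range(len(out)))
    shift = RigidTransform(np.eye(3), np.array([0.0, 0.0, -zmin]))
    return out.transformed(shift)
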