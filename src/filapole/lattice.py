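"""Subunit contacts, interface-type classification and honeycomb pockets.

Death-domain-like filaments expose three recurring subunit-subunit contact
classes. Here edges between placed subunits are found from CB-CB distances,
clustered by their relative rigid transform (rotation angle + axial offset),
and assigned type ids 1/2/3 by a fixed geometric convention. Each edge has an
``a`` side (the lower-z partner, whose engaged surface faces +z) and a ``b``
side. A center subunit with all six neighbors defines the honeycomb; its six
ligand-pocket subsections are the cyclically consecutive neighbor trios in
the unrolled (azimuth, z) sheet, tagged top/bottom by where the pocket sits
relative to the ligand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from ._geom import RigidTransform, rotation_angle_axis
from .helix import FilamentModel

logger = logging.getLogger("filapole")

__all__ = [
    "ContactEdge",
    "InterfaceLabel",
    "Subsection",
    "contact_map",
    "classify_interfaces",
    "extract_pockets",
    "end_surface_report",
    "filament_diameters",
    "ca_rmsd",
    "SURFACES",
]

SURFACES = ("1a", "1b", "2a", "2b", "3a", "3b")

#: transform-clustering tolerances: far below inter-class separation in a
#: 53 deg / 14 A lattice, robust to modelling noise
ROT_TOL_DEG = 5.0
TRANS_TOL = 2.0


@dataclass
class InterfaceLabel:
    type_id: int          # 1, 2 or 3
    side_of_i: str        # 'a' or 'b'
    side_of_j: str

    def surface_of(self, which: str) -> str:
        side = self.side_of_i if which == "i" else self.side_of_j
        return f"{self.type_id}{side}"


@dataclass
class ContactEdge:
    subunit_i: int
    subunit_j: int
    residue_pairs: list[tuple[int, int, float]]   # (res_i, res_j, CB dist A)
    rel_transform: RigidTransform                 # j relative to i
    axial_offset: float                           # z_j - z_i, signed (lab)
    rotation_deg: float = 0.0    # screw rotation, signed about the
    #                              positive-translation screw axis (invariant)
    screw_offset: float = 0.0    # |translation along the screw axis| (invariant)
    label: InterfaceLabel | None = None

    @property
    def pair(self) -> tuple[int, int]:
        return (self.subunit_i, self.subunit_j)


def contact_map(filament: FilamentModel, cutoff: float = 8.0
                ) -> list[ContactEdge]:
    """All subunit pairs with at least one CB-CB pair under ``cutoff``.

    Each unordered pair is listed once, with ``subunit_i`` the lower-z
    subunit (ties broken by azimuth, then placement order).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = len(filament)
    cbs = [filament.cb(i) for i in range(n)]
    cents = [filament.centroid(i) for i in range(n)]
    res_idx = filament.protomer.indices
    edges: list[ContactEdge] = []
    for i in range(n):
        for j in range(i + 1, n):
            # cheap sphere prefilter
            rad = max(np.linalg.norm(cbs[i] - cents[i], axis=1).max(),
                      np.linalg.norm(cbs[j] - cents[j], axis=1).max())
            if np.linalg.norm(cents[i] - cents[j]) > 2 * rad + cutoff:
                continue
            d = cdist(cbs[i], cbs[j])
            ii, jj = np.nonzero(d < cutoff)
            if ii.size == 0:
                continue
            lo, hi = i, j
            if (cents[j][2], np.arctan2(cents[j][1], cents[j][0])) < \
               (cents[i][2], np.arctan2(cents[i][1], cents[i][0])):
                lo, hi = j, i
            if lo != i:
                ii, jj = jj, ii
                d = d.T
            ti = filament.placements[lo].transform
            tj = filament.placements[hi].transform
            rel = ti.inverse().compose(tj)
            # screw decomposition of the relative transform: invariant under
            # any global rigid motion of the filament (unlike lab-frame z)
            angle, axis = rotation_angle_axis(rel.rot)
            screw = float(rel.trans @ axis)
            if screw < 0:
                axis, angle, screw = -axis, -angle, -screw
            if abs(angle) < 1e-10:
                angle = 0.0
                screw = float(np.linalg.norm(rel.trans))
            pairs = [(int(res_idx[a]), int(res_idx[b]), float(d[a, b]))
                     for a, b in zip(ii, jj)]
            edges.append(ContactEdge(
                subunit_i=lo, subunit_j=hi, residue_pairs=pairs,
                rel_transform=rel,
                axial_offset=float(cents[hi][2] - cents[lo][2]),
                rotation_deg=float(angle), screw_offset=screw))
    return edges


def classify_interfaces(edges: list[ContactEdge],
                        rot_tol: float = ROT_TOL_DEG,
                        trans_tol: float = TRANS_TOL,
                        expected_clusters: int = 3) -> dict[tuple[int, int],
                                                            InterfaceLabel]:
    """Cluster edges by relative transform and assign interface types.

    Edges are clustered by their screw decomposition (signed rotation angle,
    translation along the screw axis) with single-linkage agglomeration at
    the given tolerances; both features are invariant under global rigid
    motion. Type ids follow the axial-offset ascending rank: smallest -> 1,
    middle -> 3, largest -> 2 (ties broken by rotation-angle magnitude
    ascending), which on a six-per-turn lattice makes type 2 the near-axial
    two-level contact. Within each edge the lower-z subunit is the ``a``
    side.
    """
    if not edges:
        return {}
    feats = np.array([[e.rotation_deg / rot_tol,
                       e.screw_offset / trans_tol] for e in edges])
    if len(edges) == 1:
        clusters = np.array([1])
    else:
        z = linkage(pdist(feats, metric="chebyshev"), method="single")
        clusters = fcluster(z, t=1.0, criterion="distance")
    ids = np.unique(clusters)
    if len(ids) != expected_clusters:
        warnings.warn(
            f"expected {expected_clusters} interface clusters, found "
            f"{len(ids)}; type ids assigned by rank anyway", stacklevel=2)
    # rank clusters: |axial offset| ascending, tie-break |rotation| ascending
    keyed = []
    for cid in ids:
        sel = clusters == cid
        keyed.append((np.mean([e.screw_offset
                               for e, s in zip(edges, sel) if s]),
                      np.mean([abs(e.rotation_deg)
                               for e, s in zip(edges, sel) if s]),
                      cid))
    keyed.sort()
    rank_to_type = {0: 1, 1: 3, 2: 2}
    if len(ids) != 3:
        rank_to_type = {r: r + 1 for r in range(len(ids))}
    type_of = {cid: rank_to_type[rank] for rank, (_, _, cid) in
               enumerate(keyed)}
    labels: dict[tuple[int, int], InterfaceLabel] = {}
    for e, cid in zip(edges, clusters):
        lab = InterfaceLabel(type_id=type_of[cid], side_of_i="a",
                             side_of_j="b")
        e.label = lab
        labels[e.pair] = lab
    return labels


@dataclass
class Subsection:
    """One ligand protomer plus a pocket of three adjacent subunits."""

    ligand: int
    pocket: tuple[int, int, int]
    position_tag: str                       # 'top' | 'bottom'
    engaged_surfaces: list[tuple[int, str]]  # (pocket member, its surface)
    incomplete: bool = False


def _neighbor_edges(center: int, edges: list[ContactEdge]
                    ) -> dict[int, ContactEdge]:
    out = {}
    for e in edges:
        if e.subunit_i == center:
            out[e.subunit_j] = e
        elif e.subunit_j == center:
            out[e.subunit_i] = e
    return out


def extract_pockets(filament: FilamentModel, center: int,
                    edges: list[ContactEdge]) -> list[Subsection]:
    """The six honeycomb subsections around an interior center subunit.

    Neighbors are ordered by their planar angle in the unrolled (azimuth, z)
    sheet around the center; each cyclically consecutive trio forms one
    pocket with the center as ligand. A pocket is ``top`` when its mean z is
    below the ligand (the ligand docks onto the top surface of the pocket).
    """
    if any(e.label is None for e in edges):
        raise ValueError("edges must be classified first")
    nbrs = _neighbor_edges(center, edges)
    c0 = filament.centroid(center)
    r0 = float(np.linalg.norm(c0[:2]))
    items = []
    for nid, edge in nbrs.items():
        cn = filament.centroid(nid)
        dz = cn[2] - c0[2]
        dtheta = np.angle(np.exp(1j * (np.arctan2(cn[1], cn[0])
                                       - np.arctan2(c0[1], c0[0]))))
        planar = np.arctan2(dz, r0 * dtheta) % (2 * np.pi)
        member_side = edge.label.side_of_i if edge.subunit_i == nid \
            else edge.label.side_of_j
        surface = f"{edge.label.type_id}{member_side}"
        items.append((planar, nid, surface, dz))
    items.sort()
    incomplete = len(items) < 6
    if incomplete:
        logger.warning("center subunit %d has %d neighbors (< 6); returning "
                       "incomplete subsections", center, len(items))
    subsections = []
    m = len(items)
    if m < 3:
        return []
    n_trios = m if m >= 3 and not incomplete else m - 2
    if not incomplete:
        trios = [(items[k], items[(k + 1) % m], items[(k + 2) % m])
                 for k in range(m)]
    else:
        trios = [(items[k], items[k + 1], items[k + 2])
                 for k in range(n_trios)]
    for trio in trios:
        mean_dz = np.mean([t[3] for t in trio])
        tag = "top" if mean_dz < 0 else "bottom"
        subsections.append(Subsection(
            ligand=center,
            pocket=tuple(t[1] for t in trio),
            position_tag=tag,
            engaged_surfaces=[(t[1], t[2]) for t in trio],
            incomplete=incomplete))
    return subsections


def surface_engagement(filament: FilamentModel, edges: list[ContactEdge]
                       ) -> dict[int, set[str]]:
    """Engaged surface labels per subunit (requires classified edges)."""
    engaged: dict[int, set[str]] = {i: set() for i in range(len(filament))}
    for e in edges:
        if e.label is None:
            raise ValueError("edges must be classified first")
        engaged[e.subunit_i].add(e.label.surface_of("i"))
        engaged[e.subunit_j].add(e.label.surface_of("j"))
    return engaged


def end_surface_report(filament: FilamentModel, edges: list[ContactEdge]
                       ) -> dict[str, list[str]]:
    """Unengaged surfaces on the terminal (lowest/highest level) subunits.

    Returns ``{"top": [...], "bottom": [...]}`` with sorted unions of the
    surface labels that have no partner in the lattice on the respective
    terminal subunits.
    """
    engaged = surface_engagement(filament, edges)
    levels = [p.level for p in filament.placements]
    lo, hi = min(levels), max(levels)
    out = {"top": set(), "bottom": set()}
    for i, p in enumerate(filament.placements):
        missing = set(SURFACES) - engaged[i]
        if p.level == hi:
            out["top"] |= missing
        if p.level == lo:
            out["bottom"] |= missing
    return {k: sorted(v) for k, v in out.items()}


def filament_diameters(filament: FilamentModel) -> dict[str, float]:
    """Outer-rim and inner-cavity diameters of an axis-aligned filament.

    Uses all beads' radial distances from the z axis; the inner diameter is
    twice the smallest radial distance (the lumen radius), the outer twice
    the largest.
    """
    radii = []
    for i in range(len(filament)):
        for coords in (filament.ca(i), filament.cb(i)):
            radii.append(np.linalg.norm(coords[:, :2], axis=1))
    radii = np.concatenate(radii)
    return {"outer_diameter": float(2 * radii.max()),
            "inner_diameter": float(2 * radii.min())}


def ca_rmsd(a, b) -> float:
    """CA RMSD between two protomers after optimal superposition.

    Protomers must have equal residue counts (truncate/select beforehand for
    heterologous comparisons).
    """
    from ._geom import kabsch
    pa, pb = np.asarray(a.ca, float), np.asarray(b.ca, float)
    if pa.shape != pb.shape:
        n = min(len(pa), len(pb))
        pa, pb = pa[:n], pb[:n]
    t = kabsch(pa, pb)
    return float(np.sqrt(np.mean(np.sum((t.apply(pa) - pb) ** 2, axis=1))))
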