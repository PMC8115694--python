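"""Residue-level interface energy model, honeycomb tables and local docking.

The score is deliberately transparent rather than physical: a 5x5 class-pair
well-depth table plus a Coulomb-like charge product, switched off linearly
between ``d_on`` and ``d_off`` on CB-CB distances, with a flat clash penalty
below ``clash_d``:

    E(i, j) = [eps(cls_i, cls_j) + w_elec * q_i * q_j] * S(d)
              + clash_penalty * 1[d < clash_d]

    S(d) = 1 for d <= d_on, linear to 0 at d_off, 0 beyond.

It is hand-checkable (Lys-Glu at 5 A under defaults scores -2.5) and encodes
the designed ground truth of the synthetic scenarios; absolute values carry
no physical meaning and cross-species comparisons are made in rank order
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._geom import RigidTransform, axis_angle_matrix
from .io_model import CLASSES, CLASS_INDEX, Protomer
from .lattice import Subsection
from .helix import FilamentModel

__all__ = [
    "EnergyModel",
    "DockSample",
    "pair_energy",
    "interface_energy",
    "honeycomb_energy_table",
    "local_dock",
    "PocketComplex",
    "pocket_complex",
]


def _default_pair_matrix() -> np.ndarray:
    h, p, n, q, s = (CLASS_INDEX[c] for c in CLASSES)  # hyd, pos, neg, pol, sp
    m = np.zeros((5, 5))
    m[h, h] = -1.0
    m[p, n] = m[n, p] = -1.5
    m[p, p] = m[n, n] = +1.5
    m[q, q] = -0.5
    for charged in (p, n):
        m[q, charged] = m[charged, q] = -0.25
        m[h, charged] = m[charged, h] = +0.25
    # hydrophobic-polar and anything involving special stay 0
    return m


@dataclass
class EnergyModel:
    """Class-pair contact potential with distance switching and clashes."""

    pair_matrix: np.ndarray = field(default_factory=_default_pair_matrix)
    d_on: float = 6.0
    d_off: float = 8.0
    w_elec: float = 1.0
    clash_d: float = 3.5
    clash_penalty: float = 2.0

    def __post_init__(self):
        self.pair_matrix = np.asarray(self.pair_matrix, dtype=float)
        if self.pair_matrix.shape != (5, 5):
            raise ValueError("pair_matrix must be 5x5")
        if not np.allclose(self.pair_matrix, self.pair_matrix.T):
            raise ValueError("pair_matrix must be symmetric")
        if not self.d_on < self.d_off:
            raise ValueError("d_on must be < d_off")
        if self.clash_penalty < 0:
            raise ValueError("clash_penalty must be >= 0")

    def switch(self, d: np.ndarray) -> np.ndarray:
        return np.clip((self.d_off - d) / (self.d_off - self.d_on), 0.0, 1.0)

    @classmethod
    def null(cls) -> "EnergyModel":
        """All interactions zero (control model)."""
        return cls(pair_matrix=np.zeros((5, 5)), w_elec=0.0, clash_penalty=0.0)


def pair_energy(res_i: dict, res_j: dict, model: EnergyModel) -> float:
    """Energy of one residue pair.

    Residues are ``{"cls": str, "charge": number, "cb": (3,) array}`` (as in
    :class:`Protomer` beads).
    """
    d = float(np.linalg.norm(np.asarray(res_i["cb"], float)
                             - np.asarray(res_j["cb"], float)))
    eps = model.pair_matrix[CLASS_INDEX[res_i["cls"]],
                            CLASS_INDEX[res_j["cls"]]]
    e = (eps + model.w_elec * res_i["charge"] * res_j["charge"]) \
        * model.switch(d)
    if d < model.clash_d:
        e += model.clash_penalty
    return float(e)


class PocketComplex:
    """Precomputed ligand/pocket bead data for fast repeated scoring."""

    def __init__(self, ligand: Protomer, ligand_transform: RigidTransform,
                 pocket: list[tuple[Protomer, RigidTransform]],
                 model: EnergyModel):
        self.model = model
        self.ligand = ligand
        self.native_ca = ligand_transform.apply(ligand.ca)
        self.native_cb = ligand_transform.apply(ligand.cb)
        self.pocket_cb = [t.apply(p.cb) for p, t in pocket]
        self.pocket_sizes = [len(p) for p, _ in pocket]
        cb_all = np.vstack(self.pocket_cb)
        self._bounds = np.cumsum(self.pocket_sizes)[:-1]
        self.pocket_cb_all = cb_all
        lc, lq = ligand.classes, ligand.charges
        pc = np.concatenate([p.classes for p, _ in pocket])
        pq = np.concatenate([p.charges for p, _ in pocket])
        self.weights = (model.pair_matrix[np.ix_(lc, pc)]
                        + model.w_elec * np.outer(lq, pq))

    def energy(self, ligand_cb: np.ndarray) -> float:
        d = cdist(ligand_cb, self.pocket_cb_all)
        e = float(np.sum(self.weights * self.model.switch(d)))
        if self.model.clash_penalty:
            e += self.model.clash_penalty * int(np.count_nonzero(
                d < self.model.clash_d))
        return e

    def energy_breakdown(self, ligand_cb: np.ndarray) -> list[float]:
        d = cdist(ligand_cb, self.pocket_cb_all)
        contrib = self.weights * self.model.switch(d)
        if self.model.clash_penalty:
            contrib = contrib + self.model.clash_penalty * (
                d < self.model.clash_d)
        return [float(part.sum()) for part in
                np.split(contrib, self._bounds, axis=1)]

    def min_distance(self, ligand_cb: np.ndarray) -> float:
        return float(cdist(ligand_cb, self.pocket_cb_all).min())


def pocket_complex(filament: FilamentModel, subsection: Subsection,
                   model: EnergyModel,
                   ligand_protomer: Protomer | None = None) -> PocketComplex:
    """Build a :class:`PocketComplex` from a filament subsection.

    ``ligand_protomer`` substitutes a different species at the ligand
    position (same placement frame), e.g. for heterotypic docking.
    """
    lig = ligand_protomer if ligand_protomer is not None \
        else filament.protomer
    lt = filament.placements[subsection.ligand].transform
    pocket = [(filament.protomer, filament.placements[m].transform)
              for m in subsection.pocket]
    return PocketComplex(lig, lt, pocket, model)


def interface_energy(complex_or_filament, subsection: Subsection | None = None,
                     model: EnergyModel | None = None,
                     ligand_protomer: Protomer | None = None) -> dict:
    """Interface energy of a ligand against its pocket, with breakdown.

    Either pass a prebuilt :class:`PocketComplex`, or a filament plus a
    classified :class:`Subsection` and a model. Returns ``{"energy",
    "breakdown", "no_contact"}``; the breakdown is per pocket member.
    """
    if isinstance(complex_or_filament, PocketComplex):
        pc = complex_or_filament
    else:
        if subsection is None or model is None:
            raise ValueError("subsection and model required with a filament")
        pc = pocket_complex(complex_or_filament, subsection, model,
                            ligand_protomer)
    breakdown = pc.energy_breakdown(pc.native_cb)
    no_contact = pc.min_distance(pc.native_cb) > pc.model.d_off
    return {"energy": float(sum(breakdown)), "breakdown": breakdown,
            "no_contact": bool(no_contact)}


def honeycomb_energy_table(filament: FilamentModel, center: int,
                           edges, model: EnergyModel,
                           center_protomer: Protomer | None = None
                           ) -> pd.DataFrame:
    """Per-edge energies between a center protomer and its six neighbors.

    ``center_protomer`` places a different species at the center (heterotypic
    honeycomb); neighbors keep the filament species. One row per edge with
    the interface label, species pair, signed axial direction of the
    neighbor, and the edge energy.
    """
    from .lattice import _neighbor_edges
    if any(e.label is None for e in edges):
        raise ValueError("edges must be classified first")
    nbrs = _neighbor_edges(center, edges)
    center_prot = center_protomer or filament.protomer
    ct = filament.placements[center].transform
    rows = []
    for nid, edge in sorted(nbrs.items()):
        member = (filament.protomer, filament.placements[nid].transform)
        pc = PocketComplex(center_prot, ct, [member], model)
        energy = pc.energy(pc.native_cb)
        center_is_i = edge.subunit_i == center
        center_side = edge.label.side_of_i if center_is_i \
            else edge.label.side_of_j
        nbr_side = edge.label.side_of_j if center_is_i \
            else edge.label.side_of_i
        dz = filament.centroid(nid)[2] - filament.centroid(center)[2]
        rows.append({
            "neighbor": nid,
            "type_id": edge.label.type_id,
            "center_surface": f"{edge.label.type_id}{center_side}",
            "neighbor_surface": f"{edge.label.type_id}{nbr_side}",
            "species_pair": f"{center_prot.species_label}-"
                            f"{filament.protomer.species_label}",
            "half": "top" if dz > 0 else "bottom",
            "energy": energy,
        })
    return pd.DataFrame(rows, columns=["neighbor", "type_id",
                                       "center_surface", "neighbor_surface",
                                       "species_pair", "half", "energy"])


@dataclass
class DockSample:
    energy: float
    rmsd: float
    perturbation: tuple[float, float]   # (rotation deg, translation A)
    seed: int


# greedy minimizer constants: cheap funnel sharpening
_GREEDY_ITERS = 20
_GREEDY_ROT0 = 2.0    # deg
_GREEDY_TRANS0 = 1.0  # A


def _rotation_angle(rot: np.ndarray) -> float:
    return float(np.degrees(np.arccos(
        np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0))))


def _greedy_minimize(pc: PocketComplex, ca: np.ndarray, cb: np.ndarray,
                     rot_from_native: np.ndarray,
                     rng: np.random.Generator,
                     iters: int = _GREEDY_ITERS,
                     max_com_shift: float = 4.0,
                     max_rotation: float = 30.0):
    """Greedy descent over the 6 rigid DOF with step halving.

    Each iteration probes three random orthonormal directions (both signs)
    as translations and as rotation axes through the ligand COM and takes
    the best energy-lowering move; the step shrinks when nothing improves.
    Random (isotropic) probe directions keep the optimizer free of any
    lab-frame preference, so symmetry-related pockets are explored
    identically in distribution. This is local docking, so the ligand stays
    in its own pocket: translations beyond ``max_com_shift`` of the native
    COM and rotations beyond ``max_rotation`` of the native orientation are
    rejected rather than allowed to wander onto a neighboring interface.
    """
    native_com = pc.native_ca.mean(axis=0)
    rot_step, trans_step = _GREEDY_ROT0, _GREEDY_TRANS0
    energy = pc.energy(cb)
    for _ in range(iters):
        axes, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        best = None
        com = ca.mean(axis=0)
        for axis in axes.T:
            for sign in (1.0, -1.0):
                r = axis_angle_matrix(axis, sign * rot_step)
                if _rotation_angle(r @ rot_from_native) <= max_rotation:
                    cb_try = (cb - com) @ r.T + com
                    e = pc.energy(cb_try)
                    if best is None or e < best[0]:
                        best = (e, ("rot", axis, sign))
                shift = axis * (sign * trans_step)
                if np.linalg.norm(com + shift - native_com) > max_com_shift:
                    continue
                e = pc.energy(cb + shift)
                if best is None or e < best[0]:
                    best = (e, ("trans", axis, sign))
        if best is not None and best[0] < energy - 1e-12:
            energy = best[0]
            kind, axis, sign = best[1]
            if kind == "rot":
                r = axis_angle_matrix(axis, sign * rot_step)
                cb = (cb - com) @ r.T + com
                ca = (ca - com) @ r.T + com
                rot_from_native = r @ rot_from_native
            else:
                shift = axis * (sign * trans_step)
                cb = cb + shift
                ca = ca + shift
        else:
            rot_step *= 0.5
            trans_step *= 0.5
    return energy, ca, cb


def local_dock(pc: PocketComplex, n_samples: int, sigma_rot: float = 10.0,
               sigma_trans: float = 2.0, seed: int = 0,
               greedy_iters: int = _GREEDY_ITERS,
               max_com_shift: float = 4.0,
               max_rotation: float = 30.0) -> list[DockSample]:
    """Local rigid-body docking of the ligand into its pocket.

    Each sample perturbs the native pose by a random rotation (half-normal
    angle of scale ``sigma_rot`` about a uniform axis, around the ligand COM)
    and an isotropic normal translation (``sigma_trans``), then greedily
    minimizes the interface energy. Records the final energy and the ligand
    CA RMSD from the native pose without superposition. Fully reproducible
    from ``seed`` (one RNG stream per call).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    native_ca, native_cb = pc.native_ca, pc.native_cb
    com = native_ca.mean(axis=0)
    samples = []
    for k in range(n_samples):
        angle = abs(rng.normal(0.0, sigma_rot)) if sigma_rot > 0 else 0.0
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        shift = rng.normal(0.0, sigma_trans, size=3) if sigma_trans > 0 \
            else np.zeros(3)
        r = axis_angle_matrix(axis, angle)
        ca = (native_ca - com) @ r.T + com + shift
        cb = (native_cb - com) @ r.T + com + shift
        energy, ca, cb = _greedy_minimize(pc, ca, cb, r, rng,
                                          iters=greedy_iters,
                                          max_com_shift=max_com_shift,
                                          max_rotation=max_rotation)
        rmsd = float(np.sqrt(np.mean(np.sum((ca - native_ca) ** 2, axis=1))))
        samples.append(DockSample(energy=float(energy), rmsd=rmsd,
                                  perturbation=(float(angle),
                                                float(np.linalg.norm(shift))),
                                  seed=seed))
    return samples
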