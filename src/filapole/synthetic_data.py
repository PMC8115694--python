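"""Toy protomers, filament scenarios with designed interaction codes, and
synthetic kinetics datasets.

The toy protomer is a rigid coarse body, not a folded domain: a small
glycine core around the body centroid plus six designated surface patches of
four residue beads each. Patch positions are derived from the lattice
itself, so that in a filament built with the scenario's helical parameters
patch pairs (1a:1b), (2a:2b), (3a:3b) of neighboring subunits come into
contact range and nothing else does. Patch compositions, not geometry, carry
the interaction code (charge complementarity or mismatch per interface).

Construction detail that the directionality tests lean on: the body centroid
sits on the lab x axis and every b-patch is the image of its a-patch under
the 180-degree rotation about that axis. A helical lattice of such protomers
is exactly dihedral, so homotypic top and bottom docking landscapes are
congruent by construction and any measured asymmetry is sampling noise. For
each interface type the map between an a-patch and the partner b-patch in
the lattice is itself a 180-degree rotation, whose axis is computed and used
to lay out bead grids with exact designed pair distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import RigidTransform, rotation_angle_axis
from .helix import HelicalParams, build_filament, lattice_transform
from .io_model import Protomer
from .lattice import SURFACES

__all__ = [
    "ConstructionError",
    "ToyGeometry",
    "PAPER_LATTICE",
    "SPECIES_A_PATCHES",
    "SPECIES_B_PATCHES",
    "NULL_PATCHES",
    "make_toy_protomer",
    "make_scenario",
    "make_kinetics_dataset",
    "INTERFACE_GENERATORS",
]


class ConstructionError(ValueError):
    """Requested patch layout is not realizable on the given lattice."""


#: helical parameters of the emulated filament class (six-per-turn, C3)
PAPER_LATTICE = HelicalParams(twist_deg=53.3, rise=14.0, cn=3, n_levels=6)

#: lattice offsets (level, copy) generating the three interface types;
#: type 1 and 3 are the one-level lateral contacts, type 2 the near-axial
#: two-level contact
INTERFACE_GENERATORS = {1: (1, 0), 3: (1, -1), 2: (2, -1)}

# species A: charge-complementary lateral interfaces (types 1 and 3; type 3
# mixes in polar residues so type 1 contributes most). The axial type-2
# contact is an inert glycine pad pair: homotypic axial contacts exist
# geometrically but carry no energy. The heterotypic recognition site is a
# retracted arginine arm behind the 2a pad (with its charge-conjugate
# aspartate image behind the 2b pad), out of reach of every homotypic
# neighbor.
SPECIES_A_PATCHES = {
    "1a": "KKKK", "1b": "EEEE",
    "2a": "GGGG", "2b": "GGGG",
    "3a": "KKNN", "3b": "EEQQ",
}
SPECIES_A_ARM = "RRRR"   # 2a-face recognition arm (2b image is conjugate)

# species B: type-1 charge complementarity reversed w.r.t. A (mismatch in
# hetero contacts), lateral patches only weakly self-complementary, and a
# protruding aspartate arm on the 2b face that reaches the retracted
# arginine arm of an A-type protomer below it (bottom of B recognizes the
# top of A)
SPECIES_B_PATCHES = {
    "1a": "ESSS", "1b": "KTTT",
    "2a": "GGGG", "2b": "GGGG",
    "3a": "SSSS", "3b": "TTTT",
}
SPECIES_B_ARM = "DDDD"   # 2b-face reach arm

#: non-interacting control
NULL_PATCHES = {s: "GGGG" for s in SURFACES}

# charge-conjugate map used to keep mixed patches energy-symmetric under the
# protomer's internal C2 (K<->E, R<->D, N<->Q, S<->T; others self-paired)
_CONJUGATE = {"K": "E", "E": "K", "R": "D", "D": "R",
              "N": "Q", "Q": "N", "S": "T", "T": "S"}


@dataclass(frozen=True)
class ToyGeometry:
    """Geometric constants of the toy protomer (Angstroms)."""

    radius: float = 33.0        # body centroid distance from the helix axis
    pair_gap: float = 4.2       # designed CB-CB gap across types 1 and 2
    pair_gap_type3: float = 4.2  # type-3 gap (weakening is compositional)
    grid_step: float = 3.5      # bead spacing within a patch
    ca_inset: float = 1.2       # CA sits this far inside its CB
    core_spread: float = 1.8    # core bead scatter around the centroid
    n_core: int = 8             # glycine core beads (must be even)
    arm_retract: float = 4.5    # recognition arm depth behind the 2a pad
    arm_lateral: float = 7.0    # lateral offset of the arm column
    arm_step: float = 2.5       # bead spacing within an arm
    arm_gap: float = 4.5        # reach-arm tip to recognition-arm distance

    def gap_for(self, type_id: int) -> float:
        return self.pair_gap_type3 if type_id == 3 else self.pair_gap


def _c2x(points: np.ndarray) -> np.ndarray:
    """180-degree rotation about the lab x axis."""
    out = np.asarray(points, dtype=float).copy()
    out[..., 1] *= -1
    out[..., 2] *= -1
    return out


def _patch_sites(lattice: HelicalParams, geom: ToyGeometry
                 ) -> dict[str, np.ndarray]:
    """CB bead sites of the patches and arms, in the protomer's local frame.

    For each type t the a-patch is laid out around the contact midpoint with
    the (level+1 or +2) neighbor; the b-patch is the C2 image of the
    a-patch, so matched bead pairs across a lattice edge sit at exactly the
    designed gap. Three extra keys describe the axial recognition machinery:
    ``2a_arm`` (a retracted column behind the 2a pad, laterally offset so it
    touches nothing in the homotypic lattice), ``2b_arm`` (its C2 image) and
    ``2b_reach`` (a protruding column on the 2b face that meets a partner's
    retracted 2a arm at ``arm_gap``).
    """
    p0 = np.array([geom.radius, 0.0, 0.0])
    sites: dict[str, np.ndarray] = {}
    for type_id, (dl, dc) in INTERFACE_GENERATORS.items():
        t = lattice_transform(lattice, dl, dc)
        m = 0.5 * (p0 + t.apply(p0[None, :])[0])
        # the a-to-b pairing map is the involution A = R_t * C2x
        inv = t.rot @ np.diag([1.0, -1.0, -1.0])
        angle, w = rotation_angle_axis(inv)
        if abs(angle - 180.0) > 1e-6:
            raise ConstructionError(
                f"type {type_id} pairing map is not an involution "
                f"(angle {angle:.3f}); lattice incompatible with the C2 "
                "construction")
        # v: from the contact midpoint toward our centroid, out of the w axis
        v = (p0 - m) - ((p0 - m) @ w) * w
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            raise ConstructionError(
                f"type {type_id} contact midpoint lies on the pairing axis")
        v /= nv
        u = np.cross(w, v)
        s, h = geom.grid_step, geom.gap_for(type_id)
        grid = []
        for aw in (-s / 2, s / 2):
            for au in (-s / 2, s / 2):
                grid.append(m + aw * w + au * u + (h / 2) * v)
        sites[f"{type_id}a"] = np.array(grid)
        sites[f"{type_id}b"] = _c2x(np.array(grid))
        if type_id == 2:
            center = (m + geom.arm_lateral * u
                      + (h / 2 + geom.arm_retract) * v)
            sa = geom.arm_step
            arm = []
            for aw in (-sa / 2, sa / 2):
                for au in (-sa / 2, sa / 2):
                    arm.append(center + aw * w + au * u)
            arm = np.array(arm)
            sites["2a_arm"] = arm
            sites["2b_arm"] = _c2x(arm)
            t_inv = lattice_transform(lattice, -dl, -dc)
            sites["2b_reach"] = t_inv.apply(arm - geom.arm_gap * v)
    return sites


def _core_sites(geom: ToyGeometry, rng: np.random.Generator) -> np.ndarray:
    """C2-symmetric glycine core beads around the centroid."""
    if geom.n_core % 2:
        raise ConstructionError("n_core must be even for the C2 layout")
    p0 = np.array([geom.radius, 0.0, 0.0])
    half = []
    for _ in range(geom.n_core // 2):
        d = rng.uniform(-geom.core_spread, geom.core_spread, size=3)
        half.append(p0 + d)
    half = np.array(half)
    return np.vstack([half, _c2x(half)])


def _check_realizable(protomer: Protomer, lattice: HelicalParams,
                      geom: ToyGeometry,
                      patch_index: dict[str, np.ndarray]) -> None:
    """Verify that lattice contacts happen exactly at the designed patches.

    Checks, for every lattice offset within reach, that (a) designed patch
    pairs sit inside the full-interaction distance without clashing and (b)
    no other bead pair of any two subunits comes under the interaction
    cutoff (using the default energy-model distances).
    """
    d_on, d_off, clash = 6.0, 8.0, 3.5
    cb = protomer.cb
    designed = {INTERFACE_GENERATORS[t]: t for t in INTERFACE_GENERATORS}
    for dl in range(0, 5):
        for dc in range(lattice.cn):
            if dl == 0 and dc == 0:
                continue
            t = lattice_transform(lattice, dl, dc)
            other = t.apply(cb)
            d = np.linalg.norm(cb[:, None, :] - other[None, :, :], axis=2)
            key = None
            for (gl, gc), tid in designed.items():
                if dl == gl and (dc - gc) % lattice.cn == 0:
                    key = tid
            if key is None:
                if d.min() < d_off:
                    raise ConstructionError(
                        f"unintended contact at offset ({dl},{dc}): min "
                        f"bead distance {d.min():.2f} A < {d_off} A")
                continue
            ia = patch_index[f"{key}a"]
            ib = patch_index[f"{key}b"]
            dpatch = d[np.ix_(ia, ib)]
            matched = np.diag(dpatch)
            if matched.max() > d_off - 1.0:
                raise ConstructionError(
                    f"type {key} designed pairs too far apart: "
                    f"{matched.max():.2f} A")
            if d.min() < clash + 0.1:
                raise ConstructionError(
                    f"type {key} offset has a near-clash: {d.min():.2f} A")
            # off-patch pairs at a designed offset are tolerable only when
            # energetically silent (at least one special-class bead)
            mask = np.ones_like(d, dtype=bool)
            mask[np.ix_(ia, ib)] = False
            special = protomer.classes == 4
            silent = special[:, None] | special[None, :]
            bad = mask & ~silent & (d < d_off)
            if bad.any():
                raise ConstructionError(
                    f"type {key} offset has an energetic off-patch contact "
                    f"at {d[bad].min():.2f} A")


def make_toy_protomer(patches: dict[str, str] | None = None,
                      size: int = 32, seed: int = 0,
                      species_label: str = "A",
                      lattice: HelicalParams = PAPER_LATTICE,
                      geom: ToyGeometry = ToyGeometry(),
                      axial_arm: str | None = None,
                      arm_aa: str = "RRRR",
                      check: bool = True) -> Protomer:
    """Build a rigid toy protomer with six designed surface patches.

    ``patches`` maps surface labels (1a..3b) to 4-letter residue strings;
    ``size`` is the core + patch residue count (>= 24; 24 go to the patches
    and the remainder to the glycine core, rounded to an even count >= 2).
    ``axial_arm`` optionally adds recognition machinery at the axial face:
    ``"recognition"`` places a retracted ``arm_aa`` column behind the 2a pad
    plus its charge-conjugate C2 image behind the 2b pad (homotypically
    inert, reachable by a partner's protruding arm); ``"reach"`` places a
    protruding ``arm_aa`` column on the 2b face that meets a recognition arm
    of the subunit below. The result is deterministic given ``seed``.
    """
    if patches is None:
        patches = SPECIES_A_PATCHES
    if size < 24:
        raise ValueError("size must be >= 24 (4 residues per surface patch)")
    if axial_arm not in (None, "recognition", "reach"):
        raise ValueError("axial_arm must be None, 'recognition' or 'reach'")
    missing = set(SURFACES) - set(patches)
    if missing:
        raise ValueError(f"patch composition missing for {sorted(missing)}")
    for s in SURFACES:
        if len(patches[s]) != 4:
            raise ValueError(f"patch {s} must list exactly 4 residues")
    if len(arm_aa) != 4:
        raise ValueError("arm_aa must list exactly 4 residues")
    n_core = max(2, size - 24)
    n_core += n_core % 2
    geom = ToyGeometry(radius=geom.radius, pair_gap=geom.pair_gap,
                       pair_gap_type3=geom.pair_gap_type3,
                       grid_step=geom.grid_step, ca_inset=geom.ca_inset,
                       core_spread=geom.core_spread, n_core=n_core,
                       arm_retract=geom.arm_retract,
                       arm_lateral=geom.arm_lateral,
                       arm_step=geom.arm_step, arm_gap=geom.arm_gap)
    rng = np.random.default_rng(seed)
    core = _core_sites(geom, rng)
    sites = _patch_sites(lattice, geom)
    p0 = np.array([geom.radius, 0.0, 0.0])

    aa: list[str] = ["G"] * n_core
    cb = [core]
    patch_index: dict[str, np.ndarray] = {}
    cursor = n_core
    for s in SURFACES:
        aa.extend(patches[s])
        cb.append(sites[s])
        patch_index[s] = np.arange(cursor, cursor + 4)
        cursor += 4
    if axial_arm == "recognition":
        aa.extend(arm_aa)
        cb.append(sites["2a_arm"])
        patch_index["2a_arm"] = np.arange(cursor, cursor + 4)
        cursor += 4
        conj = "".join(_CONJUGATE.get(a, a) for a in arm_aa)
        aa.extend(conj)
        cb.append(sites["2b_arm"])
        patch_index["2b_arm"] = np.arange(cursor, cursor + 4)
        cursor += 4
    elif axial_arm == "reach":
        aa.extend(arm_aa)
        cb.append(sites["2b_reach"])
        patch_index["2b_arm"] = np.arange(cursor, cursor + 4)
        cursor += 4
    cb = np.vstack(cb)
    # CA beads sit slightly inside their CB along the bead-to-centroid line;
    # glycines get ca == cb
    direction = p0 - cb
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    ca = cb + geom.ca_inset * direction / norms
    # glycines have no CB of their own: ca == cb
    gly = np.array([a == "G" for a in aa])
    ca[gly] = cb[gly]
    prot = Protomer(species_label, aa, ca, cb)
    prot.patch_index = patch_index  # designed surface -> residue array index
    if check:
        _check_realizable(prot, lattice, geom, patch_index)
    return prot


_GOALS = ("homo_bidirectional", "hetero_polarized", "null")


def make_scenario(goal: str = "hetero_polarized", seed: int = 0,
                  lattice: HelicalParams = PAPER_LATTICE,
                  geom: ToyGeometry = ToyGeometry()) -> dict:
    """Two toy protomer species plus machine-readable ground truth.

    Goals: ``homo_bidirectional`` (species A alone assembles with exactly
    mirror-symmetric top/bottom energetics), ``hetero_polarized`` (species B
    recognizes the top of an A filament only: B's down-facing 2b patch is
    charge-complementary to A's up-facing 2a, B's 2a is inert against A's 2b
    and the lateral patches are charge-mismatched), or ``null`` (no
    interactions anywhere).
    """
    if goal not in _GOALS:
        raise ValueError(f"unknown goal {goal!r}; expected one of {_GOALS}")
    if goal == "null":
        pa = make_toy_protomer(NULL_PATCHES, seed=seed, species_label="A",
                               lattice=lattice, geom=geom)
        pb = make_toy_protomer(NULL_PATCHES, seed=seed + 1, species_label="B",
                               lattice=lattice, geom=geom)
    elif goal == "homo_bidirectional":
        # pure self-assembly code: no heterotypic recognition machinery
        pa = make_toy_protomer(SPECIES_A_PATCHES, seed=seed,
                               species_label="A", lattice=lattice, geom=geom)
        pb = make_toy_protomer(SPECIES_B_PATCHES, seed=seed + 1,
                               species_label="B", lattice=lattice, geom=geom)
    else:
        pa = make_toy_protomer(SPECIES_A_PATCHES, seed=seed,
                               species_label="A", lattice=lattice, geom=geom,
                               axial_arm="recognition", arm_aa=SPECIES_A_ARM)
        pb = make_toy_protomer(SPECIES_B_PATCHES, seed=seed + 1,
                               species_label="B", lattice=lattice, geom=geom,
                               axial_arm="reach", arm_aa=SPECIES_B_ARM)
    pidx = pa.patch_index
    charged = {"K", "R", "E", "D"}
    homo_critical = sorted(
        int(pa.indices[i])
        for s in ("1a", "1b", "3a", "3b")
        for i in pidx[s] if pa.aa[i] in charged)
    hetero_critical = sorted(
        int(pa.indices[i]) for i in pidx["2a_arm"]) \
        if "2a_arm" in pidx else []
    ground_truth = {
        "goal": goal,
        "lattice": {"twist_deg": lattice.twist_deg, "rise": lattice.rise,
                    "cn": lattice.cn, "n_levels": lattice.n_levels},
        "patches_a": {s: list(map(int, pa.indices[pidx[s]]))
                      for s in SURFACES},
        "homo_critical_positions": [] if goal == "null" else homo_critical,
        "hetero_critical_positions": [] if goal == "null"
        else hetero_critical,
        "expected_polarity": {
            "homo_A_on_A": "bidirectional",
            "hetero_B_on_A": "polarized_top" if goal == "hetero_polarized"
            else "none",
        },
    }
    return {"protomer_a": pa, "protomer_b": pb, "lattice": lattice,
            "ground_truth": ground_truth}


def _logistic(t: np.ndarray, y0: float, amplitude: float, rate: float,
              t_half: float) -> np.ndarray:
    return y0 + amplitude / (1.0 + np.exp(-rate * (t - t_half)))


def make_kinetics_dataset(panel: list[dict] | None = None,
                          noise_sd: float = 0.02, seed: int = 0,
                          n_replicates: int = 3,
                          t_max: float = 120.0, n_points: int = 61
                          ) -> tuple[pd.DataFrame, dict]:
    """Synthetic seeded-polymerization plate with sigmoidal time courses.

    ``panel`` lists samples as ``{"sample", "role", "t_half"}`` with roles
    ``none`` (no-seed control; ``t_half`` None means a flat trace), ``wt``
    and ``mutant``; ``noise_sd`` is Gaussian noise relative to the unit
    amplitude. Returns a wide plate table (``time`` plus one column per
    well) and a metadata sidecar mapping wells to samples, in the format the
    kinetics module consumes.
    """
    if panel is None:
        panel = [
            {"sample": "no_seed", "role": "none", "t_half": None},
            {"sample": "WT", "role": "wt", "t_half": 20.0},
            {"sample": "mutantM1", "role": "mutant", "t_half": 60.0},
        ]
    roles = {entry["role"] for entry in panel}
    if "none" not in roles or "wt" not in roles:
        raise ValueError("panel must include a no-seed ('none') and a WT "
                         "('wt') control")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    data = {"time": t}
    wells = {}
    widx = 0
    for entry in panel:
        for rep in range(1, n_replicates + 1):
            well = f"W{widx:03d}"
            widx += 1
            if entry["t_half"] is None:
                y = np.zeros_like(t)
            else:
                y = _logistic(t, 0.0, 1.0, 0.35, float(entry["t_half"]))
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=t.shape)
            data[well] = y
            wells[well] = {"sample": entry["sample"], "replicate": rep,
                           "role": entry["role"]}
    plate = pd.DataFrame(data)
    meta = {"wells": wells,
            "design": {entry["sample"]: entry["t_half"] for entry in panel}}
    return plate, meta
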