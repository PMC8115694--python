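"""Structure and table I/O plus the residue-bead protomer model.

All downstream stages consume :class:`Protomer`: an ordered rigid body of
residue beads, one CA/CB pair per residue, with a coarse physicochemical
class and a formal charge per residue. Real structures (PDB/mmCIF) are
reduced to this representation on read; synthetic protomers are built in it
directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("filapole")

__all__ = [
    "Protomer",
    "CLASSES",
    "classify_residue",
    "read_structure",
    "write_protomer",
    "write_filament_pdb",
    "write_table",
    "write_json",
    "FormatError",
    "EmptySelectionError",
    "ClassificationError",
]


class FormatError(ValueError):
    """File could not be parsed as PDB or mmCIF."""


class EmptySelectionError(ValueError):
    """Requested chain/selection contains no usable amino-acid residues."""


class ClassificationError(KeyError):
    """Unknown one-letter amino-acid code."""


#: residue class codes, in pair-matrix order
CLASSES = ("hydrophobic", "positive", "negative", "polar", "special")
CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}

# fixed default classification table: class and formal charge per residue.
# Histidine is grouped with the basic residues but carries no formal charge.
_CLASS_TABLE: dict[str, tuple[str, int]] = {}
for _aa in "AVLIMFW":
    _CLASS_TABLE[_aa] = ("hydrophobic", 0)
for _aa in "KR":
    _CLASS_TABLE[_aa] = ("positive", 1)
_CLASS_TABLE["H"] = ("positive", 0)
for _aa in "DE":
    _CLASS_TABLE[_aa] = ("negative", -1)
for _aa in "STNQCY":
    _CLASS_TABLE[_aa] = ("polar", 0)
for _aa in "GP":
    _CLASS_TABLE[_aa] = ("special", 0)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def classify_residue(aa: str) -> dict:
    """Class and formal charge of a one-letter amino-acid code.

    >>> classify_residue("K")
    {'cls': 'positive', 'charge': 1}
    """
    try:
        cls, charge = _CLASS_TABLE[aa.upper()]
    except KeyError:
        raise ClassificationError(f"unknown amino-acid code {aa!r}") from None
    return {"cls": cls, "charge": charge}


@dataclass
class Protomer:
    """Rigid residue-bead body: one CA and one CB bead per residue."""

    species_label: str
    aa: list[str]                 # one-letter codes, ordered
    ca: np.ndarray                # (n, 3) Angstrom
    cb: np.ndarray                # (n, 3) Angstrom; cb == ca for glycine
    indices: np.ndarray = field(default=None)  # 1-based residue indices

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float).reshape(-1, 3)
        self.cb = np.asarray(self.cb, dtype=float).reshape(-1, 3)
        n = len(self.aa)
        if self.ca.shape[0] != n or self.cb.shape[0] != n:
            raise ValueError("aa, ca and cb lengths must match")
        if self.indices is None:
            self.indices = np.arange(1, n + 1)
        else:
            self.indices = np.asarray(self.indices, dtype=int)
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("residue indices must be strictly increasing")
        self.classes = np.array(
            [CLASS_INDEX[_CLASS_TABLE[a][0]] for a in self.aa], dtype=int)
        self.charges = np.array(
            [_CLASS_TABLE[a][1] for a in self.aa], dtype=float)

    def __len__(self) -> int:
        return len(self.aa)

    @property
    def centroid(self) -> np.ndarray:
        return self.ca.mean(axis=0)

    def with_mutation(self, index: int, new_aa: str) -> "Protomer":
        """Copy with residue ``index`` (1-based) substituted.

        Coordinates are untouched: a substitution changes only the bead's
        class and charge (rigid model; sterics enter via the clash term).
        """
        if new_aa.upper() not in _CLASS_TABLE:
            raise ClassificationError(f"unknown amino-acid code {new_aa!r}")
        pos = int(np.where(self.indices == index)[0][0])
        aa = list(self.aa)
        aa[pos] = new_aa.upper()
        return Protomer(self.species_label, aa, self.ca.copy(),
                        self.cb.copy(), self.indices.copy())

    def with_species(self, label: str) -> "Protomer":
        return Protomer(label, list(self.aa), self.ca.copy(), self.cb.copy(),
                        self.indices.copy())


def _best_atom(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Highest-occupancy atom with the given name, resolving altlocs."""
    best = None
    for atom in residue:
        if atom.name == name and (best is None or atom.occ > best.occ):
            best = atom
    return best


def read_structure(path, chain_selector: str | None = None,
                   species_label: str | None = None,
                   res_range: tuple[int, int] | None = None) -> Protomer:
    """Read a PDB/mmCIF file into a single-chain residue-bead protomer.

    Insertion codes are collapsed into sequential indices, altlocs resolve to
    the highest-occupancy conformer, glycines get ``cb = ca``, and
    non-standard residues are skipped with a logged warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    model = st[0]
    chain = None
    if chain_selector is None:
        for cand in model:
            if any(r.name in _THREE_TO_ONE for r in cand):
                chain = cand
                break
    else:
        chain = model.find_chain(chain_selector)
    if chain is None:
        raise EmptySelectionError(
            f"chain {chain_selector!r} not found in {path.name}")

    aa, ca, cb = [], [], []
    for res in chain:
        seqid = res.seqid.num
        if res_range is not None and not (res_range[0] <= seqid <= res_range[1]):
            continue
        one = _THREE_TO_ONE.get(res.name)
        if one is None:
            if res.name not in ("HOH", "WAT"):
                logger.warning("skipping non-standard residue %s %s in %s",
                               res.name, res.seqid, path.name)
            continue
        ca_atom = _best_atom(res, "CA")
        if ca_atom is None:
            logger.warning("skipping residue %s %s without CA", res.name,
                           res.seqid)
            continue
        cb_atom = _best_atom(res, "CB")
        aa.append(one)
        ca.append([ca_atom.pos.x, ca_atom.pos.y, ca_atom.pos.z])
        pos = cb_atom.pos if cb_atom is not None else ca_atom.pos
        cb.append([pos.x, pos.y, pos.z])
    if not aa:
        raise EmptySelectionError(
            f"no amino-acid residues with CA in chain "
            f"{chain.name!r} of {path.name}")
    label = species_label or path.stem
    return Protomer(label, aa, np.array(ca), np.array(cb))


_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")


def _gemmi_structure(chains: list[tuple[str, Protomer, np.ndarray, np.ndarray]],
                     name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for chain_id, prot, ca, cb in chains:
        chain = gemmi.Chain(chain_id)
        for i, one in enumerate(prot.aa):
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE[one]
            res.seqid = gemmi.SeqId(int(prot.indices[i]), " ")
            for atom_name, xyz, elem in (("CA", ca[i], "C"), ("CB", cb[i], "C")):
                if atom_name == "CB" and one == "G":
                    continue
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(elem)
                # 3-decimal precision is the package-wide file convention
                atom.pos = gemmi.Position(*np.round(xyz, 3))
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_protomer(protomer: Protomer, path) -> None:
    """Write a single protomer as a one-chain PDB file."""
    st = _gemmi_structure([("A", protomer, protomer.ca, protomer.cb)],
                          protomer.species_label)
    st.write_pdb(str(path))


def write_filament_pdb(filament, path) -> None:
    """Write a filament model as a multi-chain PDB file (one chain per
    placed subunit, chain ids cycling A-Z a-z 0-9)."""
    chains = []
    for i, placement in enumerate(filament.placements):
        ca = placement.transform.apply(filament.protomer.ca)
        cb = placement.transform.apply(filament.protomer.cb)
        chains.append((_CHAIN_IDS[i % len(_CHAIN_IDS)], filament.protomer,
                       ca, cb))
    st = _gemmi_structure(chains, filament.protomer.species_label + "_filament")
    st.write_pdb(str(path))


def fetch_structure(pdb_id: str, dest_dir, timeout: float = 30.0) -> Path:
    """Download a deposited structure (mmCIF) from RCSB into ``dest_dir``.

    Returns the local path; reuses an existing download. Requires network
    access — callers analysing deposited filaments should handle the
    failure case explicitly.
    """
    import urllib.request
    pdb_id = pdb_id.lower()
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    out = dest_dir / f"{pdb_id}.cif"
    if out.exists():
        return out
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        out.write_bytes(resp.read())
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Serialize a result table to TSV with a one-line header."""
    if df.columns.duplicated().any():
        raise ValueError("column names must be unique")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
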