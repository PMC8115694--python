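"""In-silico saturation mutagenesis with dual-context ddG and selectivity
quadrant classification.

Every pocket residue that touches the ligand in any honeycomb subsection is
mutated to all 19 other amino acids, with the ligand kept wild type, in two
contexts: homotypic (ligand = filament species) and heterotypic (ligand =
partner species). The interaction energy of a context is the sum over all
six subsections of the ligand-pocket interface energy, and

    ddG = dG(mutant pocket) - dG(WT pocket)

so destabilizing mutations are positive. Mutations are classified into
selectivity quadrants by thresholding the (ddG_homo, ddG_hetero) pair:
mutations that disrupt self-assembly but spare partner recognition sit in
the homo-disrupting quadrant, and vice versa.

Because substitutions change only a bead's class and charge (coordinates and
hence the distance-switch matrix are untouched), ddG values are computed
exactly from precomputed switch matrices rather than by rescoring whole
complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import EnergyModel, PocketComplex, pocket_complex
from .helix import FilamentModel
from .io_model import CLASS_INDEX, Protomer, _CLASS_TABLE
from .lattice import Subsection

__all__ = [
    "DdgRecord",
    "SelectivityCall",
    "saturation_scan",
    "filter_outliers",
    "classify_selectivity",
    "selectivity_report",
    "calibrate_threshold",
    "recovery_metrics",
    "DEFAULT_THRESHOLD",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default quadrant threshold in package score units, sitting between the
#: score's sub-threshold noise (partial-switch cross terms, |ddG| <~ 3 on
#: the reference synthetic scenario) and the weakest designed signal there
#: (a lost charged contact summed over its honeycomb edges, |ddG| >~ 15).
#: The literature threshold of 10 applies to Rosetta units, not this score;
#: see calibrate_threshold for a data-driven alternative.
DEFAULT_THRESHOLD = 5.0

_CLASSES = ("homo_disrupting", "hetero_disrupting", "both", "neutral")


@dataclass
class DdgRecord:
    position: int          # 1-based residue index on the pocket protomer
    wt_aa: str
    mut_aa: str
    context: str           # 'homo' | 'hetero'
    pocket_id: str
    ddg: float
    raw_energy: float      # mutant-complex total energy (for outlier filter)


@dataclass
class SelectivityCall:
    position: int
    call: str
    counts: dict[str, int]     # mutations per class at this position
    n_mutations: int


class _ContextTables:
    """Switch/weight tables of all six subsections for one ligand species."""

    def __init__(self, filament: FilamentModel,
                 subsections: list[Subsection], model: EnergyModel,
                 ligand: Protomer | None):
        self.model = model
        prot = filament.protomer
        self.lig = ligand if ligand is not None else prot
        self.switches = []        # per subsection: (n_lig, n_pocket) S matrix
        self.pocket_res = []      # per subsection: residue index per column
        self.wt_energy = 0.0
        for sub in subsections:
            pc = pocket_complex(filament, sub, model, ligand)
            import scipy.spatial.distance as ssd
            d = ssd.cdist(pc.native_cb, pc.pocket_cb_all)
            s = model.switch(d)
            self.switches.append(s)
            self.pocket_res.append(np.tile(prot.indices,
                                           len(sub.pocket)))
            self.wt_energy += float(np.sum(pc.weights * s))
            if model.clash_penalty:
                self.wt_energy += model.clash_penalty * int(
                    np.count_nonzero(d < model.clash_d))

    def ddg(self, position: int, wt_aa: str, mut_aa: str) -> float:
        cw, qw = _CLASS_TABLE[wt_aa]
        cm, qm = _CLASS_TABLE[mut_aa]
        iw, im = CLASS_INDEX[cw], CLASS_INDEX[cm]
        eps = self.model.pair_matrix
        lc, lq = self.lig.classes, self.lig.charges
        dcol = (eps[lc, im] - eps[lc, iw]
                + self.model.w_elec * lq * (qm - qw))
        total = 0.0
        for s, res in zip(self.switches, self.pocket_res):
            cols = np.nonzero(res == position)[0]
            if cols.size:
                total += float(dcol @ s[:, cols].sum(axis=1))
        return total


def _interface_positions(tables: _ContextTables, protomer: Protomer
                         ) -> list[int]:
    hit = set()
    for s, res in zip(tables.switches, tables.pocket_res):
        touched = res[np.any(s > 0, axis=0)]
        hit.update(int(r) for r in touched)
    return sorted(hit)


def saturation_scan(filament: FilamentModel, subsections: list[Subsection],
                    model: EnergyModel,
                    contexts: dict[str, Protomer | None] | None = None,
                    positions: list[int] | None = None,
                    n_replicates: int = 1) -> list[DdgRecord]:
    """Scan every interface position x 19 substitutions x context.

    ``contexts`` maps context names to the ligand protomer placed at the
    honeycomb center (None = the filament's own species). Ligands stay wild
    type; the substitution is applied to all pocket protomers. Returns one
    record per (position, substitution, context) with the ddG summed over
    all six subsections. ``n_replicates`` averages repeated evaluations (a
    no-op for this deterministic model, kept for stochastic score plug-ins).
    """
    if contexts is None:
        contexts = {"homo": None}
    if len(subsections) != 6 or any(s.incomplete for s in subsections):
        raise ValueError("saturation_scan needs the six complete honeycomb "
                         "subsections of an interior center")
    prot = filament.protomer
    tables = {name: _ContextTables(filament, subsections, model, lig)
              for name, lig in contexts.items()}
    iface = _interface_positions(next(iter(tables.values())), prot)
    for tab in tables.values():
        iface = sorted(set(iface) | set(_interface_positions(tab, prot)))
    if positions is not None:
        requested = set(positions)
        skipped = requested - set(iface)
        if skipped:
            import logging
            logging.getLogger("filapole").warning(
                "positions not at any interface, skipped: %s",
                sorted(skipped))
        iface = [p for p in iface if p in requested]
    aa_of = {int(idx): aa for idx, aa in zip(prot.indices, prot.aa)}
    records: list[DdgRecord] = []
    for name, tab in tables.items():
        for pos in iface:
            wt = aa_of[pos]
            for mut in AMINO_ACIDS:
                if mut == wt:
                    continue
                vals = [tab.ddg(pos, wt, mut) for _ in range(n_replicates)]
                ddg = float(np.mean(vals))
                records.append(DdgRecord(
                    position=pos, wt_aa=wt, mut_aa=mut, context=name,
                    pocket_id="honeycomb", ddg=ddg,
                    raw_energy=tab.wt_energy + ddg))
    return records


def filter_outliers(records: list[DdgRecord], k: float = 2.0,
                    on: str = "raw_energy"
                    ) -> tuple[list[DdgRecord], list[DdgRecord]]:
    """Remove records whose score deviates from the scan mean by > k SD.

    ``on`` selects the filtered quantity: raw mutant-complex energies
    (default) or the ddG values themselves. Mean and SD are computed over
    the full scan before any removal; the removed list is returned for
    audit. With zero SD nothing is removed.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    vals = np.array([getattr(r, "raw_energy" if on == "raw_energy" else
                             "ddg") for r in records])
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    if sd == 0:
        return list(records), []
    keep, removed = [], []
    for r, v in zip(records, vals):
        (removed if abs(v - mean) >= k * sd else keep).append(r)
    return keep, removed


def classify_selectivity(ddg_homo: float, ddg_hetero: float,
                         threshold: float = DEFAULT_THRESHOLD) -> str:
    """Quadrant call for one mutation.

    homo_disrupting: disrupts self-assembly only (ddg_homo > T, hetero < T);
    hetero_disrupting: the reverse; both: deleterious for both (upper-right
    quadrant); neutral otherwise.
    """
    if not (np.isfinite(ddg_homo) and np.isfinite(ddg_hetero)):
        raise ValueError("ddG values must be finite")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hi_h = ddg_homo > threshold
    hi_x = ddg_hetero > threshold
    if hi_h and not hi_x:
        return "homo_disrupting"
    if hi_x and not hi_h:
        return "hetero_disrupting"
    if hi_h and hi_x:
        return "both"
    return "neutral"


def calibrate_threshold(records: list[DdgRecord],
                        neutral_positions: list[int] | None = None) -> float:
    """Threshold = 2 x median |ddG|, over designed-neutral positions when
    known, else over the whole scan.

    Raises when the rule degenerates (zero median: the neutral positions are
    exactly inert under the scoring model); use :data:`DEFAULT_THRESHOLD`
    in that case.
    """
    vals = [abs(r.ddg) for r in records
            if neutral_positions is None or r.position in neutral_positions]
    if not vals:
        raise ValueError("no records to calibrate on")
    t = 2.0 * float(np.median(vals))
    if t <= 0:
        raise ValueError("calibration degenerated to 0 (neutral positions "
                         "are exactly inert); use DEFAULT_THRESHOLD")
    return t


def selectivity_report(records: list[DdgRecord],
                       threshold: float = DEFAULT_THRESHOLD,
                       homo_context: str = "homo",
                       hetero_context: str = "hetero"
                       ) -> tuple[list[SelectivityCall], pd.DataFrame]:
    """Per-position selectivity calls plus the quadrant scatter table.

    Records are paired by (position, substitution) across the two contexts;
    unpaired records raise with the missing pairs listed. Each mutation gets
    a quadrant call; a position's call is the plurality class over its
    mutations, with ties going to neutral.
    """
    by_key: dict[tuple[int, str], dict[str, DdgRecord]] = {}
    for r in records:
        by_key.setdefault((r.position, r.mut_aa), {})[r.context] = r
    missing = [k for k, v in by_key.items()
               if homo_context not in v or hetero_context not in v]
    if missing:
        raise ValueError(f"unpaired records (position, mutation): "
                         f"{sorted(missing)[:10]}"
                         f"{' ...' if len(missing) > 10 else ''}")
    rows = []
    for (pos, mut), pair in sorted(by_key.items()):
        h = pair[homo_context].ddg
        x = pair[hetero_context].ddg
        rows.append({"position": pos, "wt_aa": pair[homo_context].wt_aa,
                     "mut_aa": mut, "ddg_homo": h, "ddg_hetero": x,
                     "call": classify_selectivity(h, x, threshold)})
    scatter = pd.DataFrame(rows)
    calls = []
    for pos, grp in scatter.groupby("position"):
        counts = {c: int((grp["call"] == c).sum()) for c in _CLASSES}
        best = max(counts, key=lambda c: (counts[c], c != "neutral"))
        # plurality with ties resolved to neutral
        top = counts[best]
        tied = [c for c in _CLASSES if counts[c] == top]
        call = best if len(tied) == 1 else "neutral"
        calls.append(SelectivityCall(position=int(pos), call=call,
                                     counts=counts, n_mutations=len(grp)))
    return calls, scatter


def recovery_metrics(calls: list[SelectivityCall],
                     true_positions: list[int], call_class: str
                     ) -> dict[str, float]:
    """Precision/recall of a designed position set against the calls."""
    predicted = {c.position for c in calls if c.call == call_class}
    truth = set(true_positions)
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0 if not truth else 0.0
    recall = tp / len(truth) if truth else 1.0
    return {"precision": precision, "recall": recall,
            "n_predicted": len(predicted), "n_true": len(truth)}
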