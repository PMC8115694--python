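"""Shared fixtures: synthetic scenarios assembled once per session."""

import pytest

from filapole.energetics import EnergyModel
from filapole.helix import build_filament
from filapole.lattice import classify_interfaces, contact_map, extract_pockets
from filapole.synthetic_data import make_scenario


def _assemble(goal, seed=0):
    sc = make_scenario(goal, seed=seed)
    fil = build_filament(sc["protomer_a"], sc["lattice"])
    edges = contact_map(fil, 8.0)
    classify_interfaces(edges)
    center = fil.index_of(fil.params.n_levels // 2, 0)
    subs = extract_pockets(fil, center, edges)
    return {"scenario": sc, "filament": fil, "edges": edges,
            "center": center, "subsections": subs}


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def hetero():
    """Polarized scenario: A filament with recognition arms, B ligand."""
    return _assemble("hetero_polarized")


@pytest.fixture(scope="session")
def homo():
    """Bidirectional scenario: arm-free A filament."""
    return _assemble("homo_bidirectional")


@pytest.fixture(scope="session")
def null_scenario():
    return _assemble("null")
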