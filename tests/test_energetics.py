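import numpy as np
import pytest
from scipy.stats import spearmanr

from filapole._geom import RigidTransform, random_rotation_matrix
from filapole.energetics import (EnergyModel, PocketComplex, local_dock,
                                 honeycomb_energy_table, interface_energy,
                                 pair_energy, pocket_complex)
from filapole.io_model import Protomer, classify_residue


def _res(aa, cb):
    info = classify_residue(aa)
    return {"cls": info["cls"], "charge": info["charge"],
            "cb": np.asarray(cb, dtype=float)}


def _mini_protomer(aa_and_cb, label="m"):
    aa = [a for a, _ in aa_and_cb]
    cb = np.array([c for _, c in aa_and_cb], dtype=float)
    return Protomer(label, aa, cb.copy(), cb)


@pytest.mark.parametrize("aa_i,aa_j,d,expected", [
    ("K", "E", 5.0, -2.5),        # salt bridge: -1.5 pair + (-1) elec
    ("K", "R", 5.0, +2.5),        # like-charge repulsion
    ("K", "E", 12.0, 0.0),        # beyond d_off
    ("L", "L", 5.0, -1.0),
    ("K", "E", 7.0, -1.25),       # linear switch midpoint
    ("G", "K", 5.0, 0.0),         # special class silent
])
def test_pair_energy_hand_values(aa_i, aa_j, d, expected):
    model = EnergyModel()
    e = pair_energy(_res(aa_i, [0, 0, 0]), _res(aa_j, [d, 0, 0]), model)
    assert e == pytest.approx(expected, abs=1e-12)


def test_pair_energy_clash_penalty():
    model = EnergyModel()
    e = pair_energy(_res("K", [0, 0, 0]), _res("E", [3.0, 0, 0]), model)
    assert e == pytest.approx(-2.5 + 2.0, abs=1e-12)


def test_interface_energy_matches_brute_force_double_loop(model):
    rng = np.random.default_rng(21)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(20):
        lig = _mini_protomer([(rng.choice(aas), rng.normal(scale=4, size=3))
                              for _ in range(6)])
        members = []
        for m in range(2):
            members.append(_mini_protomer(
                [(rng.choice(aas), rng.normal(scale=4, size=3) + [6, 0, 0])
                 for _ in range(5)]))
        pc = PocketComplex(lig, RigidTransform.identity(),
                           [(p, RigidTransform.identity()) for p in members],
                           model)
        got = interface_energy(pc)["energy"]
        expected = 0.0
        for i in range(len(lig)):
            ri = _res(lig.aa[i], lig.cb[i])
            for p in members:
                for j in range(len(p)):
                    expected += pair_energy(ri, _res(p.aa[j], p.cb[j]), model)
        assert got == pytest.approx(expected, abs=1e-9)


def test_separated_ligand_scores_zero_with_flag(model):
    lig = _mini_protomer([("K", [0, 0, 0])])
    far = _mini_protomer([("E", [50, 0, 0])])
    pc = PocketComplex(lig, RigidTransform.identity(),
                       [(far, RigidTransform.identity())], model)
    out = interface_energy(pc)
    assert out["energy"] == 0.0
    assert out["no_contact"]


def test_interface_energy_invariant_under_rigid_motion(hetero, model):
    fil = hetero["filament"]
    sub = hetero["subsections"][0]
    e0 = interface_energy(fil, sub, model)["energy"]
    rng = np.random.default_rng(4)
    moved = fil.transformed(RigidTransform(
        random_rotation_matrix(rng, angle_deg=77.0),
        np.array([-3.0, 9.0, 1.5])))
    e1 = interface_energy(moved, sub, model)["energy"]
    assert e1 == pytest.approx(e0, abs=1e-9)


def test_pair_energy_symmetric_in_exchange(model):
    a, b = _res("K", [0, 0, 0]), _res("Q", [4, 1, 0])
    assert pair_energy(a, b, model) == pair_energy(b, a, model)


def test_cognate_scores_better_than_charge_scrambled(homo, model):
    fil = homo["filament"]
    sub = homo["subsections"][0]
    cognate = interface_energy(fil, sub, model)["energy"]
    prot = homo["scenario"]["protomer_a"]
    scrambled = prot
    # swap charges on the 1a patch: K -> E breaks the designed salt bridges
    for i in prot.patch_index["1a"]:
        scrambled = scrambled.with_mutation(int(prot.indices[i]), "E")
    e_scr = interface_energy(fil, sub, model,
                             ligand_protomer=scrambled)["energy"]
    assert cognate < e_scr


def test_local_dock_null_perturbation_returns_native(homo, model):
    pc = pocket_complex(homo["filament"], homo["subsections"][0], model)
    samples = local_dock(pc, 5, sigma_rot=0.0, sigma_trans=0.0, seed=1,
                         greedy_iters=0)
    native = pc.energy(pc.native_cb)
    for s in samples:
        assert s.rmsd == pytest.approx(0.0, abs=1e-12)
        assert s.energy == pytest.approx(native, abs=1e-9)


def test_local_dock_reproducible_and_counts(homo, model):
    pc = pocket_complex(homo["filament"], homo["subsections"][1], model)
    a = local_dock(pc, 40, seed=123)
    b = local_dock(pc, 40, seed=123)
    assert len(a) == 40
    assert [s.energy for s in a] == [s.energy for s in b]
    assert [s.rmsd for s in a] == [s.rmsd for s in b]
    c = local_dock(pc, 40, seed=124)
    assert [s.energy for s in a] != [s.energy for s in c]


def test_local_dock_rejects_bad_sample_count(homo, model):
    pc = pocket_complex(homo["filament"], homo["subsections"][0], model)
    with pytest.raises(ValueError):
        local_dock(pc, 0)


def test_docking_funnel_on_cognate_interface(homo, model):
    pc = pocket_complex(homo["filament"], homo["subsections"][2], model)
    samples = local_dock(pc, 150, seed=9)
    en = np.array([s.energy for s in samples])
    rm = np.array([s.rmsd for s in samples])
    assert spearmanr(en, rm).statistic > 0.3
    # coarse translation grid scan: no pose in the local region beats the
    # docked minimum by more than the squeeze margin
    grid_best = np.inf
    for dx in np.arange(-3, 3.1, 1.0):
        for dy in np.arange(-3, 3.1, 1.0):
            for dz in np.arange(-3, 3.1, 1.0):
                grid_best = min(grid_best,
                                pc.energy(pc.native_cb + [dx, dy, dz]))
    assert en.min() <= grid_best + 1e-9


def test_homotypic_honeycomb_table_symmetric(homo, model):
    tab = honeycomb_energy_table(homo["filament"], homo["center"],
                                 homo["edges"], model)
    assert len(tab) == 6
    by_type = tab.groupby("type_id")["energy"].mean()
    assert by_type.idxmin() == 1          # type 1 contributes most
    top = tab[tab.half == "top"].energy.sum()
    bottom = tab[tab.half == "bottom"].energy.sum()
    assert top == pytest.approx(bottom, abs=1e-9)


def test_heterotypic_honeycomb_table_polarized(hetero, model):
    tab = honeycomb_energy_table(
        hetero["filament"], hetero["center"], hetero["edges"], model,
        center_protomer=hetero["scenario"]["protomer_b"])
    top = tab[tab.half == "top"].energy.sum()
    bottom = tab[tab.half == "bottom"].energy.sum()
    # B's down-facing arm binds the A subunit below it: the bottom half of
    # the B-centered honeycomb carries the favorable energy
    assert bottom < top
    assert bottom < 0


def test_empty_honeycomb_gives_empty_table(homo, model):
    tab = honeycomb_energy_table(homo["filament"], homo["center"], [], model)
    assert len(tab) == 0


def test_energy_model_validation():
    with pytest.raises(ValueError):
        EnergyModel(d_on=9.0, d_off=8.0)
    m = np.zeros((5, 5))
    m[0, 1] = 1.0
    with pytest.raises(ValueError):
        EnergyModel(pair_matrix=m)
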