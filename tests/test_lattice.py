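import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from filapole._geom import RigidTransform, random_rotation_matrix
from filapole.helix import HelicalParams, build_filament
from filapole.lattice import (ca_rmsd, classify_interfaces, contact_map,
                              end_surface_report, extract_pockets,
                              filament_diameters, surface_engagement)
from filapole.synthetic_data import make_toy_protomer


def _brute_force_edges(filament, cutoff):
    """Independent O(n^2) double loop over subunits and beads."""
    pairs = set()
    n = len(filament)
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(filament.cb(i), filament.cb(j))
            if (d < cutoff).any():
                pairs.add((i, j))
    return pairs


def test_single_subunit_has_no_contacts():
    prot = make_toy_protomer(seed=0)
    fil = build_filament(prot, HelicalParams(53.3, 14.0, cn=1, n_levels=1))
    assert contact_map(fil, 8.0) == []


def test_tiny_cutoff_yields_no_contacts(homo):
    assert contact_map(homo["filament"], 0.1) == []


def test_contact_map_matches_brute_force(homo):
    fil = homo["filament"]
    edges = contact_map(fil, 8.0)
    got = {tuple(sorted(e.pair)) for e in edges}
    assert got == {tuple(sorted(p))
                   for p in _brute_force_edges(fil, 8.0)}
    for e in edges:
        assert e.residue_pairs
        d_check = cdist(fil.cb(e.subunit_i), fil.cb(e.subunit_j))
        assert len(e.residue_pairs) == int((d_check < 8.0).sum())


def test_three_interface_clusters_at_filament_parameters(homo):
    labels = {e.pair: e.label for e in homo["edges"]}
    assert {l.type_id for l in labels.values()} == {1, 2, 3}


def test_degenerate_stack_clusters_with_warning():
    prot = make_toy_protomer(seed=0)
    fil = build_filament(prot, HelicalParams(53.3, 14.0, cn=1, n_levels=2))
    edges = contact_map(fil, 8.0)
    with pytest.warns(UserWarning, match="expected 3"):
        labels = classify_interfaces(edges)
    assert len({l.type_id for l in labels.values()}) == 1


def _union_find_partition(edges, rot_tol=5.0, trans_tol=2.0):
    """Exhaustive pairwise-agglomeration oracle (single linkage)."""
    n = len(edges)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            close = (abs(edges[i].rotation_deg - edges[j].rotation_deg)
                     <= rot_tol
                     and abs(edges[i].screw_offset
                             - edges[j].screw_offset) <= trans_tol)
            if close:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def test_cluster_partition_matches_agglomerative_oracle():
    prot = make_toy_protomer(seed=2)
    fil = build_filament(prot, HelicalParams(53.3, 14.0, cn=3, n_levels=10))
    assert len(fil) == 30
    edges = contact_map(fil, 8.0)
    classify_interfaces(edges)
    oracle = _union_find_partition(edges)
    # identical partitions: same type id <=> same oracle component
    for i in range(len(edges)):
        for j in range(i + 1, len(edges)):
            same_pkg = edges[i].label.type_id == edges[j].label.type_id
            assert same_pkg == (oracle[i] == oracle[j])


def test_classification_invariant_under_rigid_motion(homo):
    fil = homo["filament"]
    before = {e.pair: e.label.type_id for e in homo["edges"]}
    rng = np.random.default_rng(3)
    moved = fil.transformed(RigidTransform(
        random_rotation_matrix(rng, angle_deg=47.0),
        np.array([10.0, -4.0, 6.0])))
    edges = contact_map(moved, 8.0)
    labels = classify_interfaces(edges)
    # the partition (not the arbitrary ids or edge orientations) must match
    group = {}
    for pair, lab in labels.items():
        group.setdefault(lab.type_id, set()).add(frozenset(pair))
    group_before = {}
    for pair, tid in before.items():
        group_before.setdefault(tid, set()).add(frozenset(pair))
    assert sorted(map(frozenset, group.values()), key=sorted) \
        == sorted(map(frozenset, group_before.values()), key=sorted)


def test_side_assignment_consistent_within_cluster(homo):
    fil = homo["filament"]
    for e in homo["edges"]:
        zi = fil.centroid(e.subunit_i)[2]
        zj = fil.centroid(e.subunit_j)[2]
        assert zi <= zj
        assert (e.label.side_of_i, e.label.side_of_j) == ("a", "b")


def test_interior_center_yields_six_tagged_subsections(homo):
    subs = homo["subsections"]
    assert len(subs) == 6
    tags = [s.position_tag for s in subs]
    assert tags.count("top") == 3 and tags.count("bottom") == 3
    assert not any(s.incomplete for s in subs)


def test_every_pocket_member_contacts_the_ligand(homo):
    contact_pairs = {tuple(sorted(e.pair)) for e in homo["edges"]}
    for s in homo["subsections"]:
        for member in s.pocket:
            assert tuple(sorted((s.ligand, member))) in contact_pairs


def test_terminal_subunit_gives_incomplete_subsections(homo):
    fil = homo["filament"]
    corner = fil.index_of(0, 0)
    subs = extract_pockets(fil, corner, homo["edges"])
    assert subs and all(s.incomplete for s in subs)
    assert len(subs) < 6


def test_end_surfaces_complementary_and_interior_saturated(homo):
    fil = homo["filament"]
    report = end_surface_report(fil, homo["edges"])
    flip = {"1a": "1b", "1b": "1a", "2a": "2b", "2b": "2a",
            "3a": "3b", "3b": "3a"}
    assert sorted(flip[s] for s in report["top"]) == report["bottom"]
    # an interior subunit engages all six surfaces (periodic-like interior)
    engaged = surface_engagement(fil, homo["edges"])
    assert engaged[homo["center"]] == {"1a", "1b", "2a", "2b", "3a", "3b"}


def test_single_ring_exposes_axial_surfaces():
    prot = make_toy_protomer(seed=0)
    fil = build_filament(prot, HelicalParams(53.3, 14.0, cn=3, n_levels=1))
    edges = contact_map(fil, 8.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        classify_interfaces(edges)
    report = end_surface_report(fil, edges)
    for end in ("top", "bottom"):
        assert {"2a", "2b"} <= set(report[end])


def test_diameters_and_monomer_rmsd(homo):
    dia = filament_diameters(homo["filament"])
    assert dia["outer_diameter"] > dia["inner_diameter"] > 0
    prot = homo["scenario"]["protomer_a"]
    assert ca_rmsd(prot, prot) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(9)
    moved = RigidTransform(random_rotation_matrix(rng, angle_deg=30.0),
                           np.array([1.0, 2.0, 3.0]))
    import copy
    other = copy.deepcopy(prot)
    other.ca = moved.apply(prot.ca)
    assert ca_rmsd(prot, other) == pytest.approx(0.0, abs=1e-9)
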