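import numpy as np
import pytest

from filapole._geom import RigidTransform
from filapole.energetics import EnergyModel, PocketComplex
from filapole.io_model import Protomer
from filapole.mutscreen import (DdgRecord, classify_selectivity,
                                calibrate_threshold, filter_outliers,
                                recovery_metrics, saturation_scan,
                                selectivity_report)


def _one_bead(aa, cb, label="m"):
    cb = np.asarray([cb], dtype=float)
    return Protomer(label, [aa], cb.copy(), cb)


def _energy(lig, pocket, model):
    pc = PocketComplex(lig, RigidTransform.identity(),
                       [(pocket, RigidTransform.identity())], model)
    return pc.energy(pc.native_cb)


def test_hand_computed_ddg_for_charge_reversal():
    # pocket Lys in contact with ligand Glu; K->E:
    # (eps(-,-) + 1) - (eps(+,-) - 1) = 2.5 - (-2.5) = +5
    model = EnergyModel()
    lig = _one_bead("E", [0, 0, 0])
    wt = _one_bead("K", [5, 0, 0])
    mut = wt.with_mutation(1, "E")
    ddg = _energy(lig, mut, model) - _energy(lig, wt, model)
    assert ddg == pytest.approx(5.0, abs=1e-12)


def test_identity_substitution_has_zero_ddg():
    model = EnergyModel()
    lig = _one_bead("E", [0, 0, 0])
    wt = _one_bead("K", [5, 0, 0])
    same = wt.with_mutation(1, "K")
    assert _energy(lig, same, model) == _energy(lig, wt, model)


def test_ddg_additive_over_independent_contacts():
    # two pocket beads, each touching its own ligand bead and nothing else:
    # the double mutation's ddG is the sum of the single-site ddGs
    model = EnergyModel()
    lig = Protomer("l", ["E", "Q"],
                   np.array([[0.0, 0, 0], [30.0, 0, 0]]),
                   np.array([[0.0, 0, 0], [30.0, 0, 0]]))
    wt = Protomer("p", ["K", "N"],
                  np.array([[5.0, 0, 0], [35.0, 0, 0]]),
                  np.array([[5.0, 0, 0], [35.0, 0, 0]]))
    e_wt = _energy(lig, wt, model)
    d1 = _energy(lig, wt.with_mutation(1, "A"), model) - e_wt
    d2 = _energy(lig, wt.with_mutation(2, "A"), model) - e_wt
    both = wt.with_mutation(1, "A").with_mutation(2, "A")
    d12 = _energy(lig, both, model) - e_wt
    assert d12 == pytest.approx(d1 + d2, abs=1e-12)


def test_scan_produces_19_records_per_position_and_context(hetero, model):
    recs = saturation_scan(
        hetero["filament"], hetero["subsections"], model,
        contexts={"homo": None, "hetero": hetero["scenario"]["protomer_b"]})
    positions = {r.position for r in recs}
    for context in ("homo", "hetero"):
        for pos in positions:
            n = sum(1 for r in recs
                    if r.position == pos and r.context == context)
            assert n == 19
    assert len(recs) == len(positions) * 19 * 2


def test_scan_skips_non_interface_positions(hetero, model, caplog):
    prot = hetero["filament"].protomer
    core = int(prot.indices[0])          # buried glycine core bead
    recs = saturation_scan(hetero["filament"], hetero["subsections"], model,
                           contexts={"homo": None},
                           positions=[core])
    assert recs == []


def _fake_records(values, context="homo"):
    return [DdgRecord(position=i + 1, wt_aa="A", mut_aa="V", context=context,
                      pocket_id="honeycomb", ddg=v, raw_energy=v)
            for i, v in enumerate(values)]


def test_outlier_filter_zero_sd_removes_nothing():
    kept, removed = filter_outliers(_fake_records([3.0] * 6), k=2)
    assert len(kept) == 6 and removed == []


def test_outlier_filter_hand_case():
    kept, removed = filter_outliers(_fake_records([0, 0, 0, 0, 100.0]), k=2)
    assert [r.ddg for r in removed] == [100.0]
    assert len(kept) == 4


def test_outlier_filter_normal_tail_fraction():
    rng = np.random.default_rng(17)
    vals = rng.standard_normal(1000)
    kept, removed = filter_outliers(_fake_records(vals), k=2)
    frac = len(removed) / 1000
    # P(|z| > 2) = 4.55%; binomial(1000, .0455) 3-sigma band
    assert 0.026 < frac < 0.066


@pytest.mark.parametrize("h,x,expected", [
    (12.0, 3.0, "homo_disrupting"),
    (3.0, 12.0, "hetero_disrupting"),
    (15.0, 20.0, "both"),
    (0.0, 0.0, "neutral"),
    (-20.0, 2.0, "neutral"),
])
def test_quadrant_classification(h, x, expected):
    assert classify_selectivity(h, x, threshold=10.0) == expected


def test_selectivity_report_recovers_designed_positions(hetero, model):
    recs = saturation_scan(
        hetero["filament"], hetero["subsections"], model,
        contexts={"homo": None, "hetero": hetero["scenario"]["protomer_b"]})
    gt = hetero["scenario"]["ground_truth"]
    calls, scatter = selectivity_report(recs)
    homo_m = recovery_metrics(calls, gt["homo_critical_positions"],
                              "homo_disrupting")
    het_m = recovery_metrics(calls, gt["hetero_critical_positions"],
                             "hetero_disrupting")
    assert homo_m["precision"] == 1.0 and homo_m["recall"] == 1.0
    assert het_m["precision"] == 1.0 and het_m["recall"] == 1.0
    assert set(scatter.columns) >= {"position", "mut_aa", "ddg_homo",
                                    "ddg_hetero", "call"}


def test_selectivity_report_all_neutral_input():
    recs = (_fake_records([0.1] * 5, "homo")
            + _fake_records([0.2] * 5, "hetero"))
    calls, _ = selectivity_report(recs, threshold=5.0)
    assert all(c.call == "neutral" for c in calls)


def test_selectivity_report_rejects_unpaired_records():
    recs = _fake_records([1.0, 2.0], "homo")
    with pytest.raises(ValueError, match="unpaired"):
        selectivity_report(recs)


def test_calibration_rule_and_degenerate_guard():
    recs = (_fake_records([1.0, 2.0, 3.0, 4.0], "homo")
            + _fake_records([0.0] * 4, "hetero"))
    assert calibrate_threshold(recs[:4]) == pytest.approx(5.0)
    with pytest.raises(ValueError, match="degenerat"):
        calibrate_threshold(recs[4:])
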