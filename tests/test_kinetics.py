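import numpy as np
import pytest
from scipy.stats import spearmanr

from filapole.kinetics import (activity_ratio, analyze_plate,
                               fit_polymerization_curve, fret_ratio,
                               half_time_by_interpolation, holm_correction,
                               paired_t_test)
from filapole.synthetic_data import make_kinetics_dataset


def _sigmoid(t, t_half, rate=0.4, amp=1.0, y0=0.0):
    return y0 + amp / (1.0 + np.exp(-rate * (t - t_half)))


def test_noiseless_sigmoid_recovered_exactly():
    t = np.linspace(0, 100, 60)
    fit = fit_polymerization_curve(t, _sigmoid(t, 30.0))
    assert fit.t_half == pytest.approx(30.0, abs=1e-6)
    assert fit.apparent_rate == pytest.approx(1 / 30.0, abs=1e-8)
    assert not fit.no_polymerization


def test_noisy_sigmoid_recovered_within_five_percent():
    rng = np.random.default_rng(42)
    t = np.linspace(0, 100, 60)
    y = _sigmoid(t, 30.0) + rng.normal(0, 0.02, t.shape)
    fit = fit_polymerization_curve(t, y)
    assert abs(fit.t_half - 30.0) / 30.0 < 0.05


def test_flat_noisy_baseline_flagged():
    rng = np.random.default_rng(7)
    t = np.linspace(0, 100, 60)
    fit = fit_polymerization_curve(t, rng.normal(0, 0.02, t.shape))
    assert fit.no_polymerization
    assert fit.apparent_rate == 0.0


def test_fit_invariances_baseline_and_time_shift():
    t = np.linspace(0, 100, 60)
    y = _sigmoid(t, 40.0)
    base = fit_polymerization_curve(t, y)
    shifted = fit_polymerization_curve(t, y + 5.0)
    assert shifted.t_half == pytest.approx(base.t_half, abs=1e-6)
    assert shifted.baseline == pytest.approx(base.baseline + 5.0, abs=1e-6)
    later = fit_polymerization_curve(t + 10.0, y)
    assert later.t_half == pytest.approx(base.t_half + 10.0, abs=1e-6)


def test_fit_input_validation():
    t = np.linspace(0, 100, 60)
    with pytest.raises(ValueError):
        fit_polymerization_curve(t[:5], _sigmoid(t[:5], 30.0))
    bad = t.copy()
    bad[10] = bad[9]
    with pytest.raises(ValueError):
        fit_polymerization_curve(bad, _sigmoid(t, 30.0))


def test_interpolation_half_time_agrees_with_fit():
    t = np.linspace(0, 100, 201)
    th = half_time_by_interpolation(t, _sigmoid(t, 37.0), smooth=1)
    assert th == pytest.approx(37.0, abs=0.5)


def test_activity_ratio_endpoints_and_linearity():
    assert activity_ratio(0.05, 0.0, 0.05).value == 1.0
    assert activity_ratio(0.0, 0.0, 0.05).value == 0.0
    assert activity_ratio(0.025, 0.0, 0.05).value == pytest.approx(0.5)
    hyper = activity_ratio(0.08, 0.0, 0.05)
    assert hyper.out_of_range and hyper.value > 1


def test_activity_ratio_affine_invariant():
    a = activity_ratio(0.03, 0.01, 0.05).value
    b = activity_ratio(0.3, 0.1, 0.5).value
    assert a == pytest.approx(b, abs=1e-12)


def test_activity_ratio_undefined_normalization():
    with pytest.raises(ZeroDivisionError):
        activity_ratio(0.02, 0.05, 0.05)


def test_paired_t_identical_vectors():
    out = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert out["t_stat"] == 0.0 and out["p_value"] == 1.0


def test_paired_t_matches_hand_formula():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 3.0, 5.0, 6.0])
    out = paired_t_test(a, b)
    d = b - a
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert out["t_stat"] == pytest.approx(t_hand, abs=1e-12)
    assert out["df"] == 3
    assert 0 < out["p_value"] < 0.05


def test_paired_t_input_validation():
    with pytest.raises(ValueError):
        paired_t_test([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])


def test_paired_t_degenerate_constant_shift():
    out = paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert out["degenerate"] and out["p_value"] == 0.0


def test_holm_correction_monotone():
    p = [0.01, 0.04, 0.03, 0.9]
    adj = holm_correction(p)
    assert np.all(adj >= p)
    assert adj.max() <= 1.0


def test_fret_ratio_hand_cases():
    d = np.ones(5)
    assert np.allclose(fret_ratio(d, d), 0.5)
    assert np.allclose(fret_ratio(d, np.zeros(5)), 0.0)
    rng = np.random.default_rng(2)
    don = rng.uniform(0.5, 2, 20)
    acc = rng.uniform(0.5, 2, 20)
    assert np.allclose(fret_ratio(don, acc), acc / (don + acc))


def test_fret_ratio_masks_zero_denominator():
    out = fret_ratio(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
    assert not out.mask[0] and out.mask[1]


def test_plate_pipeline_recovers_designed_ratios():
    panel = [
        {"sample": "no_seed", "role": "none", "t_half": None},
        {"sample": "WT", "role": "wt", "t_half": 20.0},
        {"sample": "m_slow", "role": "mutant", "t_half": 60.0},
    ]
    plate, meta = make_kinetics_dataset(panel, noise_sd=0.02, seed=5)
    table = analyze_plate(plate, meta)
    per_sample = table.groupby("sample")["activity_ratio"].mean()
    assert per_sample["WT"] == pytest.approx(1.0, abs=1e-9)
    assert per_sample["no_seed"] == pytest.approx(0.0, abs=1e-9)
    assert per_sample["m_slow"] == pytest.approx(1 / 3, abs=0.05)


def test_rank_order_of_mutant_activities_preserved():
    designed = [25.0, 35.0, 50.0, 70.0, 90.0]
    panel = ([{"sample": "no_seed", "role": "none", "t_half": None},
              {"sample": "WT", "role": "wt", "t_half": 20.0}]
             + [{"sample": f"m{i}", "role": "mutant", "t_half": th}
                for i, th in enumerate(designed)])
    plate, meta = make_kinetics_dataset(panel, noise_sd=0.05, seed=8)
    table = analyze_plate(plate, meta)
    per = table.groupby("sample")["activity_ratio"].mean()
    got = [per[f"m{i}"] for i in range(len(designed))]
    rho = spearmanr(got, [-t for t in designed]).statistic
    assert rho > 0.9999
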