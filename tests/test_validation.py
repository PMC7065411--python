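"""Hold-out machinery: split rule, MSPE decomposition, St.-Pierre regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cowbw import (
    InputError,
    default_config,
    fit_mixed,
    mspe_decompose,
    simulate_herd,
    split_every_fifth,
    stpierre_regression,
    validate_model,
)


def _toy_records(n):
    return pd.DataFrame(
        {
            "cow_id": [f"AT{i:04d}" for i in range(n)],
            "day": np.full(n, 10),
        }
    )


def test_every_fifth_split_counts_small():
    est, val = split_every_fifth(_toy_records(10))
    assert (len(est), len(val)) == (8, 2)


def test_every_fifth_split_counts_study_size():
    """44 441 records split 35 553 / 8 888."""
    est, val = split_every_fifth(_toy_records(44441))
    assert (len(est), len(val)) == (35553, 8888)


def test_split_is_invariant_to_input_order():
    df = _toy_records(100)
    df["day"] = np.arange(100) % 7 + 1
    shuffled = df.sample(frac=1.0, random_state=3)
    est_a, val_a = split_every_fifth(df)
    est_b, val_b = split_every_fifth(shuffled)
    pd.testing.assert_frame_equal(val_a, val_b)
    pd.testing.assert_frame_equal(est_a, est_b)


def test_split_rejects_empty_input():
    with pytest.raises(InputError):
        split_every_fifth(_toy_records(0))


def test_perfect_prediction_decomposes_to_zero():
    p = np.array([600.0, 650.0, 700.0, 750.0])
    assert mspe_decompose(p, p) == (0.0, 0.0, 0.0, 0.0)


def test_pure_mean_shift_is_all_central_tendency():
    p = np.array([600.0, 650.0, 700.0, 750.0])
    mspe, ect, er, ed = mspe_decompose(p + 5.0, p)
    assert mspe == pytest.approx(25.0, abs=1e-12)
    assert ect == pytest.approx(25.0, abs=1e-12)
    assert er == pytest.approx(0.0, abs=1e-12)
    assert ed == pytest.approx(0.0, abs=1e-12)


def test_four_point_worked_example():
    """O=(1,2,3,6), P=(1,2,3,4): brute-force arithmetic on the formulas."""
    o = np.array([1.0, 2.0, 3.0, 6.0])
    p = np.array([1.0, 2.0, 3.0, 4.0])
    mspe, ect, er, ed = mspe_decompose(o, p)
    assert mspe == pytest.approx(1.0, abs=1e-12)
    assert ect == pytest.approx(0.25, abs=1e-12)
    s_o, s_p = o.std(), p.std()
    r = np.mean((o - o.mean()) * (p - p.mean())) / (s_o * s_p)
    assert er == pytest.approx((s_p - r * s_o) ** 2, abs=1e-12)
    assert ed == pytest.approx((1 - r**2) * s_o**2, abs=1e-12)
    assert ect + er + ed == pytest.approx(1.0, abs=1e-12)


def test_er_is_zero_when_observed_on_predicted_slope_is_one():
    """O = P + noise orthogonal to P has slope 1, hence ER = 0 exactly."""
    p = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1.0, -1.0, -1.0, 1.0])  # in-sample orthogonal to p
    o = p + e
    _, _, er, _ = mspe_decompose(o, p)
    assert er == pytest.approx(0.0, abs=1e-14)
    _, slope = stpierre_regression(o, p)
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_constant_predictions_rejected():
    with pytest.raises(InputError):
        mspe_decompose([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(InputError):
        stpierre_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(InputError):
        mspe_decompose([1.0, 2.0], [1.0, 2.0, 3.0])


@settings(deadline=None, max_examples=200)
@given(
    o=arrays(np.float64, 12, elements=st.floats(-1e3, 1e3)),
    p=arrays(np.float64, 12, elements=st.floats(-1e3, 1e3)),
)
def test_decomposition_identity_for_any_vectors(o, p):
    """ECT + ER + ED = MSPE to 1e-9 relative error for arbitrary input."""
    if p.std() < 1e-6:
        return
    mspe, ect, er, ed = mspe_decompose(o, p)
    assert ect + er + ed == pytest.approx(mspe, rel=1e-9, abs=1e-9)


@settings(deadline=None, max_examples=50)
@given(c=st.floats(0.1, 50.0))
def test_joint_scaling_is_quadratic(c):
    o = np.array([500.0, 620.0, 710.0, 680.0, 590.0])
    p = np.array([510.0, 600.0, 720.0, 660.0, 600.0])
    base = mspe_decompose(o, p)
    scaled = mspe_decompose(c * o, c * p)
    for a, b in zip(scaled, base):
        assert a == pytest.approx(c**2 * b, rel=1e-9)


def test_stpierre_closed_forms():
    p = np.array([600.0, 650.0, 700.0, 750.0])
    i, s = stpierre_regression(p, p)
    assert (i, s) == (pytest.approx(0.0, abs=1e-12), pytest.approx(0.0, abs=1e-12))
    i, s = stpierre_regression(p + 5.0, p)
    assert (i, s) == (pytest.approx(5.0), pytest.approx(0.0, abs=1e-12))
    i, s = stpierre_regression(1.2 * p, p)
    assert s == pytest.approx(0.2, rel=1e-9)
    assert i == pytest.approx(0.2 * p.mean(), rel=1e-9)


def test_noise_free_validation_gives_zero_mspe():
    cfg = default_config("hgbghw", n_records=1200, seed=13,
                         residual_sd=0.0, farm_sd=0.0)
    herd = simulate_herd(cfg)
    reports = validate_model(cfg.truth, herd)
    for rep in reports.values():
        assert rep.mspe == pytest.approx(0.0, abs=1e-12)


def test_prediction_shift_moves_ect_by_expansion():
    """ect(P+10) = (bias - 10)^2 expands as ect + 100 - 20*bias."""
    rng = np.random.default_rng(4)
    p = rng.normal(700.0, 50.0, 200)
    o = p + rng.normal(2.0, 10.0, 200)
    _, ect0, _, _ = mspe_decompose(o, p)
    _, ect1, _, _ = mspe_decompose(o, p + 10.0)
    bias = o.mean() - p.mean()
    assert ect1 == pytest.approx(ect0 + 100.0 - 20.0 * bias, rel=1e-9)


def test_periods_reported_separately_with_insufficient_flag():
    cfg = default_config("hgbghw", n_records=300, seed=2, dry_fraction=0.0)
    herd = simulate_herd(cfg)
    reports = validate_model(cfg.truth, herd)
    assert not reports["lactation"].insufficient
    assert reports["dry"].insufficient and reports["dry"].n == 0


def test_report_percentages_sum_to_100(small_herd, eq2_spec):
    est, val = split_every_fifth(small_herd)
    fit = fit_mixed(est, eq2_spec)
    reports = validate_model(fit.coefficients, val)
    for rep in reports.values():
        assert rep.ect_pct + rep.er_pct + rep.ed_pct == pytest.approx(100.0, abs=1e-6)
        assert rep.rmspe == pytest.approx(np.sqrt(rep.mspe), rel=1e-12)
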