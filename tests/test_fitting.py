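"""Estimation pipeline: recovery, LSMs, stage curves, assembly, stepwise."""

import numpy as np
import pandas as pd
import pytest

from cowbw import (
    FitError,
    InputError,
    ModelSpec,
    assemble_prediction_model,
    default_config,
    fit_mixed,
    fit_stage_curves,
    packaged_model,
    simulate_herd,
    stage_lsm,
)
from cowbw.fit import REFERENCE_STAGE, STAGE_CLASSES, design_matrix
from cowbw.model import stage_class_midpoints, stage_effect


@pytest.fixture(scope="module")
def noiseless_fit(noiseless_herd, eq2_spec):
    return fit_mixed(noiseless_herd, eq2_spec)


def test_noiseless_slopes_and_effects_recovered_exactly(noiseless_fit):
    """Zero residual and farm SD: every identified coefficient to <=1e-6."""
    truth = packaged_model("hgbghw")
    c = noiseless_fit.coefficients
    for m in ("HG", "BG", "HW"):
        assert c.pooled_slope[m] == pytest.approx(truth.pooled_slope[m], abs=1e-6)
        for g in truth.genotype_slope[m]:
            assert c.genotype_slope[m][g] == pytest.approx(
                truth.genotype_slope[m][g], abs=1e-6
            )
    for g, v in truth.genotype_effect.items():
        assert c.genotype_effect[g] == pytest.approx(v, abs=1e-6)
    for p, v in truth.parity_effect.items():
        assert c.parity_effect[p] == pytest.approx(v, abs=1e-6)
    assert noiseless_fit.farm_variance == 0.0
    assert noiseless_fit.rmse < 1e-6


def test_noiseless_prediction_function_recovered(noiseless_fit):
    """intercept + stage curve reproduces the generating equation at every day.

    Only the sum of intercept and curve constant is identified, so the
    recovery check is on the full prediction function.
    """
    truth = packaged_model("hgbghw")
    c = noiseless_fit.coefficients
    for day in list(range(1, 365)) + list(range(-56, 0)):
        period = "lactation" if day >= 1 else "dry"
        got = c.intercept + stage_effect(day, period, c)
        want = truth.intercept + stage_effect(day, period, truth)
        assert got == pytest.approx(want, abs=1e-6)


def test_noiseless_stage_lsm_differences_match_truth(noiseless_fit):
    """LSM contrasts between stage classes equal truth-curve contrasts."""
    truth = packaged_model("hgbghw")
    mids = stage_class_midpoints()
    lsm = noiseless_fit.stage_lsm

    # evaluate the truth polynomial at the exact (half-integer) midpoints
    def curve(day):
        c = truth.lactation_curve if day >= 1 else truth.dry_curve
        return float(np.polynomial.polynomial.polyval(day, c))

    for s in STAGE_CLASSES:
        got = lsm[s] - lsm[REFERENCE_STAGE]
        want = curve(mids[s]) - curve(mids[REFERENCE_STAGE])
        assert got == pytest.approx(want, abs=1e-6)


def test_rmse_equals_sqrt_residual_variance(small_herd, eq2_spec):
    fit = fit_mixed(small_herd, eq2_spec)
    assert fit.rmse == pytest.approx(np.sqrt(fit.residual_variance), rel=1e-12)
    assert fit.farm_variance >= 0.0
    assert len(fit.stage_lsm) == 17


def test_lsm_translation_equivariance(small_herd, eq2_spec):
    """Adding a constant to every observed weight shifts every LSM by it."""
    fit = fit_mixed(small_herd, eq2_spec)
    shifted = small_herd.df.copy()
    shifted["bw_observed"] = shifted["bw_observed"] + 50.0
    fit2 = fit_mixed(shifted, eq2_spec)
    for s in STAGE_CLASSES:
        assert fit2.stage_lsm[s] - fit.stage_lsm[s] == pytest.approx(50.0, abs=1e-4)


def test_stage_lsm_recomputes_covariate_means(small_herd, eq2_spec):
    fit = fit_mixed(small_herd, eq2_spec)
    again = stage_lsm(fit)
    assert again == fit.stage_lsm
    other = stage_lsm(fit, small_herd.df.head(1000))
    assert other != fit.stage_lsm  # different covariate means shift the scale


def test_stage_curve_degree4_exact_interpolation():
    """LSMs generated from a quartic at the 13 midpoints are fit exactly."""
    truth_c = np.array([12.0, -0.3, 2.3e-3, -5.7e-6, 4.7e-9])
    mids = stage_class_midpoints()
    lsm = {
        ("lactation", k): float(
            np.polynomial.polynomial.polyval(mids[("lactation", k)], truth_c)
        )
        for k in range(1, 14)
    }
    lact, dry, rmse = fit_stage_curves(lsm)
    assert dry is None
    assert np.allclose(lact, truth_c, atol=1e-8)
    assert rmse["lactation"] == pytest.approx(0.0, abs=1e-9)


def test_dry_curve_closed_form_regression():
    """Four points (4,8,12,16) at days (-49,-35,-21,-7): slope 2/7, intercept 18."""
    lsm = {("dry", k): v for k, v in zip(range(1, 5), (4.0, 8.0, 12.0, 16.0))}
    _, dry, rmse = fit_stage_curves(lsm, dry_days=(-49, -35, -21, -7))
    assert dry[1] == pytest.approx(2.0 / 7.0, rel=1e-12)
    assert dry[0] == pytest.approx(18.0, rel=1e-12)
    assert rmse["dry"] == pytest.approx(0.0, abs=1e-12)


def test_constant_lsms_yield_constant_curves():
    lsm = {("lactation", k): 7.5 for k in range(1, 14)}
    lsm.update({("dry", k): 7.5 for k in range(1, 5)})
    lact, dry, _ = fit_stage_curves(lsm)
    assert lact[0] == pytest.approx(7.5, abs=1e-8)
    assert np.allclose(lact[1:], 0.0, atol=1e-9)
    assert dry[0] == pytest.approx(7.5, abs=1e-10)
    assert dry[1] == pytest.approx(0.0, abs=1e-10)


def test_too_few_stage_means_rejected():
    lsm = {("lactation", k): 1.0 * k for k in range(1, 4)}
    with pytest.raises(FitError):
        fit_stage_curves(lsm)


def test_assembled_model_matches_categorical_within_curve_rmse(small_herd, eq2_spec):
    """At class representative days the assembled model reproduces the
    categorical model up to the curve-fit residual (mean gap <= max RMSE)."""
    fit = fit_mixed(small_herd, eq2_spec)
    df = small_herd.df
    X, names = design_matrix(df, eq2_spec)
    beta = np.array([fit.fe_params[n] for n in names])
    categorical = X @ beta
    from cowbw.model import predict_frame, stage_class_midpoints, stage_from_day

    mids = stage_class_midpoints()
    at_mid = df.copy()
    at_mid["day"] = [
        mids[(s.period, s.class_index)]
        for s in (stage_from_day(int(d)) for d in df["day"])
    ]
    assembled = predict_frame(at_mid, fit.coefficients)
    gap = np.abs(assembled - categorical).mean()
    assert gap <= max(fit.curve_rmse.values()) + 1e-9
    # per class the gap is exactly that class's curve residual
    per_class = pd.DataFrame(
        {"cls": at_mid["day"], "gap": np.abs(assembled - categorical)}
    ).groupby("cls")["gap"].std()
    assert (per_class.fillna(0.0) < 1e-9).all()


def test_assembled_coefficients_pass_reference_invariants(small_herd, eq2_spec):
    fit = fit_mixed(small_herd, eq2_spec)
    c = fit.coefficients
    assert c.genotype_effect["BS"] == 0.0
    assert c.parity_effect["P5plus"] == 0.0
    assert all(c.genotype_slope[m]["BS"] == 0.0 for m in c.model_spec)
    c.validate()


def test_quadratic_spec_cannot_be_assembled(small_herd):
    spec = ModelSpec(("HG",), quadratic=True)
    fit = fit_mixed(small_herd, spec)
    assert fit.coefficients is None
    with pytest.raises(InputError):
        assemble_prediction_model(fit)


def test_stepwise_ranking_prefers_girth_and_nested_gains(small_herd):
    """RMSE strictly decreases HG -> HG+BG -> HG+BG+HW; HG beats ST."""
    from cowbw import stepwise_evaluate

    candidates = [
        ModelSpec(("ST",)),
        ModelSpec(("HG",)),
        ModelSpec(("HG", "BG")),
        ModelSpec(("HG", "BG", "HW")),
    ]
    ranking = stepwise_evaluate(small_herd, candidates)
    labels = [e["spec"].label for e in ranking]
    assert labels[0] == "HGBGHW"
    rmse = {e["spec"].label: e["rmse"] for e in ranking}
    assert rmse["HGBGHW"] < rmse["HGBG"] < rmse["HG"] < rmse["ST"]


def test_single_candidate_ranking(small_herd):
    from cowbw import stepwise_evaluate

    ranking = stepwise_evaluate(small_herd, [ModelSpec(("HG",))])
    assert len(ranking) == 1 and ranking[0]["error"] is None


def test_missing_genotype_class_is_named(small_herd, eq2_spec):
    df = small_herd.df[small_herd.df.genotype != "HF"]
    with pytest.raises(FitError, match="HF"):
        fit_mixed(df, eq2_spec)


def test_fit_result_serializes(tmp_path, small_herd, eq2_spec):
    fit = fit_mixed(small_herd, eq2_spec)
    path = tmp_path / "fit.yaml"
    fit.save(path, provenance={"seed": 7})
    import yaml

    doc = yaml.safe_load(path.read_text())
    assert doc["provenance"]["seed"] == 7
    assert doc["rmse"] == pytest.approx(fit.rmse)
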