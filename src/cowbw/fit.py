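"""Estimation of body-weight prediction equations from weighing records.

The pipeline mirrors standard livestock-morphometrics practice:

1. a linear mixed model of observed weight on genotype, parity,
   physiological-stage class, body-measurement regressions (pooled and,
   optionally, genotype-specific) and a random farm intercept, estimated by
   REML;
2. least-squares means (LSMs) of the 17 physiological-stage classes at
   equal fixed-effect class weights and grand-mean covariates;
3. per-period polynomial curves (degree 4 in DIM during lactation, linear
   in the dry period) fitted to the stage LSMs by ordinary least squares,
   giving a continuous stage term;
4. assembly into a :class:`~cowbw.model.CoefficientSet` whose intercept is
   re-centred so that predictions at a stage class's representative day
   match the categorical model's predictions up to the curve-fit residual.

Reference coding throughout: Brown Swiss, parity >=5 and the first
lactation month carry zero effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import FitError, InputError
from .model import (
    GENOTYPES,
    MEASUREMENTS,
    PARITY_CLASSES,
    REFERENCE_GENOTYPE,
    REFERENCE_PARITY,
    CoefficientSet,
    classify_parity,
    stage_class_midpoints,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_mixed",
    "stepwise_evaluate",
    "stage_lsm",
    "fit_stage_curves",
    "assemble_prediction_model",
]

#: Stage classes in fixed order; the first lactation month is the baseline.
STAGE_CLASSES: tuple[tuple[str, int], ...] = tuple(
    [("lactation", k) for k in range(1, 14)] + [("dry", k) for k in range(1, 5)]
)
REFERENCE_STAGE = ("lactation", 1)

_NONREF_GENOTYPES = tuple(g for g in GENOTYPES if g != REFERENCE_GENOTYPE)
_NONREF_PARITIES = tuple(p for p in PARITY_CLASSES if p != REFERENCE_PARITY)

# Noise floor (kg) below which the REML problem is singular and the exact
# least-squares solution is returned with zero variance components.
_NOISELESS_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Which measurements enter the equation and in what functional form."""

    measurements: tuple[str, ...]
    genotype_specific: bool = False
    quadratic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if not self.measurements:
            raise InputError("model spec needs at least one measurement")
        if len(set(self.measurements)) != len(self.measurements):
            raise InputError("duplicate measurements in model spec")
        unknown = [m for m in self.measurements if m not in MEASUREMENTS]
        if unknown:
            raise InputError(f"unknown measurement(s): {', '.join(unknown)}")

    @property
    def label(self) -> str:
        return "".join(self.measurements)


@dataclass
class FitResult:
    """A fitted equation plus everything needed to audit and reuse it."""

    coefficients: CoefficientSet
    farm_variance: float
    residual_variance: float
    rmse: float
    aic: float
    stage_lsm: dict[tuple[str, int], float]
    curve_rmse: dict[str, float]
    n_records: int
    spec: ModelSpec
    fe_params: dict[str, float]
    covariate_means: dict[str, float]
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "farm_variance": float(self.farm_variance),
            "residual_variance": float(self.residual_variance),
            "rmse": float(self.rmse),
            "aic": float(self.aic),
            "stage_lsm": {f"{p}_{k}": float(v) for (p, k), v in self.stage_lsm.items()},
            "curve_rmse": {k: float(v) for k, v in self.curve_rmse.items()},
            "n_records": int(self.n_records),
            "spec": {
                "measurements": list(self.spec.measurements),
                "genotype_specific": self.spec.genotype_specific,
                "quadratic": self.spec.quadratic,
            },
            "fe_params": {k: float(v) for k, v in self.fe_params.items()},
            "covariate_means": {k: float(v) for k, v in self.covariate_means.items()},
            "converged": bool(self.converged),
        }

    def save(self, path, provenance: Mapping | None = None) -> None:
        doc = self.to_dict()
        if provenance:
            doc["provenance"] = dict(provenance)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _stage_labels(day: np.ndarray) -> list[tuple[str, int]]:
    lact = day >= 1
    idx = np.where(lact, (day - 1) // 28 + 1, (day + 56) // 14 + 1).astype(int)
    return [("lactation", i) if l else ("dry", i) for l, i in zip(lact, idx)]


def _check_classes(df: pd.DataFrame, stages: list[tuple[str, int]]) -> None:
    missing = [g for g in GENOTYPES if g not in set(df["genotype"])]
    if missing:
        raise FitError(f"empty genotype class(es): {', '.join(missing)}")
    present_par = set(df["parity"].map(classify_parity))
    missing = [p for p in PARITY_CLASSES if p not in present_par]
    if missing:
        raise FitError(f"empty parity class(es): {', '.join(missing)}")
    present_st = set(stages)
    missing_st = [s for s in STAGE_CLASSES if s not in present_st]
    if missing_st:
        names = ", ".join(f"{p} {k}" for p, k in missing_st)
        raise FitError(f"empty physiological-stage class(es): {names}")


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Reference-coded fixed-effects design matrix and column names."""
    for m in spec.measurements:
        if m not in df.columns:
            raise FitError(f"records lack measurement column {m}")
        if df[m].isna().any():
            raise FitError(f"measurement {m} has missing values")
    n = len(df)
    stages = _stage_labels(df["day"].to_numpy(dtype=float))
    geno = df["genotype"].to_numpy()
    par = df["parity"].map(classify_parity).to_numpy()

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    for g in _NONREF_GENOTYPES:
        cols.append((geno == g).astype(float))
        names.append(f"G[{g}]")
    for p in _NONREF_PARITIES:
        cols.append((par == p).astype(float))
        names.append(f"P[{p}]")
    stage_arr = np.array([f"{p}_{k}" for p, k in stages])
    for s in STAGE_CLASSES:
        if s == REFERENCE_STAGE:
            continue
        cols.append((stage_arr == f"{s[0]}_{s[1]}").astype(float))
        names.append(f"PS[{s[0]}_{s[1]}]")
    for m in spec.measurements:
        cols.append(df[m].to_numpy(dtype=float))
        names.append(f"b[{m}]")
    if spec.genotype_specific:
        for m in spec.measurements:
            x = df[m].to_numpy(dtype=float)
            for g in _NONREF_GENOTYPES:
                cols.append(x * (geno == g))
                names.append(f"b[{m}:{g}]")
    if spec.quadratic:
        for m in spec.measurements:
            cols.append(df[m].to_numpy(dtype=float) ** 2)
            names.append(f"b2[{m}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit_mixed(records, spec: ModelSpec, reml: bool = True) -> FitResult:
    """REML fit of the mixed model with a random farm intercept.

    With noise-free input (zero empirical residual variance) the REML
    problem is singular; the exact ordinary-least-squares solution is then
    returned with zero variance components.
    """
    df = records.df if hasattr(records, "df") else records
    if df["farm_id"].nunique() < 2:
        raise FitError("at least two farms are required to separate farm variance")
    stages = _stage_labels(df["day"].to_numpy(dtype=float))
    _check_classes(df, stages)

    X, names = design_matrix(df, spec)
    y = df["bw_observed"].to_numpy(dtype=float)

    beta_ols, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            "check for collinear measurements"
        )
    resid = y - X @ beta_ols
    ols_sd = float(np.sqrt(np.mean(resid**2)))

    if ols_sd < _NOISELESS_TOL:
        fe = dict(zip(names, beta_ols))
        farm_var, resid_var, aic, converged = 0.0, ols_sd**2, float("nan"), True
    else:
        model = MixedLM(y, X, groups=df["farm_id"].to_numpy())
        result, failures = None, []
        # the default gradient optimizer occasionally stalls on flat
        # profiles; fall back to gradient-free optimizers before giving up
        for method in (None, "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    candidate = (
                        model.fit(reml=reml) if method is None
                        else model.fit(reml=reml, method=method)
                    )
            except Exception as exc:
                failures.append(f"{method or 'default'}: {exc}")
                continue
            if candidate.converged:
                result = candidate
                break
            failures.append(f"{method or 'default'}: not converged")
        if result is None:
            raise FitError(
                "REML estimation did not converge; attempts: "
                + "; ".join(failures)
            )
        fe = dict(zip(names, np.asarray(result.fe_params)))
        farm_var = float(np.asarray(result.cov_re)[0, 0])
        resid_var = float(result.scale)
        k_par = X.shape[1] + 2  # fixed effects + farm and residual variances
        aic = float(-2.0 * result.llf + 2.0 * k_par)
        converged = bool(result.converged)

    covariate_means = {m: float(df[m].mean()) for m in spec.measurements}
    if spec.quadratic:
        covariate_means.update(
            {f"{m}^2": float((df[m] ** 2).mean()) for m in spec.measurements}
        )

    lsm = _lsm_from_params(fe, spec, covariate_means)
    lact_curve, dry_curve, curve_rmse = fit_stage_curves(lsm)
    fit = FitResult(
        coefficients=None,  # filled by assemble below
        farm_variance=farm_var,
        residual_variance=resid_var,
        rmse=float(np.sqrt(resid_var)),
        aic=aic,
        stage_lsm=lsm,
        curve_rmse=curve_rmse,
        n_records=len(df),
        spec=spec,
        fe_params=fe,
        covariate_means=covariate_means,
        converged=converged,
    )
    fit._curves = (lact_curve, dry_curve)
    if not spec.quadratic:
        fit.coefficients = assemble_prediction_model(fit)
    return fit


def stepwise_evaluate(records, candidates: Sequence[ModelSpec]) -> list[dict]:
    """Fit each candidate spec and rank by RMSE (ties: fewer measurements).

    Failed fits are recorded with their error message and ranked last.
    """
    entries = []
    for spec in candidates:
        try:
            fit = fit_mixed(records, spec)
            entries.append(
                {"spec": spec, "rmse": fit.rmse, "aic": fit.aic, "fit": fit,
                 "error": None}
            )
        except FitError as exc:
            entries.append(
                {"spec": spec, "rmse": float("inf"), "aic": float("inf"),
                 "fit": None, "error": str(exc)}
            )
    entries.sort(key=lambda e: (e["rmse"], len(e["spec"].measurements)))
    return entries


# ---------------------------------------------------------------------------
# stage LSMs and curves
# ---------------------------------------------------------------------------

def _lsm_from_params(fe: Mapping[str, float], spec: ModelSpec,
                     covariate_means: Mapping[str, float]) -> dict:
    """Stage-class LSMs: equal class weights, covariates at grand means.

    Matches the usual mixed-procedure convention: every genotype class gets
    weight 1/5 and every parity class 1/4 (so covariate-by-genotype columns
    enter at grand mean / 5), covariates sit at their overall means, and
    the farm effect is zero.
    """
    base = fe["Intercept"]
    base += sum(fe[f"G[{g}]"] for g in _NONREF_GENOTYPES) / len(GENOTYPES)
    base += sum(fe[f"P[{p}]"] for p in _NONREF_PARITIES) / len(PARITY_CLASSES)
    for m in spec.measurements:
        base += covariate_means[m] * fe[f"b[{m}]"]
        if spec.genotype_specific:
            base += sum(
                fe[f"b[{m}:{g}]"] for g in _NONREF_GENOTYPES
            ) * covariate_means[m] / len(GENOTYPES)
        if spec.quadratic:
            base += covariate_means[f"{m}^2"] * fe[f"b2[{m}]"]
    out = {}
    for s in STAGE_CLASSES:
        effect = 0.0 if s == REFERENCE_STAGE else fe[f"PS[{s[0]}_{s[1]}]"]
        out[s] = base + effect
    return out


def stage_lsm(fit: FitResult, records=None) -> dict[tuple[str, int], float]:
    """Least-squares mean of each of the 17 stage classes.

    If ``records`` is given, covariate grand means are recomputed from it;
    otherwise the means stored at fit time are used.
    """
    means = dict(fit.covariate_means)
    if records is not None:
        df = records.df if hasattr(records, "df") else records
        means.update({m: float(df[m].mean()) for m in fit.spec.measurements})
        if fit.spec.quadratic:
            means.update(
                {f"{m}^2": float((df[m] ** 2).mean()) for m in fit.spec.measurements}
            )
    return _lsm_from_params(fit.fe_params, fit.spec, means)


def _polyfit_scaled(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares polynomial in ascending powers, fit on x/100 for
    conditioning and rescaled back exactly."""
    t = np.asarray(x, dtype=float) / 100.0
    c = np.polynomial.polynomial.polyfit(t, np.asarray(y, dtype=float), degree)
    return c / (100.0 ** np.arange(degree + 1))


def fit_stage_curves(
    lsm: Mapping[tuple[str, int], float],
    lactation_days: Sequence[float] | None = None,
    dry_days: Sequence[float] | None = None,
):
    """OLS stage curves through the (representative day, LSM) points.

    Degree 4 for lactation, degree 1 for the dry period.  Representative
    days default to the stage-class midpoints (DIM 14.5, 42.5, ..., 350.5;
    dry -49.5, -35.5, -21.5, -7.5).  Returns ascending-power coefficient
    tuples and the per-period root-mean-square curve residual.
    """
    mid = stage_class_midpoints()
    curves: dict[str, np.ndarray | None] = {"lactation": None, "dry": None}
    curve_rmse: dict[str, float] = {}
    for period, degree, days_arg in (
        ("lactation", 4, lactation_days),
        ("dry", 1, dry_days),
    ):
        items = sorted(
            ((k, v) for k, v in lsm.items() if k[0] == period),
            key=lambda kv: kv[0][1],
        )
        if not items:
            continue
        y = np.array([v for _, v in items], dtype=float)
        if days_arg is not None:
            x = np.asarray(days_arg, dtype=float)
            if len(x) != len(y):
                raise FitError(
                    f"{period}: {len(x)} abscissae given for {len(y)} LSM values"
                )
        else:
            x = np.array([mid[k] for k, _ in items])
        if len(y) < degree + 1:
            raise FitError(
                f"{period}: need at least {degree + 1} stage means to fit a "
                f"degree-{degree} curve, got {len(y)}"
            )
        c = _polyfit_scaled(x, y, degree)
        fitted = np.polynomial.polynomial.polyval(x, c)
        curves[period] = c
        curve_rmse[period] = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return curves["lactation"], curves["dry"], curve_rmse


def assemble_prediction_model(fit: FitResult) -> CoefficientSet:
    """Swap categorical stage effects for the fitted per-period curves.

    The curves are fitted to the stage LSMs, which sit on the scale
    "intercept + average class effects + grand-mean covariate term".  That
    constant ``C`` is subtracted from the fitted intercept so that
    ``intercept + curve(day)`` reproduces the categorical model's
    ``intercept + stage effect`` at each class's representative day up to
    the curve-fit residual.  Only the sum is identified; the split between
    intercept and curve constants follows this LSM convention.
    """
    if fit.spec.quadratic:
        raise InputError(
            "quadratic specs are evaluation-only and cannot be assembled "
            "into a CoefficientSet"
        )
    fe = fit.fe_params
    if hasattr(fit, "_curves"):
        lact_curve, dry_curve = fit._curves
    else:
        lact_curve, dry_curve, _ = fit_stage_curves(fit.stage_lsm)
    if lact_curve is None or dry_curve is None:
        raise FitError("both lactation and dry stage curves are required")

    lsm_const = fit.stage_lsm[REFERENCE_STAGE]  # = C (reference effect is 0)
    intercept = fe["Intercept"] - lsm_const

    genotype_effect = {g: float(fe[f"G[{g}]"]) for g in _NONREF_GENOTYPES}
    genotype_effect[REFERENCE_GENOTYPE] = 0.0
    parity_effect = {p: float(fe[f"P[{p}]"]) for p in _NONREF_PARITIES}
    parity_effect[REFERENCE_PARITY] = 0.0
    pooled_slope = {m: float(fe[f"b[{m}]"]) for m in fit.spec.measurements}
    genotype_slope: dict[str, dict[str, float]] = {}
    for m in fit.spec.measurements:
        if fit.spec.genotype_specific:
            genotype_slope[m] = {
                g: float(fe[f"b[{m}:{g}]"]) for g in _NONREF_GENOTYPES
            }
        else:
            genotype_slope[m] = {g: 0.0 for g in _NONREF_GENOTYPES}
        genotype_slope[m][REFERENCE_GENOTYPE] = 0.0

    return CoefficientSet(
        name=f"fit_{fit.spec.label.lower()}",
        intercept=float(intercept),
        genotype_effect=genotype_effect,
        parity_effect=parity_effect,
        pooled_slope=pooled_slope,
        genotype_slope=genotype_slope,
        lactation_curve=tuple(lact_curve),
        dry_curve=tuple(dry_curve),
        model_spec=fit.spec.measurements,
    )
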