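"""Hold-out validation of body-weight prediction equations.

Implements the deterministic every-fifth-record split, RMSPE and R²,
the Bibby–Toutenburg decomposition of the mean square prediction error
into error of central tendency (ECT, squared mean bias), error due to
regression (ER, observed-on-predicted slope away from 1) and error of
disturbance (ED, random scatter), and the St.-Pierre centered-residual
regression.  Reports are produced separately for the lactation and dry
periods.

Population (divide-by-n) variances are used inside the decomposition so
that ECT + ER + ED equals MSPE as an algebraic identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InputError
from .model import CoefficientSet, predict_frame

__all__ = [
    "ValidationReport",
    "split_every_fifth",
    "mspe_decompose",
    "stpierre_regression",
    "validate_model",
    "reports_to_frame",
]


@dataclass
class ValidationReport:
    """Per-period prediction-quality summary on held-out records."""

    period: str
    n: int
    mspe: float
    rmspe: float
    r2: float
    ect: float
    er: float
    ed: float
    ect_pct: float
    er_pct: float
    ed_pct: float
    stpierre_intercept: float
    stpierre_slope: float
    insufficient: bool = False


def split_every_fifth(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 80/20 split: every fifth record goes to validation.

    Records are first sorted by cow identification number, then by day
    relative to calving (then by original order, to make the order total);
    rows at 1-based positions 5, 10, 15, ... form the validation subset.
    The result is independent of the input ordering.
    """
    df = records.df if hasattr(records, "df") else records
    if len(df) == 0:
        raise InputError("cannot split an empty record set")
    ordered = df.sort_values(
        ["cow_id", "day"], kind="mergesort"  # stable: original order breaks ties
    ).reset_index(drop=True)
    is_val = (np.arange(len(ordered)) + 1) % 5 == 0
    return ordered[~is_val].copy(), ordered[is_val].copy()


def mspe_decompose(observed, predicted) -> tuple[float, float, float, float]:
    """Bibby–Toutenburg decomposition of the mean square prediction error.

    Returns ``(mspe, ect, er, ed)`` with

        mspe = mean((O - P)^2)
        ect  = (mean O - mean P)^2
        er   = (s_P - r * s_O)^2
        ed   = (1 - r^2) * s_O^2

    using population (divide-by-n) standard deviations and the Pearson
    correlation r, so that ect + er + ed = mspe exactly.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise InputError(f"length mismatch: {o.shape} observed vs {p.shape} predicted")
    if o.size < 2:
        raise InputError("need at least two records for the decomposition")
    mspe = float(np.mean((o - p) ** 2))
    ect = float((o.mean() - p.mean()) ** 2)
    s_o = float(o.std())  # population SDs: exact three-term identity
    s_p = float(p.std())
    if s_p == 0.0:
        raise InputError("predicted values are constant; ER and ED are undefined")
    r = float(np.mean((o - o.mean()) * (p - p.mean())) / (s_o * s_p)) if s_o > 0 else 0.0
    er = float((s_p - r * s_o) ** 2)
    ed = float((1.0 - r**2) * s_o**2)
    return mspe, ect, er, ed


def stpierre_regression(observed, predicted) -> tuple[float, float]:
    """OLS of the residuals (O - P) on the mean-centered predictions.

    By construction the intercept equals the mean bias mean(O) - mean(P)
    and the slope equals cov(O, P)/var(P) - 1; both identities are checked
    against the numerical OLS solution.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise InputError(f"length mismatch: {o.shape} observed vs {p.shape} predicted")
    if o.size < 2 or p.std() == 0.0:
        raise InputError("predicted values must vary to regress on them")
    x = p - p.mean()
    res = sm.OLS(o - p, sm.add_constant(x)).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    scale = max(1.0, abs(o).max())
    assert abs(intercept - (o.mean() - p.mean())) < 1e-8 * scale
    assert abs(slope - (np.mean(x * (o - o.mean())) / np.mean(x**2) - 1.0)) < 1e-8
    return intercept, slope


def _report(period: str, o: np.ndarray, p: np.ndarray) -> ValidationReport:
    mspe, ect, er, ed = mspe_decompose(o, p)
    intercept, slope = stpierre_regression(o, p)
    r = np.corrcoef(o, p)[0, 1] if o.std() > 0 else np.nan
    pct = (
        (100.0 * ect / mspe, 100.0 * er / mspe, 100.0 * ed / mspe)
        if mspe > 0
        else (0.0, 0.0, 0.0)
    )
    return ValidationReport(
        period=period,
        n=len(o),
        mspe=mspe,
        rmspe=float(np.sqrt(mspe)),
        r2=float(r**2),
        ect=ect,
        er=er,
        ed=ed,
        ect_pct=pct[0],
        er_pct=pct[1],
        ed_pct=pct[2],
        stpierre_intercept=intercept,
        stpierre_slope=slope,
    )


def validate_model(coeffs: CoefficientSet, records) -> dict[str, ValidationReport]:
    """Predict held-out records and report per-period prediction quality.

    Periods are taken from the records' day relative to calving (never
    re-assigned from predictions).  A period with fewer than three records
    yields a report flagged ``insufficient`` instead of failing.
    """
    df = records.df if hasattr(records, "df") else records
    if "bw_observed" not in df.columns or df["bw_observed"].isna().any():
        raise InputError("validation records must carry observed body weight")
    pred = predict_frame(df, coeffs)
    period = np.where(df["day"].to_numpy(dtype=float) >= 1, "lactation", "dry")
    out: dict[str, ValidationReport] = {}
    for per in ("lactation", "dry"):
        mask = period == per
        n = int(mask.sum())
        if n < 3:
            out[per] = ValidationReport(
                period=per, n=n, mspe=np.nan, rmspe=np.nan, r2=np.nan,
                ect=np.nan, er=np.nan, ed=np.nan, ect_pct=np.nan,
                er_pct=np.nan, ed_pct=np.nan, stpierre_intercept=np.nan,
                stpierre_slope=np.nan, insufficient=True,
            )
            continue
        o = df.loc[mask, "bw_observed"].to_numpy(dtype=float)
        out[per] = _report(per, o, pred[mask])
    return out


def reports_to_frame(reports: dict[str, "ValidationReport"],
                     model: str = "") -> pd.DataFrame:
    """Flatten per-period reports into a one-row-per-period table."""
    rows = []
    for per, rep in reports.items():
        row = {"model": model, **rep.__dict__}
        rows.append(row)
    return pd.DataFrame(rows)


def plot_centered_residuals(coeffs: CoefficientSet, records, path) -> None:
    """Diagnostic scatter of residuals vs mean-centered predictions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records.df if hasattr(records, "df") else records
    pred = predict_frame(df, coeffs)
    obs = df["bw_observed"].to_numpy(dtype=float)
    x = pred - pred.mean()
    intercept, slope = stpierre_regression(obs, pred)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, obs - pred, s=4, alpha=0.3)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, intercept + slope * xs, color="C1",
            label=f"intercept {intercept:.2f} kg, slope {slope:.4f}")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("predicted BW centered on mean (kg)")
    ax.set_ylabel("observed - predicted BW (kg)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
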