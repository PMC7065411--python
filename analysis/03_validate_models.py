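"""Hold-out validation of the re-estimated equations.

Splits the working herd by the deterministic every-fifth-record rule,
refits both equations (HG+BG and HG+BG+HW, genotype-specific) on the
estimation subset, predicts the hold-out subset, and reports RMSPE, R²,
the Bibby–Toutenburg MSPE decomposition (ECT/ER/ED) and the St.-Pierre
centered-residual regression per period.  Under correct specification the
disturbance component should dominate (no systematic error).

Run from the repository root:  python analysis/03_validate_models.py
"""

import argparse
from pathlib import Path

import pandas as pd

from cowbw import (
    ModelSpec,
    default_config,
    fit_mixed,
    simulate_herd,
    split_every_fifth,
    validate_model,
)
from cowbw.io import read_records
from cowbw.validate import plot_centered_residuals, reports_to_frame


def load_herd(outdir: Path, seed: int):
    path = outdir / "herd.csv"
    if path.exists():
        return read_records(path)
    return simulate_herd(default_config("hgbghw", n_records=10000, seed=seed)).df


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--plot", action="store_true",
                        help="also write centered-residual diagnostic plots")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    df = load_herd(args.outdir, args.seed)
    est, val = split_every_fifth(df)
    print(f"every-fifth split: {len(est)} estimation / {len(val)} validation records")

    tables = []
    for label, meas in (("hgbg", ("HG", "BG")), ("hgbghw", ("HG", "BG", "HW"))):
        fit = fit_mixed(est, ModelSpec(meas, genotype_specific=True))
        reports = validate_model(fit.coefficients, val)
        tables.append(reports_to_frame(reports, model=label))
        for period, rep in reports.items():
            print(
                f"{label:7s} {period:9s} n={rep.n:5d}  RMSPE {rep.rmspe:5.1f} kg  "
                f"R2 {100 * rep.r2:5.1f} %  ED {rep.ed_pct:6.2f} %  "
                f"St.-Pierre intercept {rep.stpierre_intercept:+.2f} kg, "
                f"slope {rep.stpierre_slope:+.4f}"
            )
        if args.plot:
            plot_path = args.outdir / f"centered_residuals_{label}.png"
            plot_centered_residuals(fit.coefficients, val, plot_path)
            print(f"  plot -> {plot_path}")
    summary = pd.concat(tables, ignore_index=True)
    summary.to_csv(args.outdir / "validation.csv", index=False)
    print(f"validation table -> {args.outdir / 'validation.csv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
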