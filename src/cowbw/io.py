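"""Reading and writing weighing-record tables and run artifacts.

Records travel as delimited text (CSV) with one row per weighing event and
the field abbreviations used throughout the package: HG heart girth, BG
belly girth, ST stature, BL body length, PL pelvis length, BD body depth,
HW hip width, PW pin width, KW knee width (all cm), BCS body condition
score (1-5), MUSC muscle score (1-10), bw_observed body weight (kg) and a
single signed ``day`` relative to calving (lactation 1..364, dry -56..-1).
Provenance (seed, generator settings) is carried in ``#``-prefixed header
lines.  Floats are serialized at full precision so round-trips are exact.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Iterable

import pandas as pd

from .errors import InputError
from .model import DRY_DAYS, GENOTYPES, LACTATION_DAYS, MEASUREMENTS
from .simulate import Herd

logger = logging.getLogger("cowbw")

MANDATORY_COLUMNS = ("cow_id", "farm_id", "genotype", "parity", "day")


def write_records(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a record table as CSV with optional ``#`` provenance header."""
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        # repr gives the shortest decimal that round-trips the double exactly
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def write_herd(herd: Herd, path) -> None:
    """Write a simulated herd including its generative provenance."""
    cfg = herd.config
    provenance = {
        "generator": "cowbw.simulate.simulate_herd",
        "seed": cfg.seed,
        "truth": cfg.truth.name,
        "n_records": len(herd.df),
        "farm_sd_kg": cfg.farm_sd,
        "residual_sd_kg": cfg.residual_sd,
        "dry_fraction": cfg.dry_fraction,
    }
    write_records(herd.df, path, provenance)


def _row_errors(row, idx: int) -> list[str]:
    errs = []
    if row["genotype"] not in GENOTYPES:
        errs.append(f"row {idx}: unknown genotype {row['genotype']!r}")
    try:
        parity = float(row["parity"])
        if parity < 1 or parity != int(parity):
            errs.append(f"row {idx}: parity must be an integer >= 1, got {row['parity']}")
    except (TypeError, ValueError):
        errs.append(f"row {idx}: unparseable parity {row['parity']!r}")
    try:
        day = float(row["day"])
        lact_ok = LACTATION_DAYS[0] <= day <= LACTATION_DAYS[1]
        dry_ok = DRY_DAYS[0] <= day <= DRY_DAYS[1]
        if not (lact_ok or dry_ok):
            errs.append(
                f"row {idx}: day {row['day']} outside the lactation domain "
                f"{LACTATION_DAYS[0]}..{LACTATION_DAYS[1]} and dry domain "
                f"{DRY_DAYS[0]}..{DRY_DAYS[1]}"
            )
    except (TypeError, ValueError):
        errs.append(f"row {idx}: unparseable day {row['day']!r}")
    for trait in MEASUREMENTS:
        if trait not in row.index or pd.isna(row[trait]):
            continue
        v = row[trait]
        if not v > 0:
            errs.append(f"row {idx}: {trait} must be strictly positive, got {v}")
        elif trait == "BCS" and not 1.0 <= v <= 5.0:
            errs.append(f"row {idx}: BCS must be within the 1-5 range, got {v}")
        elif trait == "MUSC" and not 1.0 <= v <= 10.0:
            errs.append(f"row {idx}: muscle score must be within 1-10, got {v}")
    return errs


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows violating record invariants; return survivors and messages."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"missing mandatory column(s): {', '.join(missing)}")
    messages: list[str] = []
    keep = []
    for idx, row in df.iterrows():
        errs = _row_errors(row, idx)
        if errs:
            messages.extend(errs)
        else:
            keep.append(idx)
    return df.loc[keep].copy(), messages


def read_records(path, return_errors: bool = False):
    """Read and validate a record CSV (``#`` header lines are skipped).

    Invalid rows are dropped with row-numbered log messages; accepted and
    rejected counts are logged.
    """
    # round_trip parsing: the written repr digits map back to the same double
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    accepted, messages = validate_records(df)
    for msg in messages:
        logger.warning(msg)
    logger.info(
        "read %d records from %s (%d accepted, %d rejected)",
        len(df), path, len(accepted), len(df) - len(accepted),
    )
    if return_errors:
        return accepted, messages
    return accepted


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
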