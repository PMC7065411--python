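"""Body-weight prediction equations for dairy cows.

The prediction model is a linear equation

    BW = mu + G_i + P_j + PS(day) + sum_l (b_l + b_l(G_i)) * X_l

with a genotype class effect ``G_i`` (Fleckvieh subclassed by Red-Holstein
gene proportion, Holstein-Friesian, Brown Swiss; Brown Swiss is the
reference), a parity class effect ``P_j`` (classes 1, 2, 3+4, >=5; the
oldest class is the reference), a physiological-stage term ``PS`` evaluated
as a fitted polynomial in the day relative to calving (degree 4 during
lactation, linear during the dry period), and pooled plus genotype-specific
regressions on body measurements ``X_l`` in cm.

Two estimated coefficient sets ship with the package as structured text
files: ``model_hgbg`` (heart girth + belly girth) and ``model_hgbghw``
(heart girth + belly girth + hip width).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, InputError

__all__ = [
    "GENOTYPES",
    "PARITY_CLASSES",
    "MEASUREMENTS",
    "LACTATION_DAYS",
    "DRY_DAYS",
    "PhysiologicalStage",
    "CowRecord",
    "CoefficientSet",
    "classify_genotype",
    "classify_parity",
    "stage_from_day",
    "stage_effect",
    "predict_bw",
    "predict_frame",
    "load_coefficients",
    "save_coefficients",
    "packaged_model",
]

#: Genotype class labels; Brown Swiss (BS) is the reference class.
GENOTYPES = ("FV", "FV_RH_m", "FV_RH_h", "HF", "BS")
REFERENCE_GENOTYPE = "BS"

#: Parity class labels; the oldest class (>=5) is the reference class.
PARITY_CLASSES = ("P1", "P2", "P3_4", "P5plus")
REFERENCE_PARITY = "P5plus"

#: Body measurements (cm) plus the two scored traits.
MEASUREMENTS = ("HG", "BG", "ST", "BL", "PL", "BD", "HW", "PW", "KW", "BCS", "MUSC")

#: Valid day ranges relative to calving.
LACTATION_DAYS = (1, 364)  # 13 stage classes of 28 days
DRY_DAYS = (-56, -1)  # 4 stage classes of 14 days


# ---------------------------------------------------------------------------
# classification helpers
# ---------------------------------------------------------------------------

def classify_genotype(breed: str, rh_fraction: float = 0.0) -> str:
    """Map a breed label and Red-Holstein gene fraction to a genotype class.

    HF and BS map to themselves.  Fleckvieh cows are subclassed by their RH
    ancestry: <=10 % -> FV, >10 to <=44.5 % -> FV_RH_m, >44.5 % -> FV_RH_h.
    """
    if breed in ("HF", "BS"):
        return breed
    if breed != "FV":
        raise InputError(f"unknown breed label {breed!r}; expected FV, HF or BS")
    if not 0.0 <= rh_fraction <= 1.0:
        raise InputError(f"RH gene fraction must be in [0, 1], got {rh_fraction}")
    if rh_fraction <= 0.10:
        return "FV"
    if rh_fraction <= 0.445:
        return "FV_RH_m"
    return "FV_RH_h"


def classify_parity(parity: int) -> str:
    """Map a parity number (>=1) to its class: 1, 2, 3+4 or >=5."""
    if parity < 1:
        raise InputError(f"parity must be >= 1, got {parity}")
    if parity == 1:
        return "P1"
    if parity == 2:
        return "P2"
    if parity in (3, 4):
        return "P3_4"
    return "P5plus"


@dataclass(frozen=True)
class PhysiologicalStage:
    """Stage within the lactation/dry cycle, indexed by day relative to calving.

    Lactation days 1-364 fall into 13 four-week classes; dry days -56..-1
    fall into 4 two-week classes.  ``class_index`` is derived from ``day``.
    """

    period: str  # "lactation" or "dry"
    day: int

    def __post_init__(self) -> None:
        if self.period == "lactation":
            lo, hi = LACTATION_DAYS
        elif self.period == "dry":
            lo, hi = DRY_DAYS
        else:
            raise InputError(f"unknown period {self.period!r}")
        if not lo <= self.day <= hi:
            raise DomainError(
                f"{self.period} day must be in [{lo}, {hi}], got {self.day}"
            )

    @property
    def class_index(self) -> int:
        if self.period == "lactation":
            return (self.day - 1) // 28 + 1
        return (self.day - DRY_DAYS[0]) // 14 + 1

    @property
    def class_midpoint(self) -> float:
        """Representative (midpoint) day of the stage class."""
        if self.period == "lactation":
            return (self.class_index - 1) * 28 + 14.5
        return DRY_DAYS[0] + (self.class_index - 1) * 14 + 6.5


def stage_from_day(day: int) -> PhysiologicalStage:
    """Build a stage from a signed day relative to calving (lactation > 0)."""
    if day >= 1:
        return PhysiologicalStage("lactation", int(day))
    if day <= -1:
        return PhysiologicalStage("dry", int(day))
    raise DomainError(
        f"day 0 is undefined; lactation days are {LACTATION_DAYS[0]}..{LACTATION_DAYS[1]}, "
        f"dry days {DRY_DAYS[0]}..{DRY_DAYS[1]}"
    )


def stage_class_midpoints() -> dict[tuple[str, int], float]:
    """Midpoint day of every stage class (13 lactation + 4 dry)."""
    out: dict[tuple[str, int], float] = {}
    for m in range(1, 14):
        out[("lactation", m)] = (m - 1) * 28 + 14.5
    for s in range(1, 5):
        out[("dry", s)] = DRY_DAYS[0] + (s - 1) * 14 + 6.5
    return out


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class CowRecord:
    """A single weighing event.

    Measurements are in cm, BCS on the 1-5 scale, muscle score on 1-10;
    ``bw_observed`` (kg) is optional for pure prediction.  Measurements not
    required by a model's specification may be missing (``None``).
    """

    cow_id: str
    farm_id: str
    genotype: str
    parity: int
    day: int
    rh_fraction: float = 0.0
    HG: float | None = None
    BG: float | None = None
    ST: float | None = None
    BL: float | None = None
    PL: float | None = None
    BD: float | None = None
    HW: float | None = None
    PW: float | None = None
    KW: float | None = None
    BCS: float | None = None
    MUSC: float | None = None
    bw_observed: float | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise InputError(f"unknown genotype class {self.genotype!r}")
        classify_parity(self.parity)  # validates >= 1
        stage_from_day(self.day)  # validates domain
        for trait in MEASUREMENTS:
            v = getattr(self, trait)
            if v is None:
                continue
            if not v > 0:
                raise InputError(f"{trait} must be strictly positive, got {v}")
        if self.BCS is not None and not 1.0 <= self.BCS <= 5.0:
            raise InputError(f"BCS must be within [1, 5], got {self.BCS}")
        if self.MUSC is not None and not 1.0 <= self.MUSC <= 10.0:
            raise InputError(f"muscle score must be within [1, 10], got {self.MUSC}")

    @property
    def stage(self) -> PhysiologicalStage:
        return stage_from_day(self.day)

    @property
    def parity_class(self) -> str:
        return classify_parity(self.parity)


# ---------------------------------------------------------------------------
# coefficient sets
# ---------------------------------------------------------------------------

@dataclass
class CoefficientSet:
    """A complete body-weight prediction equation.

    ``lactation_curve`` holds 5 polynomial coefficients in ascending powers
    of DIM (kg, kg/d, ...); ``dry_curve`` holds 2 (kg, kg/d) in the signed
    day relative to calving.  Reference classes (BS, parity >=5) carry zero
    effects; genotype-specific slopes are deviations from the pooled slope
    and are zero for BS.
    """

    name: str
    intercept: float
    genotype_effect: dict[str, float]
    parity_effect: dict[str, float]
    pooled_slope: dict[str, float]
    genotype_slope: dict[str, dict[str, float]]
    lactation_curve: tuple[float, ...]
    dry_curve: tuple[float, ...]
    model_spec: tuple[str, ...]

    def __post_init__(self) -> None:
        self.lactation_curve = tuple(float(c) for c in self.lactation_curve)
        self.dry_curve = tuple(float(c) for c in self.dry_curve)
        self.model_spec = tuple(self.model_spec)
        self.validate()

    def validate(self) -> None:
        for g in GENOTYPES:
            if g not in self.genotype_effect:
                raise InputError(f"genotype effect missing for class {g}")
        for p in PARITY_CLASSES:
            if p not in self.parity_effect:
                raise InputError(f"parity effect missing for class {p}")
        if self.genotype_effect[REFERENCE_GENOTYPE] != 0.0:
            raise InputError("reference genotype (BS) effect must be 0")
        if self.parity_effect[REFERENCE_PARITY] != 0.0:
            raise InputError("reference parity (>=5) effect must be 0")
        for m in self.model_spec:
            if m not in self.pooled_slope:
                raise InputError(f"model_spec trait {m} has no pooled slope")
            slopes = self.genotype_slope.get(m, {})
            if slopes.get(REFERENCE_GENOTYPE, 0.0) != 0.0:
                raise InputError(f"BS slope deviation for {m} must be 0")

    # -- evaluation ---------------------------------------------------------

    def effective_slope(self, measurement: str, genotype: str) -> float:
        """Pooled slope plus the genotype-specific deviation (kg/cm)."""
        dev = self.genotype_slope.get(measurement, {}).get(genotype, 0.0)
        return self.pooled_slope[measurement] + dev

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "genotype_effect": dict(self.genotype_effect),
            "parity_effect": dict(self.parity_effect),
            "pooled_slope": dict(self.pooled_slope),
            "genotype_slope": {m: dict(d) for m, d in self.genotype_slope.items()},
            "lactation_curve": list(self.lactation_curve),
            "dry_curve": list(self.dry_curve),
            "model_spec": list(self.model_spec),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        return cls(
            name=d["name"],
            intercept=float(d["intercept"]),
            genotype_effect={k: float(v) for k, v in d["genotype_effect"].items()},
            parity_effect={k: float(v) for k, v in d["parity_effect"].items()},
            pooled_slope={k: float(v) for k, v in d["pooled_slope"].items()},
            genotype_slope={
                m: {k: float(v) for k, v in sub.items()}
                for m, sub in d["genotype_slope"].items()
            },
            lactation_curve=tuple(float(c) for c in d["lactation_curve"]),
            dry_curve=tuple(float(c) for c in d["dry_curve"]),
            model_spec=tuple(d["model_spec"]),
        )


class _FullPrecisionDumper(yaml.SafeDumper):
    """YAML dumper writing floats via repr so round-trips are bit-exact."""


_FullPrecisionDumper.add_representer(
    float,
    lambda dumper, value: dumper.represent_scalar("tag:yaml.org,2002:float", repr(value)),
)


def save_coefficients(coeffs: CoefficientSet, path) -> None:
    """Write a coefficient set as a structured text (YAML) file."""
    with open(path, "w") as fh:
        yaml.dump(coeffs.to_dict(), fh, Dumper=_FullPrecisionDumper, sort_keys=False)


def load_coefficients(path) -> CoefficientSet:
    """Read a coefficient set from a structured text (YAML) file."""
    with open(path) as fh:
        return CoefficientSet.from_dict(yaml.safe_load(fh))


def packaged_model(name: str) -> CoefficientSet:
    """Load one of the shipped coefficient sets: ``hgbg`` or ``hgbghw``."""
    key = name.lower().replace("model_", "")
    if key not in ("hgbg", "hgbghw"):
        raise InputError(f"unknown packaged model {name!r}; expected hgbg or hgbghw")
    ref = resources.files("cowbw").joinpath(f"data/model_{key}.yaml")
    with resources.as_file(ref) as path:
        return load_coefficients(path)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def stage_effect(day: int, period: str, coeffs: CoefficientSet) -> float:
    """Evaluate the fitted physiological-stage polynomial at a given day.

    Degree 4 in DIM during lactation (days 1-364), linear in the signed day
    during the dry period (days -56..-1).  Days outside the fitted range are
    rejected because the curvature of the polynomials is not trustworthy
    beyond it.
    """
    stage = PhysiologicalStage(period, int(day))  # validates domain
    if stage.period == "lactation":
        return float(np.polynomial.polynomial.polyval(day, coeffs.lactation_curve))
    return float(np.polynomial.polynomial.polyval(day, coeffs.dry_curve))


def _required_measurements(record: CowRecord, coeffs: CoefficientSet) -> dict[str, float]:
    values: dict[str, float] = {}
    missing = []
    for m in coeffs.model_spec:
        v = getattr(record, m)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            missing.append(m)
        else:
            values[m] = float(v)
    if missing:
        raise InputError(
            f"record {record.cow_id}: missing required measurement(s) "
            f"{', '.join(missing)} for model {coeffs.name}"
        )
    return values


def predict_bw(record: CowRecord, coeffs: CoefficientSet) -> float:
    """Predict body weight (kg) for one record at the population level.

    The random farm effect and the residual are set to zero; the prediction
    is the fixed-effect part of the mixed model with the stage term taken
    from the fitted per-period curve.
    """
    x = _required_measurements(record, coeffs)
    stage = record.stage
    value = (
        coeffs.intercept
        + coeffs.genotype_effect[record.genotype]
        + coeffs.parity_effect[record.parity_class]
        + stage_effect(stage.day, stage.period, coeffs)
    )
    for m, v in x.items():
        value += coeffs.effective_slope(m, record.genotype) * v
    return float(value)


def predict_frame(df: pd.DataFrame, coeffs: CoefficientSet) -> np.ndarray:
    """Vectorized prediction over a herd table.

    Requires columns ``genotype``, ``parity``, ``day`` and one column per
    measurement in ``coeffs.model_spec``.
    """
    missing_cols = [m for m in coeffs.model_spec if m not in df.columns]
    if missing_cols:
        raise InputError(f"herd table lacks required column(s): {', '.join(missing_cols)}")
    day = df["day"].to_numpy()
    if ((day < DRY_DAYS[0]) | (day == 0) | (day > LACTATION_DAYS[1])).any():
        bad = day[(day < DRY_DAYS[0]) | (day == 0) | (day > LACTATION_DAYS[1])][0]
        raise DomainError(
            f"day {bad} outside supported range "
            f"[{DRY_DAYS[0]}, -1] U [1, {LACTATION_DAYS[1]}]"
        )
    for m in coeffs.model_spec:
        if df[m].isna().any():
            n_bad = int(df[m].isna().sum())
            raise InputError(f"{n_bad} record(s) missing required measurement {m}")

    geno = df["genotype"].to_numpy()
    parity_cls = df["parity"].map(classify_parity).to_numpy()
    pred = np.full(len(df), coeffs.intercept, dtype=float)
    pred += pd.Series(geno).map(coeffs.genotype_effect).to_numpy(dtype=float)
    pred += pd.Series(parity_cls).map(coeffs.parity_effect).to_numpy(dtype=float)
    lact = day >= 1
    pred[lact] += np.polynomial.polynomial.polyval(day[lact], coeffs.lactation_curve)
    pred[~lact] += np.polynomial.polynomial.polyval(day[~lact], coeffs.dry_curve)
    for m in coeffs.model_spec:
        slope = np.array([coeffs.effective_slope(m, g) for g in geno])
        pred += slope * df[m].to_numpy(dtype=float)
    return pred
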