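"""Default measurement profiles for the synthetic-herd generator.

Per-period (lactation / dry) means, standard deviations and truncation
bounds for the nine body measurements plus BCS and muscle score, and the
period-specific between-trait Pearson correlation matrices.  The numbers
describe a mixed Fleckvieh / Holstein / Brown Swiss population on
commercial dairy farms; dry cows are heavier with wider girths, while the
skeletal measurements barely change between periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .model import MEASUREMENTS

__all__ = ["MeasurementProfile", "lactation_profile", "dry_profile", "GENOTYPE_MIXTURE"]

#: Genotype class frequencies of the reference population
#: (2604 FV, 773 FV_RH_m, 373 FV_RH_h, 1056 HF, 1500 BS of 6306 cows).
GENOTYPE_MIXTURE = {
    "FV": 2604 / 6306,
    "FV_RH_m": 773 / 6306,
    "FV_RH_h": 373 / 6306,
    "HF": 1056 / 6306,
    "BS": 1500 / 6306,
}

# trait order: HG BG ST BL PL BD HW PW KW BCS MUSC
_LACT_MEAN = [210.0, 256.0, 146.0, 90.0, 56.0, 84.0, 57.0, 39.0, 53.0, 3.15, 5.1]
_LACT_SD = [10.3, 13.6, 4.5, 5.6, 3.0, 4.5, 3.4, 4.7, 5.5, 0.58, 1.5]
_LACT_LO = [173.0, 204.0, 128.0, 73.0, 46.0, 67.0, 45.0, 27.0, 36.0, 1.0, 1.0]
_LACT_HI = [253.0, 312.0, 163.0, 111.0, 68.0, 99.0, 68.0, 59.0, 69.0, 5.0, 9.0]

_DRY_MEAN = [217.0, 271.0, 146.0, 91.0, 56.0, 86.0, 58.0, 40.0, 55.0, 3.57, 5.9]
_DRY_SD = [11.2, 13.5, 4.6, 5.8, 3.1, 4.2, 3.4, 4.8, 6.2, 0.56, 1.6]
_DRY_LO = [185.0, 235.0, 130.0, 75.0, 45.0, 71.0, 47.0, 27.0, 36.0, 2.0, 1.0]
_DRY_HI = [264.0, 307.0, 163.0, 109.0, 66.0, 99.0, 67.0, 57.0, 71.0, 5.0, 9.0]

# Between-trait Pearson correlations, lactation period (upper triangle by row).
_LACT_UPPER = [
    #    BG    ST    BL    PL    BD    HW    PW    KW    BCS   MUSC
    [0.72, 0.25, 0.16, 0.44, 0.55, 0.57, 0.34, 0.21, 0.35, 0.34],  # HG
    [0.16, 0.25, 0.32, 0.62, 0.54, 0.34, 0.24, 0.30, 0.34],  # BG
    [0.40, 0.50, 0.41, 0.36, 0.04, 0.14, 0.00, -0.12],  # ST
    [0.24, 0.33, 0.32, 0.00, 0.05, 0.00, 0.01],  # BL
    [0.48, 0.56, 0.23, 0.20, 0.13, 0.02],  # PL
    [0.60, 0.22, 0.24, 0.06, 0.03],  # BD
    [0.36, 0.32, 0.16, 0.11],  # HW
    [0.21, 0.11, 0.22],  # PW
    [0.22, 0.13],  # KW
    [0.58],  # BCS
]

# Between-trait Pearson correlations, dry period (upper triangle by row).
_DRY_UPPER = [
    #    BG    ST    BL    PL    BD    HW    PW    KW    BCS   MUSC
    [0.72, 0.25, 0.08, 0.40, 0.53, 0.53, 0.29, 0.15, 0.45, 0.37],  # HG
    [0.20, 0.19, 0.33, 0.60, 0.51, 0.26, 0.22, 0.39, 0.35],  # BG
    [0.43, 0.48, 0.41, 0.34, 0.04, 0.19, 0.04, -0.08],  # ST
    [0.23, 0.28, 0.25, -0.06, 0.13, 0.05, 0.10],  # BL
    [0.46, 0.53, 0.22, 0.18, 0.21, 0.10],  # PL
    [0.54, 0.19, 0.27, 0.21, 0.16],  # BD
    [0.36, 0.34, 0.27, 0.20],  # HW
    [0.18, 0.16, 0.17],  # PW
    [0.23, 0.14],  # KW
    [0.49],  # BCS
]


def _full_matrix(upper_rows: list[list[float]]) -> np.ndarray:
    n = len(MEASUREMENTS)
    mat = np.eye(n)
    for i, row in enumerate(upper_rows):
        for off, r in enumerate(row, start=1):
            mat[i, i + off] = r
            mat[i + off, i] = r
    return mat


@dataclass
class MeasurementProfile:
    """Marginal moments, truncation bounds and correlations for one period."""

    traits: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        k = len(self.traits)
        if not (self.mean.shape == self.sd.shape == self.lower.shape
                == self.upper.shape == (k,)) or self.corr.shape != (k, k):
            raise ConfigError("profile arrays must match the trait list length")
        if (self.sd <= 0).any():
            raise ConfigError("all measurement SDs must be > 0")
        if (self.lower >= self.upper).any():
            raise ConfigError("truncation bounds must satisfy lower < upper")
        if ((self.mean < self.lower) | (self.mean > self.upper)).any():
            raise ConfigError("profile means must lie inside the truncation bounds")


def lactation_profile() -> MeasurementProfile:
    """Default lactation-period profile of the reference population."""
    return MeasurementProfile(
        traits=MEASUREMENTS,
        mean=_LACT_MEAN, sd=_LACT_SD, lower=_LACT_LO, upper=_LACT_HI,
        corr=_full_matrix(_LACT_UPPER),
    )


def dry_profile() -> MeasurementProfile:
    """Default dry-period profile of the reference population."""
    return MeasurementProfile(
        traits=MEASUREMENTS,
        mean=_DRY_MEAN, sd=_DRY_SD, lower=_DRY_LO, upper=_DRY_HI,
        corr=_full_matrix(_DRY_UPPER),
    )
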