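"""Synthetic herd generation.

Produces weighing records with the statistical structure the estimation
pipeline assumes: a genotype mixture over five classes, a random farm
effect, a day relative to calving drawn per record (dry with a configurable
probability), body measurements drawn from a period-specific truncated
multivariate normal with a target correlation matrix, and observed body
weight generated from a known ``CoefficientSet`` plus farm effect and
residual noise.  Because the generating equation is known, fitted models
can be checked for parameter recovery and the validation machinery for
behaviour under correct specification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from statsmodels.stats.correlation_tools import corr_nearest

from .errors import ConfigError, InputError
from .model import (
    DRY_DAYS,
    GENOTYPES,
    LACTATION_DAYS,
    MEASUREMENTS,
    CoefficientSet,
    packaged_model,
    predict_frame,
    stage_class_midpoints,
)
from .profiles import (
    GENOTYPE_MIXTURE,
    MeasurementProfile,
    dry_profile,
    lactation_profile,
)

__all__ = [
    "SimulationConfig",
    "Herd",
    "repair_correlation",
    "simulate_herd",
    "split_cow_level",
    "default_config",
]

#: RH gene-fraction interval sampled per FV subclass (informational only).
_RH_INTERVALS = {
    "FV": (0.0, 0.10),
    "FV_RH_m": (0.10, 0.445),
    "FV_RH_h": (0.445, 1.0),
    "HF": (0.0, 0.0),
    "BS": (0.0, 0.0),
}

_PARITY_MAX = 13
_PARITY_MEAN = 3.0


def repair_correlation(matrix: np.ndarray) -> np.ndarray:
    """Return the nearest positive semi-definite correlation matrix.

    A correlation matrix assembled from two printed triangles need not be
    PSD; this projects onto the PSD cone (Higham-style eigenvalue clipping
    with unit diagonal preserved).  An already-PSD input is returned
    unchanged.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InputError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise InputError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise InputError("correlation matrix must have unit diagonal")
    if (np.abs(mat) > 1.0 + 1e-12).any():
        raise InputError("correlation entries must lie within [-1, 1]")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals[0] >= -1e-12:
        return mat
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # iteration cap is fine: PSD is checked below
        repaired = np.asarray(corr_nearest(mat, threshold=1e-12, n_fact=200))
    if np.linalg.eigvalsh(repaired)[0] < -1e-10:
        raise ConfigError("correlation repair failed to reach a PSD matrix")
    return repaired


def _parity_probs() -> np.ndarray:
    """Truncated-geometric parity distribution over 1..13 with mean 3.0."""
    k = np.arange(1, _PARITY_MAX + 1)

    def mean_minus_target(p: float) -> float:
        w = p * (1 - p) ** (k - 1)
        w /= w.sum()
        return float((w * k).sum()) - _PARITY_MEAN

    p = brentq(mean_minus_target, 0.05, 0.9, xtol=1e-12)
    w = p * (1 - p) ** (k - 1)
    return w / w.sum()


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate the reference population."""

    n_farms: int = 167
    cows_per_farm: int = 38
    records_per_cow: int = 1
    n_records: int | None = None  # overrides n_farms*cows_per_farm*records_per_cow
    genotype_mixture: dict[str, float] = field(
        default_factory=lambda: dict(GENOTYPE_MIXTURE)
    )
    dry_fraction: float = 0.10
    lactation: MeasurementProfile = field(default_factory=lactation_profile)
    dry: MeasurementProfile = field(default_factory=dry_profile)
    farm_sd: float = 20.0
    residual_sd: float = 30.4
    truth: CoefficientSet = field(default_factory=lambda: packaged_model("hgbghw"))
    seed: int = 0
    days_at_class_midpoints: bool = False  # balanced design for exactness checks
    max_rejection_rounds: int = 200

    def __post_init__(self) -> None:
        if self.n_farms < 1 or self.cows_per_farm < 1 or self.records_per_cow < 1:
            raise ConfigError("herd dimensions must be positive")
        total = abs(sum(self.genotype_mixture.values()) - 1.0)
        if total > 1e-8:
            raise ConfigError("genotype mixture proportions must sum to 1")
        unknown = set(self.genotype_mixture) - set(GENOTYPES)
        if unknown:
            raise ConfigError(f"unknown genotype class(es) in mixture: {sorted(unknown)}")
        if not 0.0 <= self.dry_fraction < 1.0:
            raise ConfigError("dry_fraction must be in [0, 1)")
        if self.farm_sd < 0:
            raise ConfigError("farm_sd must be >= 0")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")

    @property
    def total_records(self) -> int:
        if self.n_records is not None:
            return int(self.n_records)
        return self.n_farms * self.cows_per_farm * self.records_per_cow


@dataclass
class Herd:
    """A simulated herd: the record table plus full generative provenance.

    ``df`` carries one row per weighing record; ``bw_observed`` equals
    ``bw_true + farm_effect + residual`` exactly, so the generating model
    can be reconstructed record by record.
    """

    df: pd.DataFrame
    config: SimulationConfig
    farm_effects: dict[str, float]


def default_config(model: str = "hgbghw", n_records: int = 20000,
                   seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition config: truth and residual SD tied to a packaged model.

    The generating residual SD defaults to the estimation-data RMSE of the
    chosen packaged equation (30.4 kg for hgbghw, 32.5 kg for hgbg).
    """
    truth = packaged_model(model)
    residual_sd = {"model_hgbghw": 30.4, "model_hgbg": 32.5}[truth.name]
    cfg = SimulationConfig(
        n_records=n_records, truth=truth, residual_sd=residual_sd, seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg


def _draw_truncated_mvn(rng: np.random.Generator, profile: MeasurementProfile,
                        n: int, max_rounds: int) -> np.ndarray:
    """Record-level rejection sampling from a truncated multivariate normal."""
    if n == 0:
        return np.empty((0, len(profile.traits)))
    corr = repair_correlation(profile.corr)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    out = np.empty((n, len(profile.traits)))
    filled = 0
    for _ in range(max_rounds):
        need = n - filled
        batch = max(2 * need, 256)
        z = rng.standard_normal((batch, corr.shape[0]))
        x = profile.mean + (z @ chol.T) * profile.sd
        ok = ((x >= profile.lower) & (x <= profile.upper)).all(axis=1)
        accepted = x[ok]
        take = min(len(accepted), need)
        out[filled:filled + take] = accepted[:take]
        filled += take
        if filled == n:
            return out
    raise ConfigError(
        "rejection sampling failed: truncation bounds appear infeasible "
        f"(accepted {filled} of {n} records in {max_rounds} rounds)"
    )


def simulate_herd(config: SimulationConfig) -> Herd:
    """Generate a herd deterministically from the config (including seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.total_records
    n_cows = math.ceil(n / config.records_per_cow)

    # farms and their random effects
    farm_ids = [f"F{i + 1:04d}" for i in range(config.n_farms)]
    farm_eff = rng.normal(0.0, config.farm_sd, config.n_farms) if config.farm_sd > 0 \
        else np.zeros(config.n_farms)
    farm_effects = dict(zip(farm_ids, farm_eff))

    # cow-level attributes; cows are spread round-robin over farms
    classes = list(config.genotype_mixture)
    probs = np.array([config.genotype_mixture[g] for g in classes])
    cow_geno = rng.choice(len(classes), size=n_cows, p=probs)
    cow_rh = np.zeros(n_cows)
    for gi, g in enumerate(classes):
        lo, hi = _RH_INTERVALS[g]
        mask = cow_geno == gi
        if hi > lo:
            cow_rh[mask] = rng.uniform(lo, hi, mask.sum())
    cow_parity = rng.choice(
        np.arange(1, _PARITY_MAX + 1), size=n_cows, p=_parity_probs()
    )
    cow_farm_idx = np.arange(n_cows) % config.n_farms

    # expand to records
    rec_cow = np.repeat(np.arange(n_cows), config.records_per_cow)[:n]
    m = len(rec_cow)

    # stage days: dry with probability dry_fraction, else lactation
    is_dry = rng.random(m) < config.dry_fraction
    day = np.empty(m, dtype=float)
    day[~is_dry] = rng.integers(LACTATION_DAYS[0], LACTATION_DAYS[1] + 1,
                                (~is_dry).sum())
    day[is_dry] = rng.integers(DRY_DAYS[0], DRY_DAYS[1] + 1, is_dry.sum())
    if config.days_at_class_midpoints:
        mid = stage_class_midpoints()
        lact_mids = np.array([mid[("lactation", k)] for k in range(1, 14)])
        dry_mids = np.array([mid[("dry", k)] for k in range(1, 5)])
        day[~is_dry] = lact_mids[((day[~is_dry] - 1) // 28).astype(int)]
        day[is_dry] = dry_mids[((day[is_dry] - DRY_DAYS[0]) // 14).astype(int)]

    # measurements per period
    meas = np.empty((m, len(MEASUREMENTS)))
    meas[~is_dry] = _draw_truncated_mvn(
        rng, config.lactation, int((~is_dry).sum()), config.max_rejection_rounds
    )
    meas[is_dry] = _draw_truncated_mvn(
        rng, config.dry, int(is_dry.sum()), config.max_rejection_rounds
    )

    df = pd.DataFrame(
        {
            "cow_id": [f"AT{c + 1:06d}" for c in rec_cow],
            "farm_id": [farm_ids[cow_farm_idx[c]] for c in rec_cow],
            "genotype": [classes[cow_geno[c]] for c in rec_cow],
            "rh_fraction": cow_rh[rec_cow],
            "parity": cow_parity[rec_cow],
            "day": day,
            "period": np.where(is_dry, "dry", "lactation"),
        }
    )
    for j, t in enumerate(MEASUREMENTS):
        df[t] = meas[:, j]

    df["bw_true"] = predict_frame(df, config.truth)
    df["farm_effect"] = df["farm_id"].map(farm_effects)
    df["residual"] = rng.normal(0.0, config.residual_sd, m) \
        if config.residual_sd > 0 else np.zeros(m)
    df["bw_observed"] = df["bw_true"] + df["farm_effect"] + df["residual"]
    return Herd(df=df, config=config, farm_effects=farm_effects)


def split_cow_level(herd, fraction: float, seed: int = 0):
    """Partition records by cow so no cow appears in both subsets.

    ``fraction`` is the share of cows placed in the second (validation)
    subset.  Deterministic for a given seed.
    """
    df = herd.df if isinstance(herd, Herd) else herd
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must be strictly between 0 and 1")
    cows = np.sort(df["cow_id"].unique())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cows))
    n_val = int(round(fraction * len(cows)))
    val_cows = set(cows[perm[:n_val]])
    in_val = df["cow_id"].isin(val_cows)
    return df[~in_val].copy(), df[in_val].copy()
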