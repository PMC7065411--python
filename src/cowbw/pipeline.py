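"""End-to-end orchestration: simulate -> split -> fit -> assemble -> validate.

``run_pipeline`` executes the full analysis on one herd (simulated or read
from disk), writes every artifact as text under an output directory, and
records a manifest with the configuration, the seed and a content hash of
each file so identical configurations produce identical artifacts.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import CowbwError, InputError
from .fit import ModelSpec, fit_mixed
from .io import file_sha256, read_records, write_herd, write_records
from .model import packaged_model, save_coefficients
from .simulate import default_config, simulate_herd, split_cow_level
from .validate import reports_to_frame, validate_model

logger = logging.getLogger("cowbw")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    outdir: str
    model: str = "hgbghw"  # packaged equation used as truth / model spec
    herd_path: str | None = None  # read records instead of simulating
    n_records: int = 5000
    seed: int = 1
    refit: bool = True  # re-estimate on the estimation subset; else packaged
    genotype_specific: bool = True
    split: str = "every_fifth"  # or "cow_level"
    cow_level_fraction: float = 0.2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.split not in ("every_fifth", "cow_level"):
            raise InputError(f"unknown split rule {self.split!r}")
        if self.model not in ("hgbg", "hgbghw"):
            raise InputError(f"unknown model choice {self.model!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the pipeline; return artifact paths and the validation reports."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "simulate" if config.herd_path is None else "read"
        if config.herd_path is None:
            herd = simulate_herd(
                default_config(config.model, n_records=config.n_records,
                               seed=config.seed)
            )
            df = herd.df
            artifacts["herd"] = outdir / "herd.csv"
            write_herd(herd, artifacts["herd"])
        else:
            df = read_records(config.herd_path)
        truth = packaged_model(config.model)

        stage = "split"
        if config.split == "every_fifth":
            from .validate import split_every_fifth

            est, val = split_every_fifth(df)
        else:
            est, val = split_cow_level(df, config.cow_level_fraction,
                                       seed=config.seed)

        stage = "fit"
        if config.refit:
            spec = ModelSpec(truth.model_spec,
                             genotype_specific=config.genotype_specific)
            fit = fit_mixed(est, spec)
            coeffs = fit.coefficients
            artifacts["fit_result"] = outdir / "fit_result.yaml"
            fit.save(artifacts["fit_result"],
                     provenance={"seed": config.seed, "model": config.model})
        else:
            fit = None
            coeffs = truth

        stage = "assemble"
        artifacts["coefficients"] = outdir / "coefficients.yaml"
        save_coefficients(coeffs, artifacts["coefficients"])

        stage = "validate"
        reports = validate_model(coeffs, val)
        table = reports_to_frame(reports, model=coeffs.name)
        artifacts["validation"] = outdir / "validation.csv"
        table.to_csv(artifacts["validation"], index=False)

        stage = "manifest"
        manifest = {
            "config": {k: v for k, v in config.__dict__.items()},
            "seed": config.seed,
            "versions": {
                "cowbw": __version__,
                "python": platform.python_version(),
            },
            "files": {
                name: {"path": str(p), "sha256": file_sha256(p)}
                for name, p in artifacts.items()
            },
        }
        manifest_path = outdir / "manifest.yaml"
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        artifacts["manifest"] = manifest_path
    except CowbwError as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise CowbwError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {"artifacts": artifacts, "reports": reports, "fit": fit}
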