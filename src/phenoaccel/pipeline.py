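"""End-to-end pipeline: filters -> scoring -> recalibration -> analysis."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis.report import AnalysisReport, build_report
from .io import exclude_readmissions, read_cohort
from .phenoage import load_coefficients, score_dataframe
from .recalibration import augment_cohort
from .simulate import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("phenoaccel")


@dataclass(frozen=True)
class PipelineConfig:
    """Either a cohort file or a simulation config must be provided."""

    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    coefficients_path: str | None = None
    with_adjusted_curves: bool = True


def _constants_checksum(path: str | None) -> str:
    if path is None:
        ref = resources.files("phenoaccel.constants") / "phenoage_levine_default.json"
        data = ref.read_bytes()
    else:
        data = Path(path).read_bytes()
    return hashlib.sha256(data).hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, AnalysisReport]:
    """Run the full analysis; returns the augmented cohort and the report.

    Deterministic given the simulation seed. Logs the seed, package
    version, and the SHA-256 checksum of the coefficients file so scoring
    provenance is auditable.
    """
    if (config.cohort_path is None) == (config.simulation is None):
        raise ValueError("provide exactly one of cohort_path or simulation")
    log.info("phenoaccel %s; constants sha256=%s", __version__,
             _constants_checksum(config.coefficients_path))

    if config.simulation is not None:
        log.info("simulating cohort: n=%d seed=%d", config.simulation.n, config.simulation.seed)
        cohort = generate_cohort(config.simulation)
    else:
        cohort = read_cohort(config.cohort_path)

    try:
        cohort = exclude_readmissions(cohort)
    except Exception as exc:
        raise RuntimeError(f"stage readmission-filter: {exc}") from exc

    coeffs = load_coefficients(config.coefficients_path)
    try:
        phenoages = score_dataframe(cohort, coeffs)
    except Exception as exc:
        raise RuntimeError(f"stage scoring: {exc}") from exc

    try:
        cohort, fit = augment_cohort(cohort, phenoages)
    except Exception as exc:
        raise RuntimeError(f"stage recalibration: {exc}") from exc
    log.info("recalibration: slope=%.4f intercept=%.2f y", fit.slope, fit.intercept)

    try:
        report = build_report(cohort, with_adjusted_curves=config.with_adjusted_curves)
    except Exception as exc:
        raise RuntimeError(f"stage analysis: {exc}") from exc
    return cohort, report
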