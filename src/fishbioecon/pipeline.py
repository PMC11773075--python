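"""End-to-end analysis: fit (optional) → reference points → sweep → taxes.

:func:`run_pipeline` executes the whole chain for every configured species
and returns an :class:`AnalysisReport`; :func:`write_report` materializes it
as diff-friendly CSV/JSON artifacts.  Given the same config and seed the
report payload is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assessment import AssessmentResult, fit_dynamic_schaefer
from .config import RunConfig, SpeciesConfig
from .control import DiscountedOptimum, discount_sweep, discounted_optimum
from .economics import EconomicParams, ReferencePoint, reference_table
from .io import (
    assessment_payload,
    assessment_row,
    read_series_csv,
    reference_table_frame,
    sweep_frame,
    tax_table_frame,
)
from .production import BiologicalParams
from .taxes import TaxSchedule, tax_table

__all__ = ["SpeciesResult", "AnalysisReport", "run_pipeline", "write_report"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and species."""


@dataclass(frozen=True)
class SpeciesResult:
    """Everything computed for one species."""

    name: str
    bio: BiologicalParams
    econ: EconomicParams
    assessment: AssessmentResult | None
    reference_points: list[ReferencePoint]  # MSY, MEY, OAE, OSY
    sweep: list[DiscountedOptimum]
    taxes: list[TaxSchedule]


@dataclass(frozen=True)
class AnalysisReport:
    """Full-run results plus provenance (config hash, seed, version)."""

    species: list[SpeciesResult]
    seed: int
    config_hash: str
    version: str = field(default=__version__)


def _config_digest(config: RunConfig) -> str:
    doc = {
        "seed": config.seed,
        "osy_delta": config.osy_delta,
        "deltas": [float(d) for d in config.deltas],
        "species": [
            {
                "name": s.name,
                "params": None
                if s.params is None
                else {"K": s.params.K, "q": s.params.q, "r": s.params.r},
                "series_csv": None if s.series_csv is None else str(s.series_csv),
                "ip": s.ip,
                "n_starts": s.n_starts,
                "economics": {"price": s.econ.price, "unit_cost": s.econ.unit_cost},
            }
            for s in config.species
        ],
    }
    canonical = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str, species: str):
    log.info("[%s] %s", species, name)


def _run_species(spec: SpeciesConfig, config: RunConfig) -> SpeciesResult:
    assessment = None
    if spec.series_csv is not None:
        _stage("fitting dynamic production model", spec.name)
        try:
            series = read_series_csv(spec.series_csv, species=spec.name)
            assessment = fit_dynamic_schaefer(
                series,
                ip=spec.ip,
                n_starts=spec.n_starts,
                seed=config.seed,
            )
        except Exception as err:
            raise PipelineError(f"[{spec.name}] fit stage failed: {err}") from err
        bio = assessment.params
        log.info(
            "[%s] fitted K=%.6g q=%.6g r=%.6g (MSY %.6g t, R^2 %.3f)",
            spec.name,
            bio.K,
            bio.q,
            bio.r,
            assessment.msy,
            assessment.r_squared,
        )
    else:
        bio = spec.params

    try:
        _stage("computing MSY/MEY/OAE reference points", spec.name)
        points = reference_table(bio, spec.econ)
        osy = discounted_optimum(bio, spec.econ, config.osy_delta)
        points.append(
            ReferencePoint(
                regime="OSY",
                effort=osy.e_star,
                harvest=osy.h_star,
                biomass=osy.x_star,
                total_revenue=spec.econ.price * osy.h_star,
                total_cost=spec.econ.unit_cost * osy.e_star,
                rent=osy.profit,
            )
        )
    except Exception as err:
        raise PipelineError(f"[{spec.name}] reference-point stage failed: {err}") from err

    try:
        _stage("sweeping discount rates", spec.name)
        sweep = discount_sweep(bio, spec.econ, config.deltas)
    except Exception as err:
        raise PipelineError(f"[{spec.name}] discount-sweep stage failed: {err}") from err

    try:
        _stage("deriving tax schedules", spec.name)
        taxes = tax_table(bio, spec.econ, osy_delta=config.osy_delta)
    except Exception as err:
        raise PipelineError(f"[{spec.name}] tax stage failed: {err}") from err

    return SpeciesResult(
        name=spec.name,
        bio=bio,
        econ=spec.econ,
        assessment=assessment,
        reference_points=points,
        sweep=sweep,
        taxes=taxes,
    )


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run every configured species through the full analysis chain."""
    results = [_run_species(s, config) for s in config.species]
    return AnalysisReport(
        species=results, seed=config.seed, config_hash=_config_digest(config)
    )


def _report_payload(report: AnalysisReport) -> dict:
    def num(x):
        return None if x is None else ("inf" if math.isinf(x) else float(x))

    def scrub(obj):
        """JSON-safe copy: numpy scalars -> Python floats/bools/ints."""
        if isinstance(obj, dict):
            return {k: scrub(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [scrub(v) for v in obj]
        if isinstance(obj, (bool,)) or obj is None or isinstance(obj, str):
            return obj
        import numpy as np

        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, (int, np.integer)):
            return int(obj)
        if isinstance(obj, (float, np.floating)):
            return num(float(obj))
        return obj

    return scrub({
        "version": report.version,
        "seed": report.seed,
        "config_hash": report.config_hash,
        "species": {
            r.name: {
                "params": {"K": r.bio.K, "q": r.bio.q, "r": r.bio.r},
                "economics": {"price": r.econ.price, "unit_cost": r.econ.unit_cost},
                "assessment": None
                if r.assessment is None
                else assessment_payload(r.assessment),
                "reference_points": [
                    {
                        "regime": p.regime,
                        "effort": p.effort,
                        "harvest": p.harvest,
                        "biomass": p.biomass,
                        "total_revenue": p.total_revenue,
                        "total_cost": p.total_cost,
                        "rent": p.rent,
                    }
                    for p in r.reference_points
                ],
                "sweep": [
                    {
                        "delta": s.delta,
                        "x_star": s.x_star,
                        "h_star": s.h_star,
                        "e_star": s.e_star,
                        "profit": s.profit,
                        "present_value": num(s.present_value),
                    }
                    for s in r.sweep
                ],
                "taxes": [
                    {
                        "regime": t.regime,
                        "landing_tax": t.landing_tax,
                        "effort_tax": t.effort_tax,
                        "target_effort": t.target_effort,
                        "target_harvest": t.target_harvest,
                    }
                    for t in r.taxes
                ],
            }
            for r in report.species
        },
    })


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the report as CSV tables plus a single JSON payload.

    Returns the list of files written: ``report.json``, a parameter table
    (fitted species only), the regime reference table, per-species sweep
    tables and the tax table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    payload = _report_payload(report)
    json_path = out / "report.json"
    json_path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    written.append(json_path)

    fitted = {r.name: r.assessment for r in report.species if r.assessment is not None}
    if fitted:
        import pandas as pd

        frames = [assessment_row(name, res) for name, res in fitted.items()]
        path = out / "parameter_table.csv"
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.12g"
        )
        written.append(path)

    ref_path = out / "reference_table.csv"
    reference_table_frame(
        {r.name: r.reference_points for r in report.species}
    ).to_csv(ref_path, index=False, float_format="%.12g")
    written.append(ref_path)

    for r in report.species:
        path = out / f"sweep_{r.name}.csv"
        sweep_frame(r.sweep).to_csv(path, index=False, float_format="%.12g")
        written.append(path)

    tax_path = out / "tax_table.csv"
    tax_table_frame({r.name: r.taxes for r in report.species}).to_csv(
        tax_path, index=False, float_format="%.12g"
    )
    written.append(tax_path)
    log.info("wrote %d report files to %s", len(written), out)
    return written
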