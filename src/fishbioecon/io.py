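"""CSV/JSON readers and writers for series, tables and fit results.

All numeric output is formatted at 12 significant digits so that any
write-then-read round trip is lossless at that precision, and identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .assessment import AssessmentResult
from .control import DiscountedOptimum
from .economics import ReferencePoint
from .series import CatchEffortSeries
from .taxes import TaxSchedule

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "reference_table_frame",
    "sweep_frame",
    "tax_table_frame",
    "assessment_row",
    "assessment_payload",
]

log = logging.getLogger(__name__)

SERIES_COLUMNS = ["year", "catch_t", "effort_boats"]
_FLOAT_FMT = "%.12g"


class SeriesParseError(ValueError):
    """Malformed series CSV; the message carries offending line numbers."""


def read_series_csv(path: str | Path, species: str | None = None) -> CatchEffortSeries:
    """Strictly parse a ``year,catch_t,effort_boats`` CSV.

    Rejects missing columns, non-numeric cells and duplicate years, naming
    the offending line (header is line 1).  Rows with zero effort but
    positive catch are legal — CPUE is simply undefined there — and are
    reported at WARNING level.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SeriesParseError(f"{path}: missing column(s) {', '.join(missing)}")
    parsed = {}
    for col in SERIES_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise SeriesParseError(
                f"{path}: non-numeric value in column {col!r} at line(s) {lines}"
            )
        parsed[col] = values.to_numpy()
    years = parsed["year"]
    if np.any(years != years.astype(int)):
        raise SeriesParseError(f"{path}: non-integer year values")
    years = years.astype(int)
    dup = pd.Series(years).duplicated()
    if dup.any():
        dup_years = sorted(set(years[dup.to_numpy()]))
        raise SeriesParseError(f"{path}: duplicate year(s) {dup_years}")
    order = np.argsort(years)
    catches = parsed["catch_t"][order]
    efforts = parsed["effort_boats"][order]
    zero_e = (efforts == 0) & (catches > 0)
    if zero_e.any():
        flagged = years[order][zero_e].tolist()
        log.warning(
            "%s: zero effort with positive catch in year(s) %s; CPUE undefined there",
            path,
            flagged,
        )
    return CatchEffortSeries(
        years=years[order], catches=catches, efforts=efforts, species=species
    )


def write_series_csv(series: CatchEffortSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def reference_table_frame(
    points_by_species: dict[str, list[ReferencePoint]]
) -> pd.DataFrame:
    """Regime table with the canonical column layout (one row per regime)."""
    rows = []
    for species, points in points_by_species.items():
        for pt in points:
            rows.append(
                {
                    "species": species,
                    "regime": pt.regime,
                    "effort_boats": pt.effort,
                    "harvest_t": pt.harvest,
                    "biomass_t": pt.biomass,
                    "total_revenue_omr": pt.total_revenue,
                    "total_cost_omr": pt.total_cost,
                    "profit_omr": pt.rent,
                }
            )
    return pd.DataFrame(rows)


def sweep_frame(sweep: list[DiscountedOptimum]) -> pd.DataFrame:
    """Tidy discount-rate sweep for plotting biomass/harvest/effort/profit."""
    return pd.DataFrame(
        {
            "delta": [s.delta for s in sweep],
            "x_star": [s.x_star for s in sweep],
            "h_star": [s.h_star for s in sweep],
            "e_star": [s.e_star for s in sweep],
            "profit": [s.profit for s in sweep],
            "present_value": [
                math.inf if s.pv_infinite else s.present_value for s in sweep
            ],
        }
    )


def tax_table_frame(taxes_by_species: dict[str, list[TaxSchedule]]) -> pd.DataFrame:
    """Species x tax-type table with one column per target regime."""
    rows = []
    for species, schedules in taxes_by_species.items():
        by_regime = {s.regime: s for s in schedules}
        for tax_type, attr in (("landing_tax", "landing_tax"), ("effort_tax", "effort_tax")):
            rows.append(
                {
                    "species": species,
                    "tax_type": tax_type,
                    "msy": getattr(by_regime["MSY"], attr),
                    "mey": getattr(by_regime["MEY"], attr),
                    "osy": getattr(by_regime["OSY"], attr),
                }
            )
    return pd.DataFrame(rows)


def assessment_row(species: str, result: AssessmentResult) -> pd.DataFrame:
    """One assessment as a single-row parameter table (IP, K, q, r, MSY,
    replacement yield, final biomass, R^2)."""
    return pd.DataFrame(
        [
            {
                "species": species,
                "ip": result.ip,
                "K_t": result.params.K,
                "q_per_boat_year": result.params.q,
                "r_per_year": result.params.r,
                "msy_t": result.msy,
                "replacement_yield_t": result.replacement_yield,
                "final_biomass_t": result.final_biomass,
                "r_squared": result.r_squared,
            }
        ]
    )


def assessment_payload(result: AssessmentResult) -> dict:
    """JSON-ready dict of an AssessmentResult (trajectory included)."""
    payload = asdict(result)
    payload["params"] = {
        "K": result.params.K,
        "r": result.params.r,
        "q": result.params.q,
    }
    pred = payload.pop("predicted_catches")
    payload["predicted_catches"] = (
        [float(x) for x in pred] if pred is not None else None
    )
    return payload
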