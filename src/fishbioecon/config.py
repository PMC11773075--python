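"""Run configuration: one JSON document describing a full analysis.

Schema (all keys lowercase)::

    {
      "seed": 1,
      "osy_delta": 0.10,
      "delta_grid": {"start": 0.0, "stop": 1.0, "step": 0.05},   # or a list
      "species": [
        {
          "name": "R_kanagurta",
          "params": {"K": 163745.5, "q": 2.177e-5, "r": 0.260469},
          # ... or instead of "params":
          # "series_csv": "mackerel.csv", "ip": 0.05, "n_starts": 20,
          "economics": {"price": 9599.6, "unit_cost": 8611.9},
          # ... or instead of "economics", an MSY-regime row to invert:
          # "msy_row": {"effort": 5982, "harvest": 10662.65,
          #             "total_revenue": 102357373.5, "total_cost": 51516277.33}
        }
      ]
    }

Every species block must supply exactly one of ``params``/``series_csv`` and
exactly one of ``economics``/``msy_row`` — economics is never defaulted
silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .economics import EconomicParams, ReferencePoint, derive_price_cost
from .production import BiologicalParams

__all__ = ["ConfigError", "SpeciesConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class SpeciesConfig:
    """Inputs for one species: fixed parameters or a series to fit, plus economics."""

    name: str
    params: BiologicalParams | None = None
    series_csv: Path | None = None
    ip: float | None = None
    n_starts: int = 20
    econ: EconomicParams = None

    def __post_init__(self) -> None:
        if (self.params is None) == (self.series_csv is None):
            raise ConfigError(
                f"species {self.name!r}: supply exactly one of 'params' or 'series_csv'"
            )
        if self.econ is None:
            raise ConfigError(
                f"species {self.name!r}: economics missing — supply 'economics' "
                "(price, unit_cost) or an invertible 'msy_row'"
            )


@dataclass(frozen=True)
class RunConfig:
    """Validated whole-run configuration."""

    species: tuple[SpeciesConfig, ...]
    seed: int = 0
    osy_delta: float = 0.10
    deltas: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigError("config lists no species")
        if self.osy_delta < 0:
            raise ConfigError(f"osy_delta must be >= 0, got {self.osy_delta}")
        if any(d < 0 for d in self.deltas):
            raise ConfigError("discount grid values must be >= 0")


def _parse_deltas(spec) -> tuple[float, ...]:
    if spec is None:
        return RunConfig.__dataclass_fields__["deltas"].default
    if isinstance(spec, (list, tuple)):
        return tuple(float(d) for d in spec)
    if isinstance(spec, dict):
        try:
            start, stop, step = spec["start"], spec["stop"], spec["step"]
        except KeyError as err:
            raise ConfigError(f"delta_grid dict needs start/stop/step, missing {err}")
        if step <= 0:
            raise ConfigError("delta_grid step must be positive")
        n = int(round((stop - start) / step))
        return tuple(np.round(start + step * np.arange(n + 1), 12))
    raise ConfigError(f"cannot interpret delta_grid: {spec!r}")


def parse_delta_grid(text: str) -> tuple[float, ...]:
    """Parse a ``start:stop:step`` command-line grid specification."""
    parts = text.split(":")
    if len(parts) != 3:
        raise ConfigError(f"delta grid must be start:stop:step, got {text!r}")
    start, stop, step = (float(p) for p in parts)
    return _parse_deltas({"start": start, "stop": stop, "step": step})


def _species_from_dict(block: dict, base_dir: Path) -> SpeciesConfig:
    if "name" not in block:
        raise ConfigError("species block missing 'name'")
    name = block["name"]
    params = None
    if "params" in block:
        p = block["params"]
        try:
            params = BiologicalParams(K=float(p["K"]), q=float(p["q"]), r=float(p["r"]))
        except (KeyError, TypeError) as err:
            raise ConfigError(f"species {name!r}: bad 'params' block ({err})")
    series_csv = None
    if "series_csv" in block:
        series_csv = (base_dir / block["series_csv"]).resolve()
    if ("economics" in block) == ("msy_row" in block):
        raise ConfigError(
            f"species {name!r}: supply exactly one of 'economics' or 'msy_row'"
        )
    if "economics" in block:
        e = block["economics"]
        try:
            econ = EconomicParams(price=float(e["price"]), unit_cost=float(e["unit_cost"]))
        except (KeyError, TypeError) as err:
            raise ConfigError(f"species {name!r}: bad 'economics' block ({err})")
    else:
        row = block["msy_row"]
        try:
            ref = ReferencePoint(
                regime="MSY",
                effort=float(row["effort"]),
                harvest=float(row["harvest"]),
                biomass=float(row.get("biomass", 0.0)),
                total_revenue=float(row["total_revenue"]),
                total_cost=float(row["total_cost"]),
                rent=float(row["total_revenue"]) - float(row["total_cost"]),
            )
        except (KeyError, TypeError) as err:
            raise ConfigError(f"species {name!r}: bad 'msy_row' block ({err})")
        econ = derive_price_cost(ref)
    return SpeciesConfig(
        name=name,
        params=params,
        series_csv=series_csv,
        ip=block.get("ip"),
        n_starts=int(block.get("n_starts", 20)),
        econ=econ,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Relative series paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as err:
            raise ConfigError(f"{path}: invalid JSON ({err})")
    if "species" not in doc or not isinstance(doc["species"], list):
        raise ConfigError(f"{path}: 'species' must be a non-empty list")
    species = tuple(_species_from_dict(b, path.parent) for b in doc["species"])
    return RunConfig(
        species=species,
        seed=int(doc.get("seed", 0)),
        osy_delta=float(doc.get("osy_delta", 0.10)),
        deltas=_parse_deltas(doc.get("delta_grid")),
    )
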