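"""Synthetic catch–effort series with the structure the assessment assumes.

The generator forward-simulates logistic biomass under a prescribed effort
trajectory, harvests proportionally (C_t = q E_t B_t) and reports catches
with multiplicative log-normal observation error.  The error draw is
mean-one (the -sigma^2/2 bias correction is applied) so that synthetic MSY
is unbiased in recovery experiments, and only the *observed* catch is
noisy — the stock itself is depleted by the true catch, which is exactly
the observation-error model the estimator fits.

Presets for the four Omani stocks mirror the published 31-year (1990–2020)
setting: true parameters from the published assessment and an initial
depletion set to the published initial proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .presets import SPECIES
from .production import BIOMASS_FLOOR_FRACTION, BiologicalParams
from .series import CatchEffortSeries

__all__ = [
    "EffortPath",
    "SimulationConfig",
    "make_effort_path",
    "simulate_fishery",
    "oman_like_scenarios",
]

#: Multiplicative jitter (lognormal sigma) on the one_way_trip plateau.
_TRIP_JITTER_SIGMA = 0.03
#: Default observation error (sd of log catch) for the species presets.
#: A moderate level typical of annual landings statistics.
DEFAULT_OBS_SIGMA = 0.15
_FIRST_YEAR = 1990


@dataclass(frozen=True)
class EffortPath:
    """Per-year fishing effort (boats) over an ordered span of calendar years."""

    years: np.ndarray
    efforts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "efforts", np.asarray(self.efforts, dtype=float))
        if len(self.years) != len(self.efforts):
            raise ValueError("years and efforts must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.efforts < 0):
            raise ValueError("efforts must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Truth and noise settings for one simulated fishery.

    ``initial_depletion`` is B1/K, the first-year stock as a fraction of
    carrying capacity; ``obs_sigma`` the standard deviation of log catch
    error; the simulation is fully determined by ``seed``.
    """

    true_params: BiologicalParams
    initial_depletion: float = 1.0
    obs_sigma: float = DEFAULT_OBS_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_depletion <= 1.0:
            raise ValueError(
                f"initial depletion must be in (0, 1], got {self.initial_depletion}"
            )
        if self.obs_sigma < 0:
            raise ValueError(f"obs_sigma must be >= 0, got {self.obs_sigma}")


def make_effort_path(
    n_years: int,
    pattern: str,
    e_start: float,
    e_end: float | None = None,
    seed: int = 0,
    first_year: int = _FIRST_YEAR,
) -> EffortPath:
    """Build an effort trajectory of a named shape.

    Patterns
    --------
    ``constant``
        Every year at ``e_start``.
    ``ramp``
        Linear interpolation from ``e_start`` to ``e_end``.
    ``one_way_trip``
        The classic fleet-development shape: effort rises linearly from
        ``e_start`` to ``e_end`` over the first two thirds of the series,
        then plateaus with small seeded multiplicative jitter.  This is the
        contrast-rich trajectory a production-model fit needs.
    """
    if n_years < 2:
        raise ValueError(f"need at least 2 years, got {n_years}")
    if e_end is None:
        e_end = e_start
    if e_start < 0 or e_end < 0:
        raise ValueError("efforts must be >= 0")
    years = np.arange(first_year, first_year + n_years)
    if pattern == "constant":
        efforts = np.full(n_years, float(e_start))
    elif pattern == "ramp":
        efforts = np.linspace(e_start, e_end, n_years)
    elif pattern == "one_way_trip":
        n_rise = max(2, (2 * n_years) // 3)
        rise = np.linspace(e_start, e_end, n_rise)
        plateau = np.full(n_years - n_rise, float(e_end))
        efforts = np.concatenate([rise, plateau])
        rng = np.random.default_rng(seed)
        jitter = np.exp(rng.normal(0.0, _TRIP_JITTER_SIGMA, size=n_years))
        efforts = efforts * jitter
    else:
        raise ValueError(
            f"unknown pattern {pattern!r}; expected constant, ramp or one_way_trip"
        )
    return EffortPath(years=years, efforts=efforts)


def simulate_fishery(
    config: SimulationConfig, path: EffortPath
) -> CatchEffortSeries:
    """Simulate observed annual catches under ``config`` along ``path``.

    B1 = initial_depletion * K; each year the true catch q E_t B_t is taken,
    the stock is stepped with the true catch, and the observed catch
    C_t = q E_t B_t * exp(eps_t - sigma^2/2), eps_t ~ N(0, sigma^2) is
    recorded.  If the stock hits its floor the series is still returned
    with ``collapsed`` set.
    """
    p = config.true_params
    rng = np.random.default_rng(config.seed)
    n = len(path.years)
    biomass = config.initial_depletion * p.K
    floor = BIOMASS_FLOOR_FRACTION * p.K
    true_catch = np.empty(n)
    collapsed = False
    for t in range(n):
        true_catch[t] = p.q * path.efforts[t] * biomass
        biomass = biomass + p.r * biomass * (1.0 - biomass / p.K) - true_catch[t]
        if biomass < floor:
            biomass = floor
            collapsed = True
    if config.obs_sigma > 0:
        eps = rng.normal(0.0, config.obs_sigma, size=n)
        observed = true_catch * np.exp(eps - config.obs_sigma**2 / 2.0)
    else:
        observed = true_catch
    return CatchEffortSeries(
        years=path.years,
        catches=observed,
        efforts=path.efforts,
        collapsed=collapsed,
    )


def oman_like_scenarios(
    n_years: int = 31,
    obs_sigma: float = DEFAULT_OBS_SIGMA,
    seed: int = 0,
) -> dict[str, tuple[SimulationConfig, EffortPath]]:
    """Preset (config, effort path) pairs for the four Omani stocks.

    True parameters are each species' published (K, q, r); the initial
    depletion is the published initial proportion (a catch ratio pressed
    into service as B1/K, exactly as in the assessment workflow, so tests
    can probe the consequences of that identification).  Effort follows a
    one-way trip from 30% to 120% of each stock's E_MSY — the historical
    fleet-growth pattern.
    """
    scenarios: dict[str, tuple[SimulationConfig, EffortPath]] = {}
    for i, (name, preset) in enumerate(SPECIES.items()):
        cfg = SimulationConfig(
            true_params=preset.params,
            initial_depletion=preset.ip,
            obs_sigma=obs_sigma,
            seed=seed + i,
        )
        e_msy = preset.params.e_msy
        path = make_effort_path(
            n_years,
            "one_way_trip",
            e_start=0.3 * e_msy,
            e_end=1.2 * e_msy,
            seed=seed + i,
        )
        scenarios[name] = (cfg, path)
    return scenarios
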