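"""Pure Schaefer surplus-production mathematics.

The model couples logistic biomass growth ``dx/dt = r x (1 - x/K)`` with a
proportional harvest rate ``H = q E x`` (catch per unit effort proportional
to stock density).  Everything downstream — equilibrium yield curves,
bioeconomic reference points, discounted optima and tax instruments — is a
closed-form consequence of these two relations, so this module holds the
parameter containers and the handful of primitive evaluations all other
modules build on.

Annual bookkeeping uses the standard difference-equation discretization
``B_{t+1} = B_t + r B_t (1 - B_t/K) - C_t``, which matches how annual
catch-and-effort statistics are fitted in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "BiologicalParams",
    "CpueLine",
    "BiomassState",
    "BIOMASS_FLOOR_FRACTION",
    "growth_increment",
    "catch_rate",
    "step_biomass",
    "equilibrium_yield",
    "cpue_from_effort",
    "cpue_line_from_params",
    "params_from_cpue_line",
]

#: Biomass is clamped at this fraction of K instead of going negative, so a
#: log-normal catch likelihood always sees a positive predicted catch.
BIOMASS_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class BiologicalParams:
    """Logistic-growth/proportional-harvest parameter triple.

    Parameters
    ----------
    K : float
        Carrying capacity (tonnes), the unfished equilibrium biomass. > 0.
    r : float
        Intrinsic (per-capita, low-density) growth rate, 1/year. >= 0.
    q : float
        Catchability coefficient, 1/(boat-year): the fraction of the stock
        taken by one boat in one year. > 0.
    """

    K: float
    r: float
    q: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"carrying capacity K must be positive, got {self.K}")
        if not self.q > 0:
            raise ValueError(f"catchability q must be positive, got {self.q}")
        if self.r < 0:
            raise ValueError(f"intrinsic growth rate r must be >= 0, got {self.r}")

    @property
    def msy(self) -> float:
        """Maximum sustainable yield r*K/4 (tonnes/year)."""
        return self.r * self.K / 4.0

    @property
    def e_msy(self) -> float:
        """Effort producing MSY, r/(2q) (boats)."""
        return self.r / (2.0 * self.q)

    @property
    def e_extinction(self) -> float:
        """Effort r/q at which equilibrium yield falls back to zero (boats)."""
        return self.r / self.q


@dataclass(frozen=True)
class CpueLine:
    """Fitted equilibrium CPUE-vs-effort line ``CPUE = a + b E``.

    Under the Schaefer model at equilibrium, ``a = qK`` (CPUE of the unfished
    stock) and ``b = -q^2 K / r``; a biologically meaningful fishery therefore
    has a > 0 and b < 0.
    """

    a: float
    b: float
    r_squared: float = math.nan


@dataclass(frozen=True)
class BiomassState:
    """Stock biomass in a given calendar year, with a collapse flag."""

    year: int
    biomass: float
    collapsed: bool = False

    def __post_init__(self) -> None:
        if self.biomass < 0:
            raise ValueError(f"biomass must be >= 0, got {self.biomass}")


def growth_increment(biomass: float, params: BiologicalParams) -> float:
    """Logistic surplus production r*x*(1 - x/K) at stock size ``biomass``.

    Zero at x = 0 and x = K, maximal (= r*K/4 = MSY) at x = K/2.
    """
    if biomass < 0:
        raise ValueError(f"biomass must be >= 0, got {biomass}")
    return params.r * biomass * (1.0 - biomass / params.K)


def catch_rate(effort: float, biomass: float, q: float) -> float:
    """Harvest rate q*E*x (tonnes/year), linear in effort and biomass."""
    if effort < 0:
        raise ValueError(f"effort must be >= 0, got {effort}")
    if biomass < 0:
        raise ValueError(f"biomass must be >= 0, got {biomass}")
    if q < 0:
        raise ValueError(f"catchability must be >= 0, got {q}")
    return q * effort * biomass


def step_biomass(
    state: BiomassState, catch: float, params: BiologicalParams
) -> BiomassState:
    """Advance the stock one year: B + r*B*(1 - B/K) - catch.

    The result is floored at ``BIOMASS_FLOOR_FRACTION * K``; hitting the floor
    sets ``collapsed`` (once collapsed, the flag is sticky).
    """
    if catch < 0:
        raise ValueError(f"catch must be >= 0, got {catch}")
    nxt = state.biomass + growth_increment(state.biomass, params) - catch
    floor = BIOMASS_FLOOR_FRACTION * params.K
    collapsed = state.collapsed
    if nxt < floor:
        nxt = floor
        collapsed = True
    return replace(state, year=state.year + 1, biomass=nxt, collapsed=collapsed)


def equilibrium_yield(effort, params: BiologicalParams):
    """Sustainable yield parabola H(E) = qEK(1 - qE/r) = qEK - q^2 E^2 K / r.

    Accepts a scalar or array effort.  Roots at E = 0 and E = r/q; the raw
    parabola is returned (negative beyond r/q) so callers and oracle tests can
    see the full curve — reference-point code only evaluates it on [0, r/q].
    """
    import numpy as np

    e = np.asarray(effort, dtype=float)
    if np.any(e < 0):
        raise ValueError("effort must be >= 0")
    if params.r == 0:
        if np.any(e > 0):
            raise ValueError("equilibrium yield undefined for r = 0 with E > 0")
        return e * 0.0 if e.ndim else 0.0
    h = params.q * e * params.K * (1.0 - params.q * e / params.r)
    return float(h) if h.ndim == 0 else h


def cpue_from_effort(effort: float, line: CpueLine) -> float:
    """Equilibrium catch-per-unit-effort a + b*E (tonnes/boat)."""
    return line.a + line.b * effort


def cpue_line_from_params(params: BiologicalParams) -> CpueLine:
    """Forward map (K, r, q) -> (a, b) = (qK, -q^2 K / r)."""
    if params.r == 0:
        raise ValueError("CPUE line slope undefined for r = 0")
    return CpueLine(
        a=params.q * params.K,
        b=-(params.q**2) * params.K / params.r,
        r_squared=1.0,
    )


def params_from_cpue_line(line: CpueLine, q: float) -> BiologicalParams:
    """Invert the CPUE line given an external catchability: K = a/q, r = -aq/b.

    Raises
    ------
    ValueError
        If a <= 0 or b >= 0 (no downward CPUE response: the equilibrium
        parabola has no biologically meaningful maximum).
    """
    if q <= 0:
        raise ValueError(f"catchability q must be positive, got {q}")
    if line.a <= 0 or line.b >= 0:
        raise ValueError(
            "CPUE line must have positive intercept and negative slope "
            f"(got a={line.a}, b={line.b})"
        )
    return BiologicalParams(K=line.a / q, r=-line.a * q / line.b, q=q)
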