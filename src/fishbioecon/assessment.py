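"""Surplus-production stock assessment from catch–effort series.

Two complementary estimators are provided:

* :func:`fit_dynamic_schaefer` — the dynamic (non-equilibrium) fit: biomass
  is projected with the annual Schaefer difference equation from a starting
  stock B1 = IP * K, predicted catches q E_t B_t are compared with observed
  catches under a log-normal observation-error likelihood, and (K, q, r)
  minimize the sum of squared log residuals by seeded multi-start
  derivative-free search.  This mirrors the workflow of catch-and-effort
  assessment software with a log-normal error model and an
  initial-proportion input.
* :func:`fit_equilibrium_cpue` — the classical equilibrium shortcut:
  ordinary least squares of CPUE on effort.  Under equilibrium assumptions
  CPUE = qK - (q^2 K / r) E, so the fitted line yields E at maximum yield
  (-a/2b) and the maximum yield (-a^2/4b) with no external information, and
  the full (K, r) given an external catchability.

The "initial proportion" passed to the dynamic fit is, by convention,
first-year catch over maximum catch (:func:`compute_ip`) pressed into
service as the initial depletion B1/K.  Those are different quantities; the
convention is reproduced deliberately, not endorsed — pass an explicit
``ip`` to decouple them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize

from .production import BIOMASS_FLOOR_FRACTION, BiologicalParams, CpueLine
from .series import CatchEffortSeries

__all__ = [
    "EstimationError",
    "AssessmentResult",
    "EquilibriumCpueFit",
    "ParameterBounds",
    "compute_ip",
    "fit_dynamic_schaefer",
    "fit_equilibrium_cpue",
    "replacement_yield",
]


class EstimationError(RuntimeError):
    """Raised when a fit cannot produce biologically meaningful parameters."""


@dataclass(frozen=True)
class ParameterBounds:
    """Search box for (K, q, r); optimization runs in log space inside it."""

    k_lo: float
    k_hi: float
    q_lo: float = 1e-8
    q_hi: float = 1e-2
    r_lo: float = 0.01
    r_hi: float = 2.0

    @classmethod
    def from_series(cls, series: CatchEffortSeries) -> "ParameterBounds":
        cmax = float(np.max(series.catches))
        if cmax <= 0:
            raise EstimationError("series has no positive catches")
        return cls(k_lo=cmax, k_hi=100.0 * cmax)


@dataclass(frozen=True)
class AssessmentResult:
    """Dynamic-fit output: parameters, derived yields and diagnostics."""

    params: BiologicalParams
    ip: float
    msy: float  # r K / 4 of the fitted parameters
    replacement_yield: float  # surplus production at the final biomass
    final_biomass: float  # stock in the last modeled year
    r_squared: float  # on ln(catch), observed vs predicted
    loss: float  # minimized sum of squared log-catch residuals
    converged: bool
    at_bounds: bool  # any parameter within ~0.1% (log) of its bound
    identifiable: bool  # False when equally good optima disagree on K
    n_starts: int
    predicted_catches: np.ndarray = field(compare=False, repr=False, default=None)


@dataclass(frozen=True)
class EquilibriumCpueFit:
    """OLS CPUE-on-effort line with its q-free reference quantities.

    ``ok`` is False when the slope is non-negative: CPUE does not decline
    with effort, so the equilibrium yield parabola has no interior maximum
    and ``e_at_max``/``yield_at_max`` are NaN.
    """

    line: CpueLine
    e_at_max: float  # -a/(2b) = r/(2q) on the model line
    yield_at_max: float  # -a^2/(4b) = rK/4 on the model line
    ok: bool
    n_points: int

    def params_given_q(self, q: float) -> BiologicalParams:
        """K = a/q and r = -aq/b, using an externally supplied catchability."""
        from .production import params_from_cpue_line

        if not self.ok:
            raise EstimationError(
                "CPUE slope is non-negative; equilibrium parameters undefined"
            )
        return params_from_cpue_line(self.line, q)


def compute_ip(series: CatchEffortSeries) -> float:
    """Initial proportion: first-year catch divided by the maximum catch."""
    if len(series) == 0:
        raise EstimationError("empty series")
    cmax = float(np.max(series.catches))
    if cmax <= 0:
        raise EstimationError("all catches are zero; initial proportion undefined")
    return float(series.catches[0]) / cmax


def replacement_yield(final_biomass: float, params: BiologicalParams) -> float:
    """Surplus production r B (1 - B/K) at the final biomass: the catch that
    would hold the stock exactly where it is."""
    if final_biomass < 0:
        raise ValueError(f"biomass must be >= 0, got {final_biomass}")
    return params.r * final_biomass * (1.0 - final_biomass / params.K)


def _project(K, q, r, ip, efforts, obs, condition_on_observed):
    """Predicted catches and final biomass under the annual difference map."""
    b = ip * K
    floor = BIOMASS_FLOOR_FRACTION * K
    pred = np.empty(len(efforts))
    for t in range(len(efforts)):
        chat = q * efforts[t] * b
        pred[t] = chat
        removal = obs[t] if condition_on_observed else chat
        b = b + r * b * (1.0 - b / K) - removal
        if b < floor:
            b = floor
    return pred, b


def _final_year_biomass(K, q, r, ip, efforts, obs, condition_on_observed):
    """Biomass at the start of the last observed year (the stock that
    produced the final catch)."""
    b = ip * K
    floor = BIOMASS_FLOOR_FRACTION * K
    for t in range(len(efforts) - 1):
        chat = q * efforts[t] * b
        removal = obs[t] if condition_on_observed else chat
        b = b + r * b * (1.0 - b / K) - removal
        if b < floor:
            b = floor
    return b


def fit_dynamic_schaefer(
    series: CatchEffortSeries,
    ip: float | None = None,
    bounds: ParameterBounds | None = None,
    n_starts: int = 20,
    seed: int = 0,
    condition_on_observed: bool = False,
) -> AssessmentResult:
    """Fit (K, q, r) to a catch–effort series under log-normal catch error.

    Parameters
    ----------
    series
        At least 10 years of annual catch and effort.
    ip
        Initial depletion B1/K supplied to the projection.  Defaults to
        :func:`compute_ip` of the series (the catch-ratio convention).
    bounds
        Parameter box; defaults to K in [max catch, 100 max catch],
        q in [1e-8, 1e-2], r in [0.01, 2].
    n_starts
        Number of seeded log-uniform starting points for the local search
        (Nelder-Mead in log space, best-of-starts, with a polishing restart).
    condition_on_observed
        If True the biomass projection removes the observed catch each year
        instead of the model-predicted catch.  The default (predicted catch)
        is the pure observation-error estimator.

    Raises
    ------
    EstimationError
        If no start converges to a finite loss.
    """
    if len(series) < 10:
        raise EstimationError(
            f"dynamic fit needs >= 10 years of data, got {len(series)}"
        )
    mask = (series.efforts > 0) & (series.catches > 0)
    if mask.sum() < 10:
        raise EstimationError("fewer than 10 usable (positive catch and effort) years")
    if ip is None:
        ip = compute_ip(series)
    if not 0 < ip <= 1:
        raise EstimationError(f"initial proportion must be in (0, 1], got {ip}")
    if bounds is None:
        bounds = ParameterBounds.from_series(series)

    efforts = np.ascontiguousarray(series.efforts, dtype=float)
    obs = np.ascontiguousarray(series.catches, dtype=float)
    log_obs = np.log(obs[mask])

    lo = np.log([bounds.k_lo, bounds.q_lo, bounds.r_lo])
    hi = np.log([bounds.k_hi, bounds.q_hi, bounds.r_hi])

    def objective(z):
        K, q, r = np.exp(z)
        pred, _ = _project(K, q, r, ip, efforts, obs, condition_on_observed)
        resid = np.log(pred[mask]) - log_obs
        return float(resid @ resid)

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    starts += list(rng.uniform(lo, hi, size=(max(0, n_starts - 1), 3)))
    box = list(zip(lo, hi))

    best = None
    solutions = []
    for z0 in starts:
        res = minimize(
            objective,
            z0,
            method="Nelder-Mead",
            bounds=box,
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
        )
        if not math.isfinite(res.fun):
            continue
        solutions.append((res.fun, np.exp(res.x), res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise EstimationError("all optimization starts failed to converge")
    # polish: restart the simplex at the incumbent optimum
    polish = minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        bounds=box,
        options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000},
    )
    if polish.fun <= best.fun:
        best = polish

    K, q, r = np.exp(best.x)
    params = BiologicalParams(K=K, r=r, q=q)
    pred, _ = _project(K, q, r, ip, efforts, obs, condition_on_observed)
    final_b = _final_year_biomass(K, q, r, ip, efforts, obs, condition_on_observed)
    log_pred = np.log(pred[mask])
    ss_res = float(np.sum((log_obs - log_pred) ** 2))
    ss_tot = float(np.sum((log_obs - log_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    if math.isfinite(r2):
        r2 = min(max(r2, 0.0), 1.0)

    at_bounds = bool(
        np.any(best.x - lo < 1e-3 * (hi - lo)) or np.any(hi - best.x < 1e-3 * (hi - lo))
    )
    # flat-loss probe: near-optimal starts that disagree materially on K
    tol = max(1e-9, 1e-6 * abs(best.fun))
    near = [p for f, p, _ in solutions if f <= best.fun + tol]
    identifiable = True
    if len(near) >= 2:
        ks = [float(p[0]) for p in near]
        identifiable = bool(max(ks) / min(ks) < 1.5)
    if at_bounds:
        identifiable = False

    return AssessmentResult(
        params=params,
        ip=float(ip),
        msy=params.msy,
        replacement_yield=replacement_yield(final_b, params),
        final_biomass=final_b,
        r_squared=r2,
        loss=float(best.fun),
        converged=bool(best.success),
        at_bounds=at_bounds,
        identifiable=identifiable,
        n_starts=len(starts),
        predicted_catches=pred,
    )


def fit_equilibrium_cpue(series: CatchEffortSeries) -> EquilibriumCpueFit:
    """OLS of CPUE on effort: CPUE = a + b E, with q-free reference points."""
    mask = series.efforts > 0
    if mask.sum() < 3:
        raise EstimationError("equilibrium regression needs >= 3 positive-effort years")
    e = series.efforts[mask]
    cpue = series.catches[mask] / e
    model = sm.OLS(cpue, sm.add_constant(e)).fit()
    a, b = float(model.params[0]), float(model.params[1])
    r2 = float(model.rsquared)
    line = CpueLine(a=a, b=b, r_squared=r2)
    ok = b < 0 and a > 0
    if ok:
        e_at_max = -a / (2.0 * b)
        yield_at_max = -(a**2) / (4.0 * b)
    else:
        e_at_max = yield_at_max = math.nan
    return EquilibriumCpueFit(
        line=line,
        e_at_max=e_at_max,
        yield_at_max=yield_at_max,
        ok=ok,
        n_points=int(mask.sum()),
    )
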