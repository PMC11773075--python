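# Methods

## Model and assumptions

The package implements the Gordon–Schaefer bioeconomic model: a single
homogeneous stock with logistic surplus production (carrying capacity K in
tonnes, intrinsic growth rate r per year), harvested at rate H = qEx by a
fleet of E identical boats with constant catchability q (per boat-year).
Price p (OMR/tonne) and unit effort cost c (OMR/boat-year) are constant —
no demand response, no fleet heterogeneity, no technical interaction
between species; each stock is analyzed independently. All regime formulas
(MSY, MEY, open access, discounted OSY, taxes) are closed forms in
(K, r, q, p, c) and the discount rate δ; they are exact consequences of the
model, so their numerical verification is against brute-force grid and
root-finding oracles rather than against alternative estimators.

Although the growth model is written in continuous time, annual data are
fitted and simulated with the standard difference equation

    B_{t+1} = B_t + r B_t (1 − B_t/K) − C_t,

which matches annual catch bookkeeping. For r < 1 (all stocks considered
here) the discrete map is monotone and free of overshoot artifacts.
Biomass is floored at 10⁻⁶·K with a sticky `collapsed` flag instead of
going negative, so a log-normal likelihood always sees positive predicted
catch.

## Estimation

`fit_dynamic_schaefer` is an observation-error estimator: biomass is
projected from B₁ = IP·K using the model-predicted catch q·E_t·B_t in the
update (a switch allows conditioning on observed catch for sensitivity),
and (K, q, r) minimize Σ_t [ln C_t − ln(q E_t B_t)]². The initial
proportion IP is, by the conventional workflow this reproduces, the
first-year catch divided by the maximum catch. That quantity is a catch
ratio, not a biomass depletion, and pressing it into the B₁/K slot is an
approximation inherited from practice; the two are kept distinct in the
API (`compute_ip` vs the `ip` argument) so users can supply a proper
depletion prior instead.

The optimizer is a seeded multi-start Nelder–Mead search in log-parameter
space within the box K ∈ [max catch, 100·max catch], q ∈ [1e-8, 1e-2],
r ∈ [0.01, 2] (20 starts by default: one at the box center, the rest
log-uniform), followed by a simplex restart at the incumbent for polish.
Fits are flagged `at_bounds` when any parameter ends within 0.1% (in log
units) of its bound, and `identifiable=False` when near-optimal starts
disagree on K by more than 50% (a flat likelihood ridge — the classic
failure mode of contrast-poor, e.g. constant-effort, series) or when the
fit is at bounds. R² is reported on ln(catch), consistent with the
log-normal loss.

`fit_equilibrium_cpue` is the classical equilibrium shortcut (OLS of CPUE
on effort, via statsmodels); it requires no q to give the yield-maximizing
effort −a/2b and maximum yield −a²/4b, but inherits the well-known
equilibrium-assumption bias and is provided as a cross-check, not the
primary estimator.

## Synthetic data

The generator emulates what the estimator assumes: logistic dynamics,
proportional harvest, and multiplicative log-normal *observation* error on
catch. The error is bias-corrected (exp(ε − σ²/2), ε ~ N(0, σ²)) so
observed catch is mean-one around the true catch and synthetic MSY is
unbiased in recovery studies; the stock is depleted by the true catch.
Default length is 31 years (mirroring a 1990–2020 annual series), default
observation σ is 0.15 — a moderate level for national landings statistics;
recovery experiments also use σ = 0.2. The bundled species scenarios use
each stock's published (K, q, r), the published initial proportion as the
initial depletion, and a "one-way trip" effort trajectory rising from 30%
to 120% of E_MSY over two thirds of the series with 3% log-normal jitter on
the plateau — contrast-rich by construction.

What the generator does *not* emulate: process error in the dynamics,
time-varying catchability, price/cost stochasticity, age structure,
multispecies interaction. Passing recovery tests therefore demonstrates
estimator correctness under the model's own assumptions, not robustness of
the assessment to real-world violations of them.

## Economics and presets

Price and cost per species are configuration, never defaulted. Because the
underlying cost survey is not itemized publicly, the presets back-derive
them from each stock's published MSY-regime row as p = TR/H and c = TC/E
(`derive_price_cost`); this reproduces the published MEY/OAE rows to within
rounding of the printed inputs. The open-access biomass is reported as
c/(pq); the corresponding printed table cells are inconsistent with that
formula under the same table's implied p and c, so they are computed but
never asserted. Taxes are static equilibrium identities evaluated at the
target regime; negative values (targets beyond open access, i.e. subsidies)
are returned flagged rather than clamped.

## Discounted optimum

The singular-path optimal stock uses the Clark closed form

    x*(δ) = (K/4)[(1 + θ − δ/r) + √((1 + θ − δ/r)² + 8θδ/r)],  θ = c/(pqK),

pinned down by its limits (δ=0 → MEY stock; δ→∞ → open-access stock) and
verified against numerical root-finding on the golden-rule marginal
condition F′(x) + cF(x)/(qx²(p − c/(qx))) = δ to 1e-6 relative over
thousands of random parameter draws. Present value is π/δ, reported as a
flagged infinity at δ = 0 (the sustained-rent interpretation remains
useful). The adjoint/switching machinery of the underlying optimal-control
derivation has no runtime representation — only the closed form is needed.
The OSY regime used in reference and tax tables defaults to δ = 0.10, the
lower end of the 10–20% band conventionally recommended for long-horizon
fishery planning; it is configurable everywhere, and
`control.match_delta_to_taxes` grid-scans which δ best explains an
externally given OSY tax pair.

## Numerical choices

- Optimization and simulation are deterministic given seeds
  (`numpy.random.default_rng`); reports embed the config hash and seed and
  regenerate byte-identically.
- `equilibrium_yield` deliberately returns the raw parabola (negative
  beyond E = r/q) so oracle tests see the full curve; regime code only
  evaluates it on [0, r/q].
- θ ≥ 1 (fishing never profitable) yields structured infeasible results
  (zero-effort points, errors from the OSY solver) instead of negative
  efforts.
- r = 0 is allowed in the dynamics (no growth) but rejected where formulas
  divide by r (yield parabola with E > 0, CPUE line, OSY).
- CSV output uses 12 significant digits; round trips are lossless at that
  precision.

## Problem sizes

Recovery studies use 31-year series; the noise-free property check runs 50
random scenarios (4 starts each) and the noisy Monte-Carlo study 100
replicates at σ = 0.2 (6 starts each) — sizes chosen to make the median-
error statistic stable while keeping the default suite quick. Grid oracles
use 2×10⁴–4×10⁴ effort points; the closed-form-vs-oracle comparison for
x*(δ) uses 1000 random draws.

## Known limitations

- The dynamic fit's identifiability flag is a heuristic (multi-start
  disagreement + bound proximity), not a formal rank test of the
  likelihood.
- No confidence intervals on fitted parameters (a bootstrap would slot in
  naturally above `fit_dynamic_schaefer`).
- Equilibrium reference points presume the stock has settled; transient
  approach paths to x* are out of scope, as are stochastic dynamic
  programs and dynamic tax phase-ins.
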