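# Methods

## Model structure and assumptions

The digestion chain is reduced to three biological steps — hydrolysis,
acidogenesis, methanogenesis — carried by three biomass pools (X_h, X_v,
X_m), with all concentrations expressed as COD (kg COD/m³ ≡ g COD/L) and
time in days.  Uptake is Contois-type: the rate saturates in substrate *per
biomass* (denominator K_s·X + S), which is appropriate for particulate
hydrolysis and keeps the specific rate bounded by k_m.  Biomass decay is
first order and recycles into the particulate pool, where it is re-digested.
Volatile fatty acids are lumped into a single pool; there is no pH, ammonia,
hydrogen or gas-phase sub-model, and temperature is fixed at the assay's
35 °C (no temperature-correction kinetics).

LCFA (S_fa) is a *tracking* pool: a fraction f_fa of the hydrolysis flux is
logged as LCFA alongside its inclusion in the hydrolysate pool, and LCFA
uptake has no product term.  S_fa therefore influences the dynamics only
through the inhibition factors and is excluded from the COD balance.  The
calcium pool S_Ca is the dose expressed as LCFA-binding-equivalent COD
(one Ca²⁺ binds two LCFA molecules, so a molar dose of r maps to 2·r times
the potential LCFA pool) and is constant in time — no precipitation or
dissolution dynamics.

### Inhibition factors

Each step's rate is multiplied by a non-competitive inhibition factor built
on the ratio of adsorption capacity to free LCFA,
K_i = K_i,fa·R/(K_i,fa·R + S_fa) with R = (a·X_tot + b·S_Ca)/S_fa.  As
printed this is 0/0 at S_fa = 0, so the implementation uses the
algebraically identical form K_i,fa·C/(K_i,fa·C + S_fa²), C = a·X_tot +
b·S_Ca, whose limits are the physically meaningful ones: exactly 1 with no
LCFA, exactly 0 when LCFA is present but there is neither biomass nor
calcium to adsorb it.  The factor is strictly increasing in X_tot and S_Ca
and strictly decreasing in S_fa (for S_fa > 0); these properties are
enforced by tests on 10⁴ random states.

### COD bookkeeping

In this formulation the product pools receive the *full* uptake flux while
biomass additionally grows by Y·flux, so the plain pool sum is not
conserved: d(ΣS + ΣX)/dt = Y_h·ρ_h + Y_v·ρ_a + Y_m·ρ_m.  Rather than
silently alter the printed fluxes, the integrator carries the cumulative
yield term as an auxiliary quadrature state and `cod_report` checks closure
of the *balance* — pool sum minus initial sum minus growth credit — which
must hold to 1e-6 relative (it holds to ~1e-15 at the default tolerances,
and a deliberately broken right-hand side is flagged).  Two consequences
worth knowing: total methane at completion exceeds the initial COD by the
yield amplification of repeated decay-recycle passes, so simulated SMP runs
above the measured scale; this is a property of the equation set, not of
the integrator.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| km_p, km_h, km_fa, km_v | max specific uptake (hydrolysis, acidogenesis, LCFA uptake, methanogenesis) | 1/d | 10, 20, 6, 20 |
| Ks_p, Ks_h, Ks_fa, Ks_v | Contois half-saturation | COD/COD | 0.5 each |
| Y_h, Y_v, Y_m | biomass yields | kgCOD/kgCOD | 0.05 each |
| kd_h, kd_v, kd_m | first-order decay | 1/d | 0.8, 0.8, 0.05 |
| f_fa | LCFA fraction of hydrolysis flux | – | 0.35 (NS1), 0.11 (NS2) |
| Khfa, Kvfa, Kmfa | inhibition constants | kg COD/m³ | 5 each |
| a, b | weights on biomass / calcium in the inhibition ratio | – | 0.5, 0.5 |

Eight of these — km_v, Y_m, kd_m, Khfa, Kvfa, Kmfa, a, b — are the
calibration targets; the rest are literature-style constants held fixed.

### Experiment conventions

* Substrate COD content defaults to 2.83 g COD/g VS, back-derived so that
  f_fa × 10 gVS/L × cod_vs reproduces the measured LCFA pools of both
  substrates (9.9 and 3.1 g COD/L); it is configurable per substrate.
* Inoculum biomass COD defaults to 1.42 g COD/g VS with active fraction 1.0.
* The inoculum's active COD is split (X_h, X_v, X_m) = (0.6, 0.2, 0.2).
  This is a deliberate design choice: LCFA can only accumulate when the
  hydrolytic LCFA source outruns the uptake capacity, i.e. when
  X_h/X_v > km_fa/(f_fa·km_p) (≈1.7 for the high-lipid substrate at the
  reference kinetics).  An even split never satisfies this, so the model
  would show no LCFA accumulation — and hence no inhibition and no calcium
  response — at any batch condition, contradicting the phenomenon the model
  exists to describe; community profiles of such digesters are dominated by
  hydrolytic/acidogenic bacteria, which supports a hydrolytic-heavy split.
  The split is configurable.
* Methane volume conversion defaults to 0.35 L CH4/g COD (STP; 0.395 at
  35 °C is available via `UnitConversions`).
* The "biomass:LCFA" axis of the response-surface sweep is inoculum COD
  relative to potential-LCFA COD; the calcium axis is the molar Ca:LCFA
  dose.  The Ca:lipid and Ca:LCFA ratios are treated as the same quantity
  (lipids hydrolyse to LCFA ~1:1 by COD in this model).

## Synthetic BMP generator

The generator emulates the assay grid (2 substrates × I/S {0.1, 0.4, 1.0} ×
Ca {0, 0.5, 1, 2}, 10 gVS/L, daily readings for 20 days): each bottle is
simulated at the ground-truth parameters, sampled daily, and multiplicative
Gaussian noise (relative s.d. 5% by default) is applied to the *daily
increments*; increments are clipped at zero and re-cumulated, so curves are
non-decreasing at any noise level, and clipping bias is negligible at the
default noise (verified by Monte Carlo to within 1% on the final volume).
Everything is driven by one `numpy` seed; regeneration is bit-identical.
What it does not emulate: gas-volume temperature/pressure corrections, CO2
scrubbing artefacts, irregular reading times, bottle-to-bottle inoculum
variability, or any systematic (non-zero-mean) measurement error — so
passing recovery tests show that the estimator works on data generated by
the model itself, not that the model is correct for real assays.

## Calibration

The loss is the sum of squared differences between simulated and observed
cumulative methane volume over all curves and observation days (unweighted
by default; a per-curve max-normalised weighting is available and is the
appropriate choice when the noise is relative, as in the synthetic data).
Optimisation uses bound-constrained trust-region least squares (`scipy`
`least_squares`, TRF) with default bounds (0.1×, 10×) around the start and
a, b capped at 1; finite-difference Jacobians use a 1e-4 relative step,
comfortably above the 1e-7 integration tolerance of the fast simulation
path.  Fits are deterministic given the start; multi-start is available via
an explicit seed list.  Non-convergence is reported, never silent.

**Identifiability.** The inhibition block carries an exact one-parameter
scale invariance: K_i,fa → c·K_i,fa, a → a/c, b → b/c leaves every
trajectory unchanged, because the model depends on the block only through
the products K_i,fa·a and K_i,fa·b.  No data can pin the scale, and the
optimizer cannot move along (or remove initial error along) this flat
direction.  `gauge_align` maps an estimate onto the convention in which `a`
takes a chosen reference value; estimates should be compared after this
alignment, and `recovery_errors` does so by default.  Joint fitting across
all curves of a study is the default; per-condition fits (which yield
condition-dependent inhibition constants) are a matter of passing subsets
of curves.

## Sensitivity screen

The relative–relative sensitivity δ = (Δy/y0)/(Δp/p0) is computed by
central difference under a ±50% default perturbation (a −100% perturbation
would zero the parameter, so the ±100% variant is one-sided and reported
alongside).  The reciprocal orientation (Δp/p)/(Δy/y) is available behind a
flag.  The default output functional is the final (day-20) cumulative
methane volume of a reference bottle — high-lipid substrate, I/S = 1.0,
Ca:LCFA = 0.5; calcium must be present in the scenario or the weight b has
no pathway to the output and screens at exactly zero.  The functional is
configurable (any callable from parameters to a scalar), and δ is undefined
(raised as an error) when the baseline output is zero.  A caveat the screen
itself reports: at the reference parameter values the day-20 output is
dominated by the upstream chain kinetics (hydrolysis/acidogenesis rates and
yields), and several calibration targets screen low — the partition between
"fixed" and "estimated" parameters is a property of the operating point,
not of the model structure.

## Numerics

* Default integrator: LSODA (stiff-capable, adaptive) at rtol 1e-9,
  atol 1e-12, reporting on a daily grid; the calibration fast path uses
  rtol 1e-7, atol 1e-9.
* Reported states are clipped to zero only within 1e-10; any larger
  negative excursion raises an integration error with solver diagnostics.
  S_m is analytically non-decreasing; sub-tolerance solver ripple is
  removed by a running maximum.
* Contois terms evaluate to zero when substrate or biomass is zero
  (empty-reactor fixed point is exact).
* A fixed-step RK4 integrator (`integrate_fixed_step`, default dt 1e-3 d)
  is kept as an independent numerical cross-check; the adaptive solution of
  the reference bottle agrees with it to better than 1e-4 relative over
  20 days.
* Response-surface sweeps flag failed cells instead of aborting.

## Known limitations

* The printed equation set is not COD-closed (see bookkeeping above);
  absolute methane volumes and SMP values are therefore upper-shifted
  relative to measured scales, and comparisons should be made within the
  model (across conditions), not against measured SMP directly.
* LCFA uptake destroys tracked LCFA without producing VFA (no β-oxidation
  product term); the LCFA pool is diagnostic, not a mass-balanced species.
* The inhibition-block scale is not identifiable (gauge invariance above);
  reported constants are meaningful only under a stated normalisation.
* Local, one-at-a-time sensitivities only; no global (Sobol/Morris)
  analysis.
* Calcium chemistry is reduced to a constant binding-equivalent pool;
  dose-dependent delays in LCFA turnover appear only through the inhibition
  ratio, and the SMP surface can decrease marginally (order 0.1%) along the
  calcium axis past the 0.5 coverage dose.
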