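"""Parameter estimation from cumulative methane curves.

Eight parameters are estimated from batch BMP curves by bound-constrained
nonlinear least squares: the methanogenesis kinetics ``km_v``, ``Y_m``,
``kd_m`` and the inhibition block ``Khfa``, ``Kvfa``, ``Kmfa``, ``a``, ``b``.
The loss is the unweighted sum of squared differences between simulated and
observed cumulative methane volume, summed over all curves and observation
days; a per-curve max-normalised weighting is available.

Identifiability note: the inhibition constants and the weights ``a``, ``b``
enter the model only through the products ``K_ifa·a`` and ``K_ifa·b``, so the
block carries an exact one-parameter scale invariance (multiply the three
constants by ``c`` and divide ``a``, ``b`` by ``c``).  The data cannot pin
that scale; :func:`gauge_align` maps an estimate onto the convention in which
``a`` takes a chosen reference value, which is how estimates should be
compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .experiment import (
    DEFAULT_CONVERSIONS,
    BatchConfig,
    InoculumSpec,
    MethaneCurve,
    SubstrateSpec,
    initial_state,
)
from .model import _rhs_core
from .params import ESTIMATED_PARAMETERS, ModelParameters

__all__ = [
    "CalibrationDataset",
    "FitResult",
    "simulate_curve_volumes",
    "objective",
    "fit",
    "gauge_align",
    "recovery_errors",
    "default_bounds",
]

#: Parameters participating in the inhibition-block scale invariance.
GAUGE_SCALED = ("Khfa", "Kvfa", "Kmfa")
GAUGE_INVERSE = ("a", "b")


@dataclass(frozen=True)
class CalibrationDataset:
    """One observed curve with the bottle specification that produced it."""

    substrate: SubstrateSpec
    config: BatchConfig
    curve: MethaneCurve
    inoculum: InoculumSpec = field(default_factory=InoculumSpec)


@dataclass
class FitResult:
    """Outcome of a least-squares calibration."""

    values: dict[str, float]
    cost: float                      # sum of squared residuals, (L CH4/L)^2
    residuals: np.ndarray
    success: bool
    nfev: int
    message: str
    free_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    init: dict[str, float]

    def aligned(self, reference_a: float = 0.5) -> dict[str, float]:
        """Estimates mapped onto the ``a = reference_a`` gauge convention."""
        return gauge_align(self.values, reference_a)


def simulate_curve_volumes(
    params: ModelParameters,
    substrate: SubstrateSpec,
    inoculum: InoculumSpec,
    config: BatchConfig,
    days: np.ndarray,
    conversions=DEFAULT_CONVERSIONS,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> np.ndarray:
    """Cumulative methane volume at the observation days (fast path).

    Lighter tolerances than the reporting integrator; adequate for the loss
    surface, whose curvature far exceeds the integration error.
    """
    days = np.asarray(days, dtype=float)
    p = substrate.parameters(params)
    y0 = initial_state(substrate, inoculum, config, conversions).as_array()
    sol = solve_ivp(lambda _t, y: _rhs_core(p, y), (0.0, float(days[-1])), y0,
                    t_eval=days, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return np.maximum(sol.y[4], 0.0) * conversions.ch4_l_per_gcod


def _residuals(
    x: np.ndarray,
    free_names: Sequence[str],
    datasets: Sequence[CalibrationDataset],
    base: ModelParameters,
    conversions,
    weights: Sequence[float] | None,
    strict: bool,
    penalty: float,
    rtol: float,
    atol: float,
) -> np.ndarray:
    params = base.replace(**dict(zip(free_names, map(float, x))))
    out = []
    for k, ds in enumerate(datasets):
        w = 1.0 if weights is None else weights[k]
        try:
            sim = simulate_curve_volumes(params, ds.substrate, ds.inoculum,
                                         ds.config, ds.curve.days, conversions,
                                         rtol=rtol, atol=atol)
        except RuntimeError:
            if strict:
                raise
            out.append(np.full(len(ds.curve), penalty))
            continue
        out.append(w * (sim - ds.curve.volume))
    return np.concatenate(out)


def objective(
    free_values: Mapping[str, float],
    datasets: Sequence[CalibrationDataset],
    base: ModelParameters | None = None,
    conversions=DEFAULT_CONVERSIONS,
    weighted: bool = False,
    strict: bool = False,
    penalty: float = 1e3,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> float:
    """Sum of squared residuals of simulated vs. observed methane volume."""
    base = base or ModelParameters()
    names = tuple(free_values)
    unknown = set(names) - set(ESTIMATED_PARAMETERS)
    if unknown:
        raise KeyError(f"not estimated parameters: {sorted(unknown)}")
    weights = _curve_weights(datasets) if weighted else None
    r = _residuals(np.array([free_values[n] for n in names]), names, datasets,
                   base, conversions, weights, strict, penalty, rtol, atol)
    return float(np.dot(r, r))


def _curve_weights(datasets: Sequence[CalibrationDataset]) -> list[float]:
    return [1.0 / max(ds.curve.final_volume, 1e-6) for ds in datasets]


def default_bounds(init: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    """(0.1x, 10x) around the initial value; ``a``, ``b`` capped at 1."""
    bounds = {}
    for name, v in init.items():
        hi = 10.0 * v
        if name in ("a", "b"):
            hi = min(hi, 1.0)
        bounds[name] = (0.1 * v, hi)
    return bounds


def fit(
    datasets: Sequence[CalibrationDataset],
    free_names: Sequence[str] = ESTIMATED_PARAMETERS,
    base: ModelParameters | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    init: Mapping[str, float] | None = None,
    conversions=DEFAULT_CONVERSIONS,
    weighted: bool = False,
    multistart_seeds: Iterable[int] | None = None,
    multistart_spread: float = 0.2,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    **ls_options,
) -> FitResult:
    """Bound-constrained least-squares calibration.

    Deterministic given ``init`` and options; with ``multistart_seeds`` the
    fit is repeated from log-uniformly perturbed starts (each seeded) and the
    best result returned.  A non-converged optimizer is reported via
    ``success=False``, never silently.
    """
    if len(datasets) == 0:
        raise ValueError("at least one dataset is required")
    base = base or ModelParameters()
    free_names = tuple(free_names)
    unknown = set(free_names) - set(ESTIMATED_PARAMETERS)
    if unknown:
        raise KeyError(f"not estimated parameters: {sorted(unknown)}")
    base_dict = base.to_dict()
    init = dict(init) if init else {n: base_dict[n] for n in free_names}
    bounds = dict(bounds) if bounds else default_bounds(init)
    for n in free_names:
        lo, hi = bounds[n]
        if not lo <= init[n] <= hi:
            raise ValueError(f"init for {n!r} outside its bounds")
    weights = _curve_weights(datasets) if weighted else None
    lo = np.array([bounds[n][0] for n in free_names])
    hi = np.array([bounds[n][1] for n in free_names])
    x0 = np.array([init[n] for n in free_names])

    options = {"method": "trf", "x_scale": x0, "diff_step": 1e-4,
               "ftol": 1e-12, "xtol": 1e-12, "gtol": 1e-12}
    options.update(ls_options)

    def solve(start: np.ndarray):
        return least_squares(
            _residuals, start, bounds=(lo, hi),
            args=(free_names, datasets, base, conversions, weights,
                  False, 1e3, rtol, atol),
            **options)

    best = solve(x0)
    if multistart_seeds is not None:
        for seed in multistart_seeds:
            rng = np.random.default_rng(seed)
            start = np.clip(
                x0 * np.exp(rng.uniform(-multistart_spread, multistart_spread,
                                        size=len(x0))),
                lo, hi)
            res = solve(start)
            if res.cost < best.cost:
                best = res

    return FitResult(
        values=dict(zip(free_names, map(float, best.x))),
        cost=float(2.0 * best.cost),   # scipy reports 0.5 * SSQ
        residuals=best.fun.copy(),
        success=bool(best.status > 0),
        nfev=int(best.nfev),
        message=str(best.message),
        free_names=free_names,
        bounds=bounds,
        init=init,
    )


def gauge_align(values: Mapping[str, float], reference_a: float = 0.5) -> dict[str, float]:
    """Map an estimate onto the gauge convention ``a = reference_a``.

    The transformation ``K_ifa → c·K_ifa``, ``a → a/c``, ``b → b/c`` leaves
    every model trajectory unchanged; this picks the representative with the
    requested ``a``.  Parameters outside the invariance are returned as-is.
    """
    if reference_a <= 0:
        raise ValueError("reference_a must be positive")
    out = dict(values)
    if "a" not in out:
        return out
    c = out["a"] / reference_a
    if c <= 0:
        raise ValueError("estimated a must be positive for gauge alignment")
    for name in GAUGE_SCALED:
        if name in out:
            out[name] = out[name] * c
    for name in GAUGE_INVERSE:
        out[name] = out[name] / c
    return out


def recovery_errors(
    estimate: Mapping[str, float],
    truth: Mapping[str, float],
    align_gauge: bool = True,
) -> dict[str, float]:
    """Relative error of each estimated parameter against the ground truth.

    With ``align_gauge`` the estimate is first mapped onto the truth's ``a``
    convention so that only identifiable discrepancies are measured.
    """
    est = gauge_align(estimate, truth["a"]) if align_gauge and "a" in estimate \
        else dict(estimate)
    return {n: abs(est[n] - truth[n]) / abs(truth[n]) for n in est}
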