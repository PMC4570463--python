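"""Local relative sensitivity screen.

For an output functional ``y(params)`` (default: cumulative methane at the
end of a reference batch) the relative–relative sensitivity of parameter
``p`` is

    delta = (dy / y0) / (dp / p0),

estimated by a central finite difference under a ±fractional perturbation of
the parameter.  Parameters with |delta| above a threshold are classified
high-sensitivity (to be estimated from data); the rest are taken from
literature values.  An upper-only +100% variant is reported alongside, since
a −100% perturbation would zero the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .experiment import (
    DEFAULT_CONVERSIONS,
    DEFAULT_INOCULUM,
    NS1,
    BatchConfig,
    InoculumSpec,
    SubstrateSpec,
    UnitConversions,
    initial_state,
)
from .params import ModelParameters, PARAMETER_NAMES

__all__ = [
    "SensitivityResult",
    "UndefinedSensitivityError",
    "final_methane_functional",
    "relative_sensitivity",
    "screen",
]

OutputFunctional = Callable[[ModelParameters], float]


class UndefinedSensitivityError(ZeroDivisionError):
    """Raised when the baseline output is zero and delta is undefined."""


@dataclass(frozen=True)
class SensitivityResult:
    """Sensitivity of one parameter."""

    name: str
    perturbation: float
    delta: float
    functional: str
    classification: str  # "low" | "high"


def final_methane_functional(
    substrate: SubstrateSpec = NS1,
    inoculum: InoculumSpec = DEFAULT_INOCULUM,
    config: BatchConfig | None = None,
    conversions: UnitConversions = DEFAULT_CONVERSIONS,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OutputFunctional:
    """Output functional: cumulative methane volume at the end of the batch.

    The substrate fixes the initial state only; the parameter set is used
    as given (so perturbing ``f_fa`` through it is honoured — pass
    ``substrate.parameters()`` as the screen's base to start from the
    substrate's own LCFA fraction).  The default reference bottle is the
    high-lipid substrate at I/S = 1.0 with a 0.5 calcium:LCFA dose: with no
    calcium in the bottle the calcium weight ``b`` has no pathway to the
    output and its sensitivity would be identically zero.
    """
    config = config or BatchConfig(is_ratio=1.0, ca_ratio=0.5)

    def y(params: ModelParameters) -> float:
        from .model import integrate  # local import keeps module deps one-way

        state0 = initial_state(substrate, inoculum, config, conversions)
        traj = integrate(params, state0, t_end=config.duration_d,
                         rtol=rtol, atol=atol)
        return float(traj.series("S_m")[-1] * conversions.ch4_l_per_gcod)

    return y


def relative_sensitivity(
    name: str,
    base_params: ModelParameters,
    output: OutputFunctional,
    perturbation: float = 0.5,
    sides: str = "central",
    reciprocal: bool = False,
) -> float:
    """Finite-difference relative sensitivity of one parameter.

    ``sides='central'`` uses (y(p+) − y(p−)) / (2·h·y0); ``'upper'`` uses the
    one-sided (y(p+) − y0) / (h·y0).  ``reciprocal=True`` returns 1/delta,
    the alternative orientation of the sensitivity ratio.
    """
    if not 0.0 < perturbation <= 1.0:
        raise ValueError("perturbation must lie in (0, 1]")
    if sides == "central" and perturbation >= 1.0:
        raise ValueError(
            "a -100% perturbation would zero the parameter; use a smaller "
            "fraction or sides='upper'")
    if name not in PARAMETER_NAMES:
        raise KeyError(f"unknown parameter {name!r}")
    p0 = getattr(base_params, name)
    if p0 <= 0:
        raise ValueError(f"base value of {name!r} must be positive")
    y0 = output(base_params)
    if y0 == 0:
        raise UndefinedSensitivityError(
            f"baseline output is zero; delta undefined for {name!r}")
    y_hi = output(base_params.replace(**{name: p0 * (1.0 + perturbation)}))
    if sides == "central":
        y_lo = output(base_params.replace(**{name: p0 * (1.0 - perturbation)}))
        delta = (y_hi - y_lo) / (2.0 * perturbation * y0)
    elif sides == "upper":
        delta = (y_hi - y0) / (perturbation * y0)
    else:
        raise ValueError("sides must be 'central' or 'upper'")
    if reciprocal:
        if delta == 0:
            raise UndefinedSensitivityError("delta is zero; reciprocal undefined")
        delta = 1.0 / delta
    return float(delta)


def screen(
    names: Sequence[str] = PARAMETER_NAMES,
    base_params: ModelParameters | None = None,
    output: OutputFunctional | None = None,
    threshold: float = 0.1,
    perturbation: float = 0.5,
    functional_label: str = "final_methane",
) -> pd.DataFrame:
    """Classify parameters as low/high sensitivity by |delta| vs. threshold.

    Returns a frame sorted by |delta| descending with columns ``parameter``,
    ``delta`` (central, ±perturbation), ``delta_upper100`` (one-sided +100%),
    ``abs_delta``, ``classification``.  ``f_fa`` cannot be screened when its
    base value is 0 (the perturbation would be degenerate); such parameters
    are skipped.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    base_params = base_params or ModelParameters()
    output = output or final_methane_functional()
    rows = []
    for name in names:
        delta = relative_sensitivity(name, base_params, output, perturbation)
        delta_up = relative_sensitivity(name, base_params, output, 1.0,
                                        sides="upper")
        cls = "high" if abs(delta) > threshold else "low"
        rows.append({"parameter": name, "delta": delta,
                     "delta_upper100": delta_up, "abs_delta": abs(delta),
                     "classification": cls})
    frame = pd.DataFrame(rows).sort_values("abs_delta", ascending=False)
    return frame.reset_index(drop=True)
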