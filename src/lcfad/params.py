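"""Kinetic and stoichiometric parameters of the digestion model.

All pools are expressed in COD units (kg COD/m^3, identical to g COD/L) and
time in days.  The parameter names follow the symbols conventional in
anaerobic-digestion kinetics: ``km_*`` are maximum specific uptake rates,
``Ks_*`` Contois half-saturation coefficients (COD/COD, dimensionless),
``Y_*`` biomass yields, ``kd_*`` first-order decay rates, ``f_fa`` the
long-chain-fatty-acid (LCFA) fraction of the hydrolysis flux, ``Khfa``,
``Kvfa``, ``Kmfa`` the LCFA inhibition constants for hydrolytic bacteria,
acidogens and methanogens, and ``a``, ``b`` the weights on active biomass and
calcium-equivalent in the inhibition ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "ESTIMATED_PARAMETERS",
    "FIXED_PARAMETERS",
    "PARAMETER_NAMES",
    "ns1_parameters",
    "ns2_parameters",
    "read_parameters",
    "write_parameters",
]

#: The eight parameters estimated from batch methane curves; the remainder are
#: low-sensitivity constants taken from the literature and held fixed.
ESTIMATED_PARAMETERS: tuple[str, ...] = (
    "km_v", "Y_m", "kd_m", "Khfa", "Kvfa", "Kmfa", "a", "b",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the LCFA-inhibited digestion model.

    Defaults are the reference values for whole algal biomass (``f_fa=0.35``);
    use :func:`ns2_parameters` (or ``replace(f_fa=0.11)``) for the
    lipid-extracted residue.
    """

    km_p: float = 10.0   # hydrolysis, 1/day
    km_h: float = 20.0   # acidogenesis, 1/day
    km_fa: float = 6.0   # LCFA uptake, 1/day
    km_v: float = 20.0   # methanogenesis, 1/day
    Ks_p: float = 0.5    # Contois coefficients, COD/COD
    Ks_h: float = 0.5
    Ks_fa: float = 0.5
    Ks_v: float = 0.5
    Y_h: float = 0.05    # yields, kgCOD biomass / kgCOD substrate
    Y_v: float = 0.05
    Y_m: float = 0.05
    kd_h: float = 0.8    # decay, 1/day
    kd_v: float = 0.8
    kd_m: float = 0.05
    f_fa: float = 0.35   # LCFA fraction of hydrolysis products
    Khfa: float = 5.0    # inhibition constants, kg COD/m^3
    Kvfa: float = 5.0
    Kmfa: float = 5.0
    a: float = 0.5       # weight on active biomass in the inhibition ratio
    b: float = 0.5       # weight on calcium equivalent in the inhibition ratio

    def __post_init__(self) -> None:
        for name, value in self.items():
            if not (value == value) or value <= 0:
                if name == "f_fa" and value == 0.0:
                    continue
                raise ValueError(f"parameter {name!r} must be positive, got {value!r}")
        for name in ("Y_h", "Y_v", "Y_m"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"yield {name!r} must lie in (0, 1)")
        if not 0.0 <= self.f_fa <= 1.0:
            raise ValueError("f_fa must lie in [0, 1]")

    # -- mapping-style helpers -------------------------------------------
    def items(self) -> Iterator[tuple[str, float]]:
        for field in dataclasses.fields(self):
            yield field.name, getattr(self, field.name)

    def to_dict(self) -> dict[str, float]:
        return dict(self.items())

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "ModelParameters":
        unknown = set(mapping) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


PARAMETER_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ModelParameters)
)
FIXED_PARAMETERS: tuple[str, ...] = tuple(
    n for n in PARAMETER_NAMES if n not in ESTIMATED_PARAMETERS
)


def ns1_parameters() -> ModelParameters:
    """Reference parameters for whole (high-lipid) algal biomass."""
    return ModelParameters()


def ns2_parameters() -> ModelParameters:
    """Reference parameters for lipid-extracted (low-lipid) residue."""
    return ModelParameters(f_fa=0.11)


def read_parameters(path: str | Path) -> ModelParameters:
    """Read a flat ``name: value`` YAML/JSON parameter file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a flat mapping of parameter names")
    return ModelParameters.from_dict(data)


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
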