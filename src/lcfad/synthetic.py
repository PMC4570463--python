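"""Synthetic BMP-study generator with known ground truth.

Emulates the batch experiment grid — two substrates (whole algal biomass and
lipid-extracted residue) × inoculum-to-substrate ratios {0.1, 0.4, 1.0} ×
calcium:LCFA molar ratios {0, 0.5, 1, 2} — monitored daily for 20 days.
Measurement noise is applied multiplicatively to the *daily increments*
(relative s.d. default 5%), increments are clipped at zero and re-cumulated,
so every generated curve is non-decreasing by construction regardless of the
noise level.  Regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .calibration import CalibrationDataset
from .experiment import (
    DEFAULT_CONVERSIONS,
    DEFAULT_INOCULUM,
    NS1,
    NS2,
    BatchConfig,
    InoculumSpec,
    MethaneCurve,
    SubstrateSpec,
    UnitConversions,
    methane_curve,
    simulate_batch,
)
from .model import IntegrationError, Trajectory
from .params import ModelParameters

__all__ = [
    "SyntheticCurve",
    "SyntheticStudy",
    "default_grid",
    "generate",
    "write_study",
]

IS_RATIOS = (0.1, 0.4, 1.0)
CA_RATIOS = (0.0, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class SyntheticCurve:
    """One generated bottle: spec, noisy curve and its noiseless truth."""

    substrate: SubstrateSpec
    config: BatchConfig
    curve: MethaneCurve
    noiseless: MethaneCurve
    ok: bool = True

    @property
    def label(self) -> str:
        return (f"{self.substrate.name}_IS{self.config.is_ratio:g}"
                f"_Ca{self.config.ca_ratio:g}")

    def to_dataset(self) -> CalibrationDataset:
        return CalibrationDataset(self.substrate, self.config, self.curve)


@dataclass
class SyntheticStudy:
    """A full synthetic BMP study with ground truth attached."""

    true_params: ModelParameters
    noise_sd_rel: float
    seed: int
    curves: list[SyntheticCurve]
    trajectories: list[Trajectory] = field(default_factory=list)

    def datasets(self) -> list[CalibrationDataset]:
        return [c.to_dataset() for c in self.curves if c.ok]


def default_grid(
    substrates: Sequence[SubstrateSpec] = (NS1, NS2),
    is_ratios: Sequence[float] = IS_RATIOS,
    ca_ratios: Sequence[float] = CA_RATIOS,
    loading_gvs_l: float = 10.0,
    duration_d: float = 20.0,
) -> list[tuple[SubstrateSpec, BatchConfig]]:
    """The 2-substrate × 3-I/S × 4-calcium experimental grid (24 bottles)."""
    return [
        (sub, BatchConfig(loading_gvs_l=loading_gvs_l, is_ratio=r_is,
                          ca_ratio=r_ca, duration_d=duration_d))
        for sub in substrates
        for r_is in is_ratios
        for r_ca in ca_ratios
    ]


def noisy_increments(volume: np.ndarray, noise_sd_rel: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Apply multiplicative Gaussian noise to daily increments and re-cumulate."""
    inc = np.diff(volume, prepend=0.0)
    inc = inc * (1.0 + noise_sd_rel * rng.standard_normal(len(inc)))
    return np.cumsum(np.maximum(inc, 0.0))


def generate(
    true_params: ModelParameters | None = None,
    configs: Sequence[tuple[SubstrateSpec, BatchConfig]] | None = None,
    noise_sd_rel: float = 0.05,
    seed: int = 0,
    inoculum: InoculumSpec = DEFAULT_INOCULUM,
    conversions: UnitConversions = DEFAULT_CONVERSIONS,
    keep_trajectories: bool = False,
    **integrate_options,
) -> SyntheticStudy:
    """Simulate every bottle, sample daily, and add seeded increment noise.

    Each substrate's own LCFA fraction overrides ``f_fa`` of ``true_params``.
    A bottle whose integration fails is kept with ``ok=False`` and an empty
    curve rather than aborting the study.
    """
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be non-negative")
    true_params = true_params or ModelParameters()
    configs = configs if configs is not None else default_grid()
    rng = np.random.default_rng(seed)
    curves: list[SyntheticCurve] = []
    trajectories: list[Trajectory] = []
    for substrate, config in configs:
        try:
            traj = simulate_batch(substrate, inoculum, config, true_params,
                                  conversions, report_step=1.0,
                                  **integrate_options)
        except IntegrationError:
            empty = MethaneCurve(days=np.array([config.duration_d]),
                                 volume=np.array([0.0]))
            curves.append(SyntheticCurve(substrate, config, empty, empty,
                                         ok=False))
            continue
        clean = methane_curve(traj, conversions)
        # observations start at day 1; day 0 is the (zero) initial reading
        days = clean.days[1:]
        vol = clean.volume[1:]
        noisy = noisy_increments(vol, noise_sd_rel, rng) if noise_sd_rel > 0 \
            else vol.copy()
        curves.append(SyntheticCurve(
            substrate, config,
            curve=MethaneCurve(days=days, volume=noisy),
            noiseless=MethaneCurve(days=days, volume=vol),
        ))
        if keep_trajectories:
            trajectories.append(traj)
    return SyntheticStudy(true_params=true_params, noise_sd_rel=noise_sd_rel,
                          seed=seed, curves=curves, trajectories=trajectories)


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write one curve file per bottle, a manifest and the ground truth.

    Returns the manifest path.  Files: ``<label>.csv`` per curve,
    ``true_parameters.yaml`` and ``manifest.yaml`` listing (config, curve
    path) pairs with the study seed and noise level.
    """
    from .io import write_curve
    from .params import write_parameters

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for c in study.curves:
        if not c.ok:
            continue
        path = outdir / f"{c.label}.csv"
        write_curve(c.curve, path)
        entries.append({
            "curve": path.name,
            "substrate": c.substrate.name,
            "f_fa": c.substrate.f_fa,
            "cod_vs": c.substrate.cod_vs,
            "loading_gvs_l": c.config.loading_gvs_l,
            "is_ratio": c.config.is_ratio,
            "ca_ratio": c.config.ca_ratio,
            "duration_d": c.config.duration_d,
        })
    write_parameters(study.true_params, outdir / "true_parameters.yaml")
    manifest = {
        "seed": study.seed,
        "noise_sd_rel": study.noise_sd_rel,
        "parameters": "true_parameters.yaml",
        "datasets": entries,
    }
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
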