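"""File I/O: methane curves, trajectories, manifests.

Curves are delimited text with header ``day,cumulative_CH4_L_per_L``;
trajectories are tidy delimited text with one column per state plus the
three inhibition factors; manifests are YAML files listing the (bottle
configuration, curve file) pairs a calibration run consumes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationDataset
from .experiment import NS1, NS2, BatchConfig, MethaneCurve, SubstrateSpec
from .model import Trajectory

__all__ = [
    "CurveParseError",
    "read_curve",
    "write_curve",
    "write_trajectory",
    "read_manifest",
]

CURVE_COLUMNS = ("day", "cumulative_CH4_L_per_L")


class CurveParseError(ValueError):
    """Malformed curve file; the message names the offending line."""


def read_curve(path: str | Path) -> MethaneCurve:
    """Read and validate a cumulative methane curve.

    Raises :class:`CurveParseError` naming the first offending line for
    malformed rows, duplicate or non-increasing days, negative values or a
    decreasing cumulative volume.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # header/parser failures
        raise CurveParseError(f"{path}: cannot parse ({exc})") from exc
    missing = set(CURVE_COLUMNS) - set(frame.columns)
    if missing:
        raise CurveParseError(f"{path}: missing columns {sorted(missing)}")
    days = pd.to_numeric(frame["day"], errors="coerce").to_numpy(dtype=float)
    vol = pd.to_numeric(frame["cumulative_CH4_L_per_L"],
                        errors="coerce").to_numpy(dtype=float)
    # +2: 1-based lines plus the header row
    for arr, what in ((days, "day"), (vol, "cumulative_CH4_L_per_L")):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise CurveParseError(
                f"{path}: line {bad[0] + 2}: non-numeric {what} value")
        neg = np.flatnonzero(arr < 0)
        if neg.size:
            raise CurveParseError(
                f"{path}: line {neg[0] + 2}: negative {what} value")
    nonmono = np.flatnonzero(np.diff(days) <= 0)
    if nonmono.size:
        raise CurveParseError(
            f"{path}: line {nonmono[0] + 3}: days not strictly increasing")
    dec = np.flatnonzero(np.diff(vol) < 0)
    if dec.size:
        raise CurveParseError(
            f"{path}: line {dec[0] + 3}: cumulative volume decreases")
    return MethaneCurve(days=days, volume=vol)


def write_curve(curve: MethaneCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    trajectory.to_frame().to_csv(path, index=False)


_SUBSTRATES = {"NS1": NS1, "NS2": NS2}


def _substrate_from_entry(entry: dict) -> SubstrateSpec:
    name = entry.get("substrate", "NS1")
    base = _SUBSTRATES.get(name)
    if base is None:
        base = SubstrateSpec(name=name, lipid_pct=0.0, carbohydrate_pct=0.0,
                             protein_pct=0.0, unknown_pct=0.0, vs_ts_pct=100.0,
                             f_fa=float(entry["f_fa"]))
    changes = {}
    for key in ("f_fa", "cod_vs"):
        if key in entry:
            changes[key] = float(entry[key])
    if changes:
        import dataclasses
        base = dataclasses.replace(base, **changes)
    return base


def read_manifest(path: str | Path) -> list[CalibrationDataset]:
    """Read a calibration manifest: YAML with a ``datasets`` list.

    Each entry names a curve file (relative paths resolve against the
    manifest's directory) and the bottle configuration keys ``substrate``,
    ``loading_gvs_l``, ``is_ratio``, ``ca_ratio``, ``duration_d`` (optional
    ``f_fa``/``cod_vs`` overrides).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "datasets" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'datasets' list")
    datasets = []
    for entry in doc["datasets"]:
        curve_path = Path(entry["curve"])
        if not curve_path.is_absolute():
            curve_path = path.parent / curve_path
        config = BatchConfig(
            loading_gvs_l=float(entry.get("loading_gvs_l", 10.0)),
            is_ratio=float(entry.get("is_ratio", 1.0)),
            ca_ratio=float(entry.get("ca_ratio", 0.0)),
            duration_d=float(entry.get("duration_d", 20.0)),
        )
        datasets.append(CalibrationDataset(
            substrate=_substrate_from_entry(entry),
            config=config,
            curve=read_curve(curve_path),
        ))
    return datasets
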