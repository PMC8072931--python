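"""CSV/JSON/YAML readers and writers for the three instrument dialects.

Formats (UTF-8, '.' decimal separator):

* titration: long CSV with columns ``addition_index, volume_added_uL,
  wavelength_nm, absorbance`` plus a JSON/YAML config carrying
  ``C_PtL_initial_M, protein_stock_M, V0_mL, path_cm`` and optionally
  ``lambda_star_nm``; in-cell analytical totals are reconstructed from
  the volumes on read.
* thermogram: CSV with ``temperature_C, cp_exc_kJ_mol_K``, or raw
  ``temperature_C, power_uW`` converted via Cp_exc = power /
  (scan rate x moles).
* peak lists: CSV with ``mass_da,intensity`` (deconvolved neutral) or
  ``mz,intensity`` (raw envelope).

All writers round-trip losslessly through their readers at 12
significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .adducts import AdductAssignment, FragmentSpec, NeutralPeakList
from .dsc import Thermogram
from .titration import Spectrum, TitrationPoint, TitrationSeries

__all__ = [
    "read_config",
    "read_titration_csv",
    "write_titration_csv",
    "titration_config",
    "read_thermogram_csv",
    "write_thermogram_csv",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_fragment_library",
    "write_assignments_csv",
    "write_report",
]

_FLOAT_FMT = "%.12g"


class InputError(ValueError):
    """Malformed input file (missing column, bad row, non-monotone grid)."""


def read_config(path_or_dict) -> dict:
    """Load a JSON or YAML config file (dicts pass through)."""
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    path = Path(path_or_dict)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}; found "
                         f"{list(df.columns)}")


# ---------------------------------------------------------------------------
# titration


def read_titration_csv(csv_path, config) -> TitrationSeries:
    """Read a long-format titration CSV plus its concentration config."""
    cfg = read_config(config)
    for key in ("C_PtL_initial_M", "protein_stock_M", "V0_mL", "path_cm"):
        if key not in cfg:
            raise InputError(f"titration config missing key {key!r}")
    df = pd.read_csv(csv_path)
    _require_columns(
        df, ["addition_index", "volume_added_uL", "wavelength_nm", "absorbance"],
        csv_path,
    )
    if df[["volume_added_uL", "wavelength_nm", "absorbance"]].isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # 1-based + header
        raise InputError(f"{csv_path}: malformed value at line {bad}")
    v0 = cfg["V0_mL"] * 1e-3
    c0 = cfg["C_PtL_initial_M"]
    stock = cfg["protein_stock_M"]
    path_cm = cfg["path_cm"]
    points: List[TitrationPoint] = []
    for idx, group in df.groupby("addition_index", sort=True):
        vols = group["volume_added_uL"].unique()
        if vols.size != 1:
            raise InputError(
                f"{csv_path}: addition {idx} has inconsistent volume_added_uL")
        v_add = float(vols[0]) * 1e-6
        wl = group["wavelength_nm"].to_numpy(dtype=float)
        order = np.argsort(wl)
        wl, ab = wl[order], group["absorbance"].to_numpy(dtype=float)[order]
        if np.any(np.diff(wl) <= 0):
            raise InputError(
                f"{csv_path}: addition {idx} has duplicate wavelengths")
        v = v0 + v_add
        points.append(TitrationPoint(
            c_ptl=c0 * v0 / v, c_protein=stock * v_add / v,
            spectrum=Spectrum(wl, ab, path_cm), v_added_l=v_add,
        ))
    return TitrationSeries(
        points=points, lambda_star_nm=cfg.get("lambda_star_nm"), v0_l=v0)


def titration_config(series: TitrationSeries) -> dict:
    """Reconstruct the concentration config implied by a series."""
    p_last = series.points[-1]
    if p_last.v_added_l > 0:
        stock = p_last.c_protein * (series.v0_l + p_last.v_added_l) / p_last.v_added_l
    else:
        stock = 0.0
    return {
        "C_PtL_initial_M": series.points[0].c_ptl,
        "protein_stock_M": stock,
        "V0_mL": series.v0_l * 1e3,
        "path_cm": series.points[0].spectrum.path_cm,
        "lambda_star_nm": series.lambda_star_nm,
    }


def write_titration_csv(series: TitrationSeries, csv_path,
                        config_path=None) -> dict:
    """Write a series to long CSV; optionally write its config JSON too.

    Returns the config dict so callers can feed it straight back to
    :func:`read_titration_csv`.
    """
    rows = []
    for i, p in enumerate(series.points):
        for wl, ab in zip(p.spectrum.wavelength_nm, p.spectrum.absorbance):
            rows.append((i, p.v_added_l * 1e6, wl, ab))
    df = pd.DataFrame(
        rows, columns=["addition_index", "volume_added_uL", "wavelength_nm",
                       "absorbance"])
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    cfg = titration_config(series)
    if config_path is not None:
        Path(config_path).write_text(json.dumps(cfg, indent=2))
    return cfg


# ---------------------------------------------------------------------------
# DSC


def read_thermogram_csv(csv_path, protein_molar: Optional[float] = None,
                        scan_rate_k_min: Optional[float] = None,
                        cell_volume_l: float = 1.0e-3) -> Thermogram:
    """Read a thermogram CSV (processed Cp_exc, or raw power in uW)."""
    df = pd.read_csv(csv_path)
    if "temperature_C" not in df.columns:
        raise InputError(f"{csv_path}: missing column 'temperature_C'")
    t_k = df["temperature_C"].to_numpy(dtype=float) + 273.15
    if "cp_exc_kJ_mol_K" in df.columns:
        cp = df["cp_exc_kJ_mol_K"].to_numpy(dtype=float)
    elif "power_uW" in df.columns:
        if not protein_molar or not scan_rate_k_min:
            raise InputError(
                f"{csv_path}: raw power input needs protein_molar and "
                "scan_rate_k_min")
        # power [uW = uJ/s] / (scan rate [K/s] x moles) -> J/mol/K -> kJ/mol/K
        rate_k_s = scan_rate_k_min / 60.0
        moles = protein_molar * cell_volume_l
        cp = df["power_uW"].to_numpy(dtype=float) * 1e-6 / (
            rate_k_s * moles) * 1e-3
    else:
        raise InputError(
            f"{csv_path}: need column 'cp_exc_kJ_mol_K' or 'power_uW'")
    if np.any(np.isnan(t_k)) or np.any(np.isnan(cp)):
        bad = int(np.where(np.isnan(t_k) | np.isnan(cp))[0][0]) + 2
        raise InputError(f"{csv_path}: malformed value at line {bad}")
    if np.any(np.diff(t_k) <= 0):
        bad = int(np.where(np.diff(t_k) <= 0)[0][0]) + 2
        raise InputError(
            f"{csv_path}: temperature grid not strictly increasing near line {bad}")
    return Thermogram(t_k, cp,
                      protein_molar if protein_molar else 2.0e-4,
                      scan_rate_k_min if scan_rate_k_min else 0.5)


def write_thermogram_csv(t: Thermogram, csv_path) -> None:
    pd.DataFrame({
        "temperature_C": t.temperature_c,
        "cp_exc_kJ_mol_K": t.cp_exc,
    }).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# mass spectrometry


def read_peaklist_csv(csv_path, tolerance_da: float = 1.5):
    """Read a peak list; returns ("neutral", NeutralPeakList) or ("raw", array).

    ``mass_da,intensity`` columns mean a deconvolved neutral-mass list;
    ``mz,intensity`` a raw envelope (returned as an (n, 2) array).
    """
    df = pd.read_csv(csv_path)
    if "intensity" not in df.columns:
        raise InputError(f"{csv_path}: missing column 'intensity'")
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2
        raise InputError(f"{csv_path}: malformed value at line {bad}")
    inten = df["intensity"].to_numpy(dtype=float)
    if "mass_da" in df.columns:
        return "neutral", NeutralPeakList(
            df["mass_da"].to_numpy(dtype=float), inten, tolerance_da)
    if "mz" in df.columns:
        return "raw", np.column_stack([df["mz"].to_numpy(dtype=float), inten])
    raise InputError(f"{csv_path}: need column 'mass_da' or 'mz'")


def write_peaklist_csv(peaks, csv_path, kind: str = "neutral") -> None:
    if kind == "neutral":
        df = pd.DataFrame({"mass_da": peaks.masses_da,
                           "intensity": peaks.intensities})
    else:
        arr = np.asarray(peaks, dtype=float).reshape(-1, 2)
        df = pd.DataFrame({"mz": arr[:, 0], "intensity": arr[:, 1]})
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)


def read_fragment_library(path_or_list) -> List[FragmentSpec]:
    """Load fragment specs from JSON/YAML: entries with label, formula,
    charge_displaced and an optional note."""
    entries = path_or_list if isinstance(path_or_list, list) \
        else read_config(path_or_list)
    if isinstance(entries, dict):
        entries = entries.get("fragments", [])
    frags = []
    for e in entries:
        frags.append(FragmentSpec(
            label=e["label"], formula=e["formula"],
            charge=int(e.get("charge_displaced", e.get("charge", 2))),
            note=e.get("note", ""),
        ))
    return frags


def write_assignments_csv(assignments: Sequence[AdductAssignment],
                          csv_path) -> None:
    rows = []
    for a in assignments:
        rows.append({
            "observed": a.observed_da,
            "predicted": a.predicted_da,
            "composition": a.composition,
            "k": a.k,
            "error_da": a.error_da,
            "intensity": a.intensity,
            "flags": ";".join(a.flags),
            "alternatives": ";".join(
                f"{r.composition}@{r.predicted_da:.1f}" for r in a.ambiguous_with),
        })
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# reports


def write_report(results: dict, path, config: Optional[dict] = None,
                 seed: Optional[int] = None) -> dict:
    """Write a JSON report with a provenance block (version, seed, config)."""
    def _clean(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    payload = {
        "provenance": {
            "package": "metallobind",
            "version": _pkg_version,
            "seed": seed,
            "config": _clean(config) if config else None,
        },
        "results": _clean(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
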