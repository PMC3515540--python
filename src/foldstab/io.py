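"""Plain-text readers and writers for every dataset the pipeline handles.

All tabular formats are headered, comma-delimited, UTF-8, decimal point.
Column names are fixed per dataset kind:

==================  =========================================
chemical unfolding  ``urea_M,signal``
DSC scan            ``temp_C,cp_kcal_mol_K`` (one file per scan)
Kirchhoff series    ``urea_M,Tm_C,dHcal_kcal_mol``
s vs concentration  ``conc_mg_mL,s_app_S``
s0 vs urea          ``urea_M,s0_20w_S``
MM vs urea          ``urea_M,mm_kDa``
thermal CD          ``temp_C,signal``
emission spectrum   ``lambda_nm,intensity``
quenching           ``quencher_M,intensity``
==================  =========================================

Sequences are read from single-record FASTA.  Fit results are written as
key-value records (parameter, value, standard_error, unit).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .equilibrium import ChemUnfoldCurve
from .fluor import EmissionSpectrum, QuenchSeries
from .hydro import MMSeries, SedSeries
from .thermal import Thermogram, ThermalCDCurve

__all__ = [
    "read_chem_curve", "write_chem_curve",
    "read_thermogram", "write_thermogram",
    "read_kirchhoff_series", "write_kirchhoff_series",
    "read_sed_series", "write_sed_series",
    "read_mm_series", "write_mm_series",
    "read_thermal_cd", "write_thermal_cd",
    "read_spectrum", "read_quench_series", "write_quench_series",
    "read_single_fasta",
    "write_fit_records", "read_fit_records",
]


def _read(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_chem_curve(path, temperature_K: float = 293.15, signal_kind: str = "fraction") -> ChemUnfoldCurve:
    df = _read(path, ["urea_M", "signal"])
    return ChemUnfoldCurve(
        denaturant_M=df["urea_M"].to_numpy(),
        signal=df["signal"].to_numpy(),
        temperature_K=temperature_K,
        signal_kind=signal_kind,
    )


def write_chem_curve(curve: ChemUnfoldCurve, path) -> None:
    pd.DataFrame({"urea_M": curve.denaturant_M, "signal": curve.signal}).to_csv(path, index=False)


def read_thermogram(path, scan_rate_C_per_min: float = 1.0, scan_index: int | None = None) -> Thermogram:
    """Read one DSC scan; scan_index defaults to a trailing integer in the
    file stem (``..._scan2.csv`` → 2) or 1."""
    df = _read(path, ["temp_C", "cp_kcal_mol_K"])
    if scan_index is None:
        stem = Path(path).stem
        digits = "".join(ch for ch in stem if ch.isdigit())
        scan_index = int(digits[-1]) if digits else 1
    return Thermogram(
        temp_C=df["temp_C"].to_numpy(),
        cp=df["cp_kcal_mol_K"].to_numpy(),
        scan_rate_C_per_min=scan_rate_C_per_min,
        scan_index=scan_index,
    )


def write_thermogram(scan: Thermogram, path) -> None:
    pd.DataFrame({"temp_C": scan.temp_C, "cp_kcal_mol_K": scan.cp}).to_csv(path, index=False)


def read_kirchhoff_series(path) -> list[tuple[float, float]]:
    """Kirchhoff input: urea is metadata only; the regression uses (Tm, dH)."""
    df = _read(path, ["urea_M", "Tm_C", "dHcal_kcal_mol"])
    return list(zip(df["Tm_C"].astype(float), df["dHcal_kcal_mol"].astype(float)))


def write_kirchhoff_series(urea_M, series: list[tuple[float, float]], path) -> None:
    tm, dh = zip(*series)
    pd.DataFrame({"urea_M": urea_M, "Tm_C": tm, "dHcal_kcal_mol": dh}).to_csv(path, index=False)


def read_sed_series(path) -> SedSeries:
    df = _read(path, ["urea_M", "s0_20w_S"])
    return SedSeries(urea_M=df["urea_M"].to_numpy(), s0_20w_S=df["s0_20w_S"].to_numpy())


def write_sed_series(series: SedSeries, path) -> None:
    pd.DataFrame({"urea_M": series.urea_M, "s0_20w_S": series.s0_20w_S}).to_csv(path, index=False)


def read_sv_concentration_series(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read(path, ["conc_mg_mL", "s_app_S"])
    return df["conc_mg_mL"].to_numpy(), df["s_app_S"].to_numpy()


def read_mm_series(path) -> MMSeries:
    df = _read(path, ["urea_M", "mm_kDa"])
    return MMSeries(urea_M=df["urea_M"].to_numpy(), mm_kDa=df["mm_kDa"].to_numpy())


def write_mm_series(series: MMSeries, path) -> None:
    pd.DataFrame({"urea_M": series.urea_M, "mm_kDa": series.mm_kDa}).to_csv(path, index=False)


def read_thermal_cd(path) -> ThermalCDCurve:
    df = _read(path, ["temp_C", "signal"])
    return ThermalCDCurve(temp_C=df["temp_C"].to_numpy(), signal=df["signal"].to_numpy())


def write_thermal_cd(curve: ThermalCDCurve, path) -> None:
    pd.DataFrame({"temp_C": curve.temp_C, "signal": curve.signal}).to_csv(path, index=False)


def read_spectrum(path) -> EmissionSpectrum:
    df = _read(path, ["lambda_nm", "intensity"])
    return EmissionSpectrum(lambda_nm=df["lambda_nm"].to_numpy(), intensity=df["intensity"].to_numpy())


def read_quench_series(path) -> QuenchSeries:
    df = _read(path, ["quencher_M", "intensity"])
    return QuenchSeries(quencher_M=df["quencher_M"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_quench_series(series: QuenchSeries, path) -> None:
    pd.DataFrame({"quencher_M": series.quencher_M, "intensity": series.intensity}).to_csv(path, index=False)


def read_single_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq)


def write_fit_records(records: list[dict], path) -> None:
    """Serialize fit results as (parameter, value, standard_error, unit) rows."""
    df = pd.DataFrame(records, columns=["parameter", "value", "standard_error", "unit"])
    df.to_csv(path, index=False)


def read_fit_records(path) -> pd.DataFrame:
    return _read(path, ["parameter", "value", "standard_error", "unit"])
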