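"""Hydrodynamic characterization of oligomeric transitions.

Standardizes apparent sedimentation coefficients to water at 20 °C
(s20,w), extrapolates them to zero protein concentration (s0_20,w),
estimates solvent density/viscosity of urea-containing buffers from
empirical relations, computes partial specific volumes from amino-acid
composition, fits logistic denaturant-transition midpoints for s0_20,w
and molar-mass series, and classifies oligomeric state from
SEC-MALLS-style weight-average masses.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import stats

from .constants import (
    WATER_DENSITY_20C_G_ML,
    WATER_VISCOSITY_20C_CP,
    celsius_to_kelvin,
)
from .sigmoid import SigmoidFit, fit_logistic

__all__ = [
    "SigmoidFit",
    "SedSeries",
    "MMSeries",
    "BufferProps",
    "correct_s_to_s20w",
    "extrapolate_s0",
    "urea_buffer_props",
    "water_density",
    "water_viscosity",
    "vbar_from_sequence",
    "fit_transition_midpoint",
    "classify_oligomer",
]


@dataclass(frozen=True)
class BufferProps:
    """Solvent density (g/mL) and viscosity (cP) at the experiment temperature."""

    density_g_mL: float
    viscosity_cP: float

    def __post_init__(self):
        if not (self.density_g_mL > 0 and self.viscosity_cP > 0):
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class SedSeries:
    """Zero-concentration standardized sedimentation coefficients vs urea."""

    urea_M: np.ndarray
    s0_20w_S: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.urea_M, dtype=float)
        s = np.asarray(self.s0_20w_S, dtype=float)
        object.__setattr__(self, "urea_M", u)
        object.__setattr__(self, "s0_20w_S", s)
        if u.shape != s.shape or u.ndim != 1:
            raise ValueError("urea_M and s0_20w_S must be 1-D and equal length")
        if np.any(np.diff(u) < 0):
            raise ValueError("urea_M must be non-decreasing")
        if np.any(s <= 0):
            raise ValueError("sedimentation coefficients must be positive")


@dataclass(frozen=True)
class MMSeries:
    """Weight-average molar masses (kDa) vs urea concentration."""

    urea_M: np.ndarray
    mm_kDa: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.urea_M, dtype=float)
        m = np.asarray(self.mm_kDa, dtype=float)
        object.__setattr__(self, "urea_M", u)
        object.__setattr__(self, "mm_kDa", m)
        if u.shape != m.shape or u.ndim != 1:
            raise ValueError("urea_M and mm_kDa must be 1-D and equal length")
        if np.any(m <= 0):
            raise ValueError("molar masses must be positive")


def correct_s_to_s20w(s_obs: float, vbar: float, buffer: BufferProps) -> float:
    """Standardize an apparent sedimentation coefficient to water at 20 °C.

    s20,w = s_obs * (eta_b / eta_w20) * (1 - vbar*rho_w20) / (1 - vbar*rho_b).
    Requires positive buoyancy (1 - vbar*rho) in both solvents.
    """
    buoy_buffer = 1.0 - vbar * buffer.density_g_mL
    buoy_water = 1.0 - vbar * WATER_DENSITY_20C_G_ML
    if buoy_buffer <= 0 or buoy_water <= 0:
        raise ValueError("buoyancy term 1 - vbar*rho must be positive in both solvents")
    return s_obs * (buffer.viscosity_cP / WATER_VISCOSITY_20C_CP) * buoy_water / buoy_buffer


def extrapolate_s0(
    conc_mg_mL: np.ndarray | list, s20w_S: np.ndarray | list
) -> tuple[float, float, float]:
    """Zero-concentration sedimentation coefficient by linear regression.

    Returns (s0_20w, slope, se_intercept).  A single concentration returns
    that value with infinite standard error (flagged degenerate).
    """
    c = np.asarray(conc_mg_mL, dtype=float)
    s = np.asarray(s20w_S, dtype=float)
    if c.shape != s.shape or c.ndim != 1 or c.size == 0:
        raise ValueError("conc and s arrays must be 1-D, equal length and non-empty")
    if np.unique(c).size == 1:
        return float(np.mean(s)), float("nan"), float("inf")
    if c.size == 2:
        slope = (s[1] - s[0]) / (c[1] - c[0])
        return float(s[0] - slope * c[0]), float(slope), float("nan")
    res = stats.linregress(c, s)
    return float(res.intercept), float(res.slope), float(res.intercept_stderr)


def water_density(temp_C: float) -> float:
    """Density of air-free water (g/mL), Kell (1975) rational polynomial."""
    t = temp_C
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.879850e-3 * t) / 1000.0


def water_viscosity(temp_C: float) -> float:
    """Viscosity of water (cP) from the Vogel equation (A=0.02414 cP, B=247.8 K, C=140 K)."""
    T = celsius_to_kelvin(temp_C)
    return 0.02414 * 10.0 ** (247.8 / (T - 140.0))


def _urea_coefficients() -> dict:
    with resources.files("foldstab.data").joinpath("urea_solution.yaml").open() as fh:
        return yaml.safe_load(fh)


_UREA = _urea_coefficients()


def urea_buffer_props(urea_M: float, temp_C: float = 20.0) -> BufferProps:
    """Density and viscosity of an aqueous urea solution.

    Density follows an apparent-molar-volume model (urea 60.056 g/mol,
    apparent specific volume 0.763 mL/g); viscosity multiplies the water
    value at ``temp_C`` by the Kawahara–Tanford cubic in molarity.  Valid
    for 0–9 M urea.
    """
    lo, hi = _UREA["valid_molarity_range"]
    if not (lo <= urea_M <= hi):
        raise ValueError(f"urea molarity {urea_M} M outside supported range [{lo}, {hi}] M")
    rho_w = water_density(temp_C)
    dens_cf = _UREA["density"]
    rho = rho_w + (dens_cf["urea_molar_mass_g_mol"] / 1000.0) * urea_M * (
        1.0 - rho_w * dens_cf["urea_apparent_specific_volume_mL_g"]
    )
    visc_cf = _UREA["viscosity_relative"]
    rel = 1.0 + visc_cf["a1"] * urea_M + visc_cf["a2"] * urea_M**2 + visc_cf["a3"] * urea_M**3
    return BufferProps(density_g_mL=rho, viscosity_cP=water_viscosity(temp_C) * rel)


def _residue_table() -> dict[str, tuple[float, float]]:
    table = {}
    with resources.files("foldstab.data").joinpath("residue_vbar.csv").open() as fh:
        rows = (r for r in fh if not r.startswith("#"))
        for rec in csv.DictReader(rows):
            table[rec["residue"]] = (float(rec["mass_g_mol"]), float(rec["vbar_mL_g"]))
    return table


_RESIDUES = _residue_table()


def vbar_from_sequence(sequence: str) -> float:
    """Partial specific volume (mL/g) as the mass-weighted mean of the
    Cohn–Edsall residue values over an amino-acid sequence."""
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("sequence is empty")
    mass_total = 0.0
    mv_total = 0.0
    for i, aa in enumerate(seq):
        if aa not in _RESIDUES:
            raise ValueError(f"unknown amino acid {aa!r} at position {i + 1}")
        mass, vbar = _RESIDUES[aa]
        mass_total += mass
        mv_total += mass * vbar
    return mv_total / mass_total


def fit_transition_midpoint(x, y) -> SigmoidFit:
    """Logistic midpoint of a denaturant (or temperature) transition.

    Shared four-parameter logistic; direction-agnostic, so decreasing
    (s0_20,w, MM) and increasing observables give the same midpoint.
    """
    return fit_logistic(x, y)


def classify_oligomer(mm_obs: float, mm_monomer: float, tol: float = 0.15) -> str:
    """Classify a weight-average mass as 'monomer', 'dimer' or 'other'.

    Dimer when the mass ratio is within 2*tol of 2, monomer when within
    tol of 1 (the dimer window is proportionally wider).
    """
    if mm_obs <= 0 or mm_monomer <= 0:
        raise ValueError("masses must be positive")
    ratio = mm_obs / mm_monomer
    if abs(ratio - 2.0) <= 2.0 * tol:
        return "dimer"
    if abs(ratio - 1.0) <= tol:
        return "monomer"
    return "other"
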