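"""Tryptophan fluorescence probes: spectral center of mass and
Stern–Volmer collisional quenching."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EmissionSpectrum",
    "QuenchSeries",
    "SternVolmerFit",
    "center_of_spectral_mass",
    "fit_stern_volmer",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission spectrum: intensity versus wavelength (nm)."""

    lambda_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lambda_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "lambda_nm", lam)
        object.__setattr__(self, "intensity", inten)
        if lam.ndim != 1 or inten.shape != lam.shape:
            raise ValueError("lambda_nm and intensity must be 1-D and equal length")
        if lam.size >= 2 and not np.all(np.diff(lam) > 0):
            raise ValueError("lambda_nm must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if not np.any(inten > 0):
            raise ValueError("at least one intensity must be strictly positive")


@dataclass(frozen=True)
class QuenchSeries:
    """Emission-maximum intensity versus quencher (acrylamide) concentration.

    The first entry must be at zero quencher: it defines F0.
    """

    quencher_M: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quencher_M, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "quencher_M", q)
        object.__setattr__(self, "intensity", f)
        if q.ndim != 1 or f.shape != q.shape:
            raise ValueError("quencher_M and intensity must be 1-D and equal length")
        if q[0] != 0.0:
            raise ValueError("first entry must be quencher_M = 0 (defines F0)")
        if not np.all(np.diff(q) > 0):
            raise ValueError("quencher_M must be strictly increasing")
        if np.any(f <= 0):
            raise ValueError("intensities must be strictly positive")

    @property
    def F0(self) -> float:
        return float(self.intensity[0])


@dataclass(frozen=True)
class SternVolmerFit:
    """K_SV (M^-1) with standard error; the intercept of F0/F vs [Q] is a
    linearity diagnostic (≈ 1 for purely collisional quenching)."""

    Ksv_per_M: float
    se: float
    intercept: float
    se_intercept: float = float("nan")
    forced_intercept: bool = False


def center_of_spectral_mass(sp: EmissionSpectrum) -> float:
    """Intensity-weighted mean emission wavelength <λ> = Σ(λi Fi)/Σ(Fi), nm."""
    total = float(np.sum(sp.intensity))
    if total <= 0:
        raise ValueError("degenerate spectrum: all intensities zero")
    return float(np.sum(sp.lambda_nm * sp.intensity) / total)


def fit_stern_volmer(q: QuenchSeries, force_intercept: bool = False) -> SternVolmerFit:
    """Stern–Volmer regression of F0/F against quencher concentration.

    Free intercept by default (reported as QC); ``force_intercept=True``
    pins the intercept at 1, matching the collisional-quenching relation
    F0/F = 1 + K_SV [Q] exactly.
    """
    if q.quencher_M.size < 4:
        raise ValueError("Stern-Volmer fit needs at least 4 quencher concentrations")
    x = q.quencher_M
    y = q.F0 / q.intensity
    if force_intercept:
        # least squares through (0, 1): slope = sum(x (y-1)) / sum(x^2)
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * (y - 1.0)) / sxx)
        resid = y - 1.0 - slope * x
        dof = x.size - 1
        se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else float("nan")
        return SternVolmerFit(
            Ksv_per_M=slope, se=se, intercept=1.0, forced_intercept=True
        )
    res = stats.linregress(x, y)
    return SternVolmerFit(
        Ksv_per_M=float(res.slope),
        se=float(res.stderr),
        intercept=float(res.intercept),
        se_intercept=float(res.intercept_stderr),
    )
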