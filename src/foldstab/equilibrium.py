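"""Chemical equilibrium unfolding: three-state linear-extrapolation model.

Dimeric chaperones such as Sis1 lose structure in urea through a native
(N) → intermediate (I) → unfolded (U) scheme.  Within the linear
extrapolation method each step's free energy depends linearly on
denaturant concentration ``d``::

    dG_NI(d) = dG_NI - m_NI * d
    dG_IU(d) = dG_IU - m_IU * d

with equilibrium constants ``K = exp(-dG(d) / (R T))``.  The observed
signal is the population-weighted mean of the three species' plateau
signals.  The model is concentration-independent: although N is a dimer,
the fitted scheme carries no explicit protein-concentration term (a known
limitation, see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import lmfit
import numpy as np

from .constants import R_GAS

__all__ = [
    "ChemUnfoldCurve",
    "ThreeStateParams",
    "ThreeStateFit",
    "three_state_fraction",
    "raw_to_fraction",
    "fit_three_state",
    "compute_cm",
]

#: default experiment temperature, K (20 °C)
DEFAULT_TEMP_K = 293.15

#: minimum number of points for a three-state fit (both transitions sampled)
MIN_POINTS_THREE_STATE = 8


@dataclass(frozen=True)
class ChemUnfoldCurve:
    """A denaturant-unfolding curve: signal observed along a urea gradient.

    ``signal_kind`` distinguishes raw ellipticity (``"raw"``, deg cm²/dmol)
    from an apparent fraction-unfolded (``"fraction"``, dimensionless).
    """

    denaturant_M: np.ndarray
    signal: np.ndarray
    temperature_K: float = DEFAULT_TEMP_K
    signal_kind: str = "fraction"

    def __post_init__(self):
        d = np.asarray(self.denaturant_M, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "denaturant_M", d)
        object.__setattr__(self, "signal", y)
        if d.ndim != 1 or y.shape != d.shape:
            raise ValueError("denaturant_M and signal must be 1-D and equal length")
        if d.size >= 2 and not np.all(np.diff(d) > 0):
            raise ValueError("denaturant_M must be strictly increasing")
        if not self.temperature_K > 0:
            raise ValueError("temperature_K must be positive")
        if self.signal_kind not in ("raw", "fraction"):
            raise ValueError(f"signal_kind must be 'raw' or 'fraction', got {self.signal_kind!r}")

    def __len__(self) -> int:
        return self.denaturant_M.size


@dataclass(frozen=True)
class ThreeStateParams:
    """Thermodynamic parameters of the N ⇌ I ⇌ U scheme at zero denaturant.

    Free energies in kcal/mol, m-values in kcal/(mol M); Y_* are the
    plateau signals of the pure species in the units of the fitted curve.
    """

    dG_NI: float
    m_NI: float
    dG_IU: float
    m_IU: float
    Y_N: float = 0.0
    Y_I: float = 0.5
    Y_U: float = 1.0

    def __post_init__(self):
        vals = (self.dG_NI, self.m_NI, self.dG_IU, self.m_IU, self.Y_N, self.Y_I, self.Y_U)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all three-state parameters must be finite")
        if self.m_NI <= 0 or self.m_IU <= 0:
            raise ValueError("m-values must be positive")


@dataclass(frozen=True)
class ThreeStateFit:
    """Result of a three-state fit; Cm values are the dG/m ratios."""

    params: ThreeStateParams
    se: dict[str, float]
    Cm_NI: float
    Cm_IU: float
    residual_rms: float
    converged: bool
    n_points: int = 0


def species_fractions(
    d: np.ndarray | float, p: ThreeStateParams, T: float = DEFAULT_TEMP_K
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equilibrium populations (fN, fI, fU) at denaturant concentration ``d``.

    fN = 1/Z, fI = K1/Z, fU = K1 K2/Z with Z = 1 + K1 + K1 K2 and
    K1 = exp(-(dG_NI - m_NI d)/(R T)), K2 likewise for I ⇌ U.
    The three fractions sum to 1 by construction.
    """
    if not T > 0:
        raise ValueError("temperature must be positive")
    d = np.asarray(d, dtype=float)
    rt = R_GAS * T
    # log-weights relative to N keep the partition sum overflow-safe
    ln_k1 = -(p.dG_NI - p.m_NI * d) / rt
    ln_k12 = ln_k1 + (-(p.dG_IU - p.m_IU * d) / rt)
    logs = np.stack([np.zeros_like(ln_k1), ln_k1, ln_k12])
    logs -= logs.max(axis=0)
    w = np.exp(logs)
    w /= w.sum(axis=0)
    return w[0], w[1], w[2]


def three_state_fraction(
    d: np.ndarray | float, p: ThreeStateParams, T: float = DEFAULT_TEMP_K
) -> np.ndarray | float:
    """Observable predicted by the three-state LEM model: Σ Y_s f_s(d)."""
    fn, fi, fu = species_fractions(d, p, T)
    out = p.Y_N * fn + p.Y_I * fi + p.Y_U * fu
    return float(out) if np.ndim(out) == 0 else out


def raw_to_fraction(
    curve: ChemUnfoldCurve,
    native_baseline: tuple[float, float],
    unfolded_baseline: tuple[float, float],
    tol: float = 1e-9,
) -> ChemUnfoldCurve:
    """Convert a raw-signal curve to apparent fraction unfolded.

    Baselines are (intercept, slope) lines in denaturant concentration:
    f(d) = (y - yN(d)) / (yU(d) - yN(d)).
    """
    d = curve.denaturant_M
    y_n = native_baseline[0] + native_baseline[1] * d
    y_u = unfolded_baseline[0] + unfolded_baseline[1] * d
    gap = y_u - y_n
    if np.any(np.abs(gap) < tol):
        bad = d[np.abs(gap) < tol]
        raise ValueError(
            f"degenerate baselines: native and unfolded lines coincide near d={bad[0]:g} M"
        )
    frac = (curve.signal - y_n) / gap
    return replace(curve, signal=frac, signal_kind="fraction")


def compute_cm(dG: float, m: float) -> float:
    """Transition midpoint Cm = dG/m (M denaturant); requires m > 0."""
    if not m > 0:
        raise ValueError("m-value must be positive")
    return dG / m


def _default_init(curve: ChemUnfoldCurve) -> ThreeStateParams:
    """Self-initialization: plateaus from curve ends, Cm guesses from the
    25% / 75% crossings of the smoothed signal, m = 2 kcal/mol/M."""
    d, y = curve.denaturant_M, curve.signal
    n = len(curve)
    k = max(1, n // 10)
    y_n = float(np.mean(y[:k]))
    y_u = float(np.mean(y[-k:]))
    # light smoothing for crossing detection only
    win = min(5, n) | 1
    kernel = np.ones(win) / win
    ys = np.convolve(y, kernel, mode="same")
    lo, hi = y_n + 0.25 * (y_u - y_n), y_n + 0.75 * (y_u - y_n)

    def _crossing(level: float, fallback: float) -> float:
        sgn = np.sign(ys - level) if y_u > y_n else np.sign(level - ys)
        idx = np.nonzero(np.diff(sgn) > 0)[0]
        return float(d[idx[0]]) if idx.size else fallback

    span = d[-1] - d[0]
    cm1 = _crossing(lo, d[0] + span / 3)
    cm2 = _crossing(hi, d[0] + 2 * span / 3)
    if cm2 <= cm1:
        cm2 = cm1 + max(0.2, 0.1 * span)
    m_guess = 2.0
    return ThreeStateParams(
        dG_NI=m_guess * max(cm1, 0.1),
        m_NI=m_guess,
        dG_IU=m_guess * max(cm2, 0.2),
        m_IU=m_guess,
        Y_N=y_n,
        Y_I=0.5 * (y_n + y_u),
        Y_U=y_u,
    )


_M_MAX = 10.0
_DG_MAX = 50.0


def fit_three_state(
    curve: ChemUnfoldCurve,
    init: ThreeStateParams | None = None,
    fix_Y_I: float | None = None,
) -> ThreeStateFit:
    """Least-squares fit of the three-state LEM model to an unfolding curve.

    The transitions are parameterized through their midpoints (Cm_NI and a
    positive increment to Cm_IU) so Cm_NI < Cm_IU holds by construction;
    dG = m·Cm is a derived parameter whose standard error is propagated
    from the fit covariance.  ``fix_Y_I`` pins the intermediate plateau
    (by default it is free, like the native and unfolded plateaus).
    """
    n = len(curve)
    n_free = 7 if fix_Y_I is None else 6
    if n < max(MIN_POINTS_THREE_STATE, n_free + 1):
        raise ValueError(
            f"three-state fit needs at least {max(MIN_POINTS_THREE_STATE, n_free + 1)} points, got {n}"
        )
    p0 = init if init is not None else _default_init(curve)
    d, y, T = curve.denaturant_M, curve.signal, curve.temperature_K
    span = float(d[-1] - d[0])

    pars = lmfit.Parameters()
    cm1_0 = min(max(p0.dG_NI / p0.m_NI, 1e-3), d[-1])
    cm2_0 = min(max(p0.dG_IU / p0.m_IU, cm1_0 + 1e-2), d[-1] + span)
    pars.add("cm_ni", value=cm1_0, min=1e-6, max=_DG_MAX / 1e-3)
    pars.add("dcm", value=cm2_0 - cm1_0, min=1e-6)
    pars.add("m_ni", value=p0.m_NI, min=1e-6, max=_M_MAX)
    pars.add("m_iu", value=p0.m_IU, min=1e-6, max=_M_MAX)
    pars.add("dg_ni", expr="m_ni * cm_ni", max=_DG_MAX)
    pars.add("dg_iu", expr="m_iu * (cm_ni + dcm)", max=_DG_MAX)
    pars.add("y_n", value=p0.Y_N)
    pars.add("y_u", value=p0.Y_U)
    if fix_Y_I is None:
        pars.add("y_i", value=p0.Y_I)
    else:
        pars.add("y_i", value=float(fix_Y_I), vary=False)

    def _residual(pr):
        p = ThreeStateParams(
            dG_NI=pr["dg_ni"].value,
            m_NI=pr["m_ni"].value,
            dG_IU=pr["dg_iu"].value,
            m_IU=pr["m_iu"].value,
            Y_N=pr["y_n"].value,
            Y_I=pr["y_i"].value,
            Y_U=pr["y_u"].value,
        )
        return three_state_fraction(d, p, T) - y

    result = lmfit.minimize(_residual, pars, method="leastsq", max_nfev=20000)
    rp = result.params
    fitted = ThreeStateParams(
        dG_NI=rp["dg_ni"].value,
        m_NI=rp["m_ni"].value,
        dG_IU=rp["dg_iu"].value,
        m_IU=rp["m_iu"].value,
        Y_N=rp["y_n"].value,
        Y_I=rp["y_i"].value,
        Y_U=rp["y_u"].value,
    )
    name_map = {
        "dG_NI": "dg_ni", "dG_IU": "dg_iu", "m_NI": "m_ni", "m_IU": "m_iu",
        "Y_N": "y_n", "Y_I": "y_i", "Y_U": "y_u",
        "Cm_NI": "cm_ni",
    }
    se = {}
    for out_name, par_name in name_map.items():
        err = rp[par_name].stderr
        se[out_name] = float(err) if err is not None else float("nan")
    # se of Cm_IU from cm_ni + dcm, ignoring their covariance would overstate;
    # use the propagated stderr when lmfit provides a covariance.
    if result.covar is not None and "dcm" in result.var_names:
        i = result.var_names.index("cm_ni")
        j = result.var_names.index("dcm")
        var = result.covar[i, i] + result.covar[j, j] + 2 * result.covar[i, j]
        se["Cm_IU"] = float(math.sqrt(max(var, 0.0)))
    else:
        se["Cm_IU"] = float("nan")

    resid = np.asarray(result.residual, dtype=float)
    fit = ThreeStateFit(
        params=fitted,
        se=se,
        Cm_NI=fitted.dG_NI / fitted.m_NI,
        Cm_IU=fitted.dG_IU / fitted.m_IU,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=bool(result.success),
        n_points=n,
    )
    if not result.success:
        warnings.warn(
            f"three-state fit did not converge: {result.message} "
            f"(residual rms {fit.residual_rms:.3g})",
            RuntimeWarning,
        )
    return fit
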