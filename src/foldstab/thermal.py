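"""DSC thermogram analysis and thermal CD melting curves.

Covers baseline subtraction with a progress-weighted pre/post connection,
calorimetric-enthalpy integration, deconvolution into independent
two-state transitions (each with its own calorimetric and van't Hoff
enthalpy — the "non-two-state" model), scan-to-scan reversibility
scoring, Kirchhoff regression of ΔH_cal against Tm to estimate ΔCp, the
per-residue ΔCp normalization, and logistic Tm fitting of thermal CD
traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import lmfit
import numpy as np
from scipy import stats

from .constants import R_GAS, celsius_to_kelvin
from .sigmoid import SigmoidFit, fit_logistic

__all__ = [
    "Thermogram",
    "TransitionFit",
    "DSCFit",
    "KirchhoffFit",
    "ThermalCDCurve",
    "subtract_baseline",
    "integrate_dHcal",
    "two_state_excess_cp",
    "fit_dsc",
    "reversibility_fraction",
    "fit_kirchhoff",
    "per_residue_dcp",
    "fit_tm_sigmoid",
]

MIN_SCAN_POINTS = 50
#: classification threshold for scan-to-scan reversibility
REVERSIBILITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class Thermogram:
    """One DSC scan: molar heat capacity (kcal/mol/K) versus temperature (°C)."""

    temp_C: np.ndarray
    cp: np.ndarray
    scan_rate_C_per_min: float = 1.0
    scan_index: int = 1

    def __post_init__(self):
        t = np.asarray(self.temp_C, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "temp_C", t)
        object.__setattr__(self, "cp", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("temp_C and cp must be 1-D and equal length")
        if t.size < MIN_SCAN_POINTS:
            raise ValueError(f"a thermogram needs >= {MIN_SCAN_POINTS} points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temp_C must be strictly increasing")
        if not self.scan_rate_C_per_min > 0:
            raise ValueError("scan_rate_C_per_min must be positive")


@dataclass(frozen=True)
class TransitionFit:
    """A single unfolding transition: midpoint and the two enthalpies.

    dH_cal is the area under the excess heat-capacity peak; dH_vH sets the
    peak shape.  Their ratio diagnoses deviation from two-state behavior.
    """

    Tm_C: float
    dH_cal: float
    dH_vH: float

    def __post_init__(self):
        if not (self.dH_cal > 0 and self.dH_vH > 0):
            raise ValueError("both enthalpies must be positive")


@dataclass(frozen=True)
class DSCFit:
    """Deconvolution of an excess-Cp thermogram into ordered transitions."""

    transitions: tuple[TransitionFit, ...]
    se: tuple[dict[str, float], ...]
    residual_rms: float
    converged: bool

    def __post_init__(self):
        tms = [tr.Tm_C for tr in self.transitions]
        if any(b - a <= 1.0 for a, b in zip(tms, tms[1:])):
            raise ValueError("transitions must be Tm-ascending with > 1 °C separation")


@dataclass(frozen=True)
class KirchhoffFit:
    """Linear Kirchhoff regression ΔH_cal(Tm) = ΔH_ref + ΔCp (Tm − Tm_ref)."""

    dCp: float
    dH_ref: float
    Tm_ref_C: float
    se_dCp: float
    se_dH_ref: float = float("nan")

    def __post_init__(self):
        if not (math.isnan(self.se_dCp) or self.se_dCp >= 0):
            raise ValueError("se_dCp must be non-negative")


@dataclass(frozen=True)
class ThermalCDCurve:
    """Thermal CD melting trace (mean residue ellipticity or delta-signal)."""

    temp_C: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temp_C, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temp_C", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("temp_C and signal must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temp_C must be strictly increasing")


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return intercept, slope


def subtract_baseline(
    t: Thermogram,
    pre_range: tuple[float, float],
    post_range: tuple[float, float],
    connection: str = "progress",
    n_iter: int = 3,
) -> Thermogram:
    """Remove the instrumental baseline from a DSC scan.

    Straight lines are fitted in the pre- and post-transition windows and
    joined either by a progress-weighted connection (weight = cumulative
    normalized excess-heat area, the calorimetric standard) or by a simple
    linear chord (``connection="chord"``).  The returned thermogram is the
    excess heat capacity, ≈ 0 inside both fitted windows.
    """
    lo1, hi1 = sorted(pre_range)
    lo2, hi2 = sorted(post_range)
    if hi1 > lo2:
        raise ValueError("pre_range must lie entirely below post_range")
    temp, cp = t.temp_C, t.cp
    pre_mask = (temp >= lo1) & (temp <= hi1)
    post_mask = (temp >= lo2) & (temp <= hi2)
    if pre_mask.sum() < 5 or post_mask.sum() < 5:
        raise ValueError("each baseline range must contain at least 5 scan points")
    a1, b1 = _fit_line(temp[pre_mask], cp[pre_mask])
    a2, b2 = _fit_line(temp[post_mask], cp[post_mask])
    pre_line = a1 + b1 * temp
    post_line = a2 + b2 * temp

    if connection == "chord":
        t_mid1, t_mid2 = 0.5 * (lo1 + hi1), 0.5 * (lo2 + hi2)
        alpha = np.clip((temp - t_mid1) / (t_mid2 - t_mid1), 0.0, 1.0)
        baseline = (1 - alpha) * pre_line + alpha * post_line
        return replace(t, cp=cp - baseline)
    if connection != "progress":
        raise ValueError(f"unknown connection rule {connection!r}")

    # progress-weighted: iterate because the weight depends on the excess
    alpha = np.clip((temp - hi1) / max(lo2 - hi1, 1e-12), 0.0, 1.0)
    excess = cp - ((1 - alpha) * pre_line + alpha * post_line)
    for _ in range(n_iter):
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (excess[1:] + excess[:-1]) * np.diff(temp))])
        total = cum[-1]
        if abs(total) < 1e-12:
            break  # no excess heat: both lines already describe the scan
        alpha = np.clip(cum / total, 0.0, 1.0)
        excess = cp - ((1 - alpha) * pre_line + alpha * post_line)
    return replace(t, cp=excess)


def integrate_dHcal(excess: Thermogram, t_lo: float, t_hi: float) -> float:
    """Calorimetric enthalpy: trapezoidal ∫ Cp dT over [t_lo, t_hi] (kcal/mol)."""
    if t_hi <= t_lo:
        raise ValueError("integration window is empty")
    temp, cp = excess.temp_C, excess.cp
    if t_lo < temp[0] - 1e-9 or t_hi > temp[-1] + 1e-9:
        raise ValueError(
            f"window [{t_lo}, {t_hi}] °C extends beyond the scan range "
            f"[{temp[0]}, {temp[-1]}] °C"
        )
    mask = (temp >= t_lo) & (temp <= t_hi)
    if mask.sum() < 2:
        raise ValueError("integration window contains fewer than 2 scan points")
    return float(np.trapezoid(cp[mask], temp[mask]))


def two_state_excess_cp(T_K: np.ndarray | float, tr: TransitionFit) -> np.ndarray | float:
    """Excess heat capacity of one two-state transition at temperature T (K).

    With K(T) = exp(-(dH_vH/R)(1/T - 1/Tm)):
    Cp_exc = dH_cal * dH_vH / (R T²) * K / (1 + K)².
    Its integral over temperature equals dH_cal.
    """
    T_K = np.asarray(T_K, dtype=float)
    if np.any(T_K <= 0):
        raise ValueError("temperature must be positive (K)")
    tm_k = celsius_to_kelvin(tr.Tm_C)
    ln_k = -(tr.dH_vH / R_GAS) * (1.0 / T_K - 1.0 / tm_k)
    # K/(1+K)^2 = 1/4 sech^2(lnK/2): overflow-safe for |lnK| large
    shape = 0.25 / np.cosh(0.5 * ln_k) ** 2
    out = tr.dH_cal * tr.dH_vH / (R_GAS * T_K**2) * shape
    return float(out) if np.ndim(out) == 0 else out


def model_excess_cp(
    temp_C: np.ndarray, transitions: list[TransitionFit] | tuple[TransitionFit, ...]
) -> np.ndarray:
    """Sum of independent two-state excess-Cp terms on a °C grid."""
    T_K = celsius_to_kelvin(np.asarray(temp_C, dtype=float))
    total = np.zeros_like(T_K)
    for tr in transitions:
        total += two_state_excess_cp(T_K, tr)
    return total


def fit_dsc(
    excess: Thermogram,
    n_transitions: int = 2,
    init: list[TransitionFit] | None = None,
    constrain_vh: bool = False,
) -> DSCFit:
    """Deconvolve an excess-Cp thermogram into 1–3 independent transitions.

    Each transition contributes a two_state_excess_cp term with its own
    Tm, dH_cal and dH_vH.  ``constrain_vh=True`` pins dH_vH = dH_cal per
    transition (free by default).  Transitions are returned Tm-ascending.
    """
    if n_transitions not in (1, 2, 3):
        raise ValueError("n_transitions must be 1, 2 or 3")
    temp, cp = excess.temp_C, excess.cp
    if init is not None and len(init) != n_transitions:
        raise ValueError("init must supply one TransitionFit per transition")
    candidates = [init] if init is not None else _candidate_inits(excess, n_transitions)

    t_lo, t_hi = float(temp[0]), float(temp[-1])

    def _unpack(pr) -> list[TransitionFit]:
        return [
            TransitionFit(pr[f"tm{i}"].value, pr[f"dhcal{i}"].value, pr[f"dhvh{i}"].value)
            for i in range(n_transitions)
        ]

    def _residual(pr):
        return model_excess_cp(temp, _unpack(pr)) - cp

    result = None
    for cand in candidates:
        pars = lmfit.Parameters()
        for i, tr in enumerate(sorted(cand, key=lambda x: x.Tm_C)):
            pars.add(f"tm{i}", value=tr.Tm_C, min=t_lo, max=t_hi)
            pars.add(f"dhcal{i}", value=tr.dH_cal, min=1e-3)
            if constrain_vh:
                pars.add(f"dhvh{i}", expr=f"dhcal{i}")
            else:
                pars.add(f"dhvh{i}", value=tr.dH_vH, min=1e-3)
        attempt = lmfit.minimize(_residual, pars, method="leastsq", max_nfev=20000)
        if result is None or attempt.chisqr < result.chisqr:
            result = attempt
    fitted = _unpack(result.params)
    order = np.argsort([tr.Tm_C for tr in fitted])
    transitions = tuple(fitted[i] for i in order)
    se = tuple(
        {
            "Tm_C": _stderr(result.params[f"tm{i}"]),
            "dH_cal": _stderr(result.params[f"dhcal{i}"]),
            "dH_vH": _stderr(result.params[f"dhvh{i}"]),
        }
        for i in order
    )
    resid = np.asarray(result.residual, dtype=float)
    rms = float(np.sqrt(np.mean(resid**2)))
    if not result.success:
        warnings.warn(
            f"DSC deconvolution did not converge: {result.message} (residual rms {rms:.3g})",
            RuntimeWarning,
        )
    return DSCFit(transitions=transitions, se=se, residual_rms=rms, converged=bool(result.success))


def _stderr(par) -> float:
    return float(par.stderr) if par.stderr is not None else float("nan")


def _candidate_inits(excess: Thermogram, n: int) -> list[list[TransitionFit]]:
    """Structured multistart: overlapping unequal transitions make the
    deconvolution multimodal, so try an equal-area split plus peak-anchored
    splits with the dominant amplitude on the main peak."""
    cands = [_init_transitions(excess, n)]
    if n >= 2:
        temp, cp = excess.temp_C, np.clip(excess.cp, 0.0, None)
        total = max(float(np.trapezoid(cp, temp)), 1.0)
        t_peak = float(temp[int(np.argmax(cp))])
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(temp))])
        t_hiq = float(np.interp(0.95 * cum[-1], cum, temp))
        t_loq = float(np.interp(0.05 * cum[-1], cum, temp))
        span = max(temp[-1] - temp[0], 1.0)
        for minority_tm in (t_hiq, t_loq, t_peak + 0.1 * span, t_peak - 0.1 * span):
            if not (temp[0] < minority_tm < temp[-1]):
                continue
            if abs(minority_tm - t_peak) < 1e-6:
                continue
            tms = sorted([t_peak, minority_tm] + [
                temp[0] + (i + 1) * span / (n + 1) for i in range(n - 2)
            ])
            cands.append([
                TransitionFit(Tm_C=tm, dH_cal=(0.8 if tm == t_peak else 0.2 / (n - 1)) * total,
                              dH_vH=max(0.5 * total, 20.0))
                for tm in tms
            ])
    return cands


def _init_transitions(excess: Thermogram, n: int) -> list[TransitionFit]:
    """Moment-based starting guesses: split the scan into n equal-area slabs."""
    temp, cp = excess.temp_C, np.clip(excess.cp, 0.0, None)
    total = np.trapezoid(cp, temp)
    if total <= 0:
        total = 1.0
        cp = np.ones_like(cp)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(temp))])
    guesses = []
    for i in range(n):
        lo_q, mid_q, hi_q = (i / n) * cum[-1], ((i + 0.5) / n) * cum[-1], ((i + 1) / n) * cum[-1]
        tm = float(np.interp(mid_q, cum, temp))
        dh = max(float(hi_q - lo_q), 1.0)
        guesses.append(TransitionFit(Tm_C=tm, dH_cal=dh, dH_vH=max(dh, 20.0)))
    return guesses


def reversibility_fraction(
    scan1: Thermogram, scan2: Thermogram
) -> tuple[float, bool]:
    """Ratio of excess-heat areas of a rescan to the first scan.

    Each scan is chord-corrected (straight line through the mean of its
    first and last few points over the shared temperature window) before
    trapezoidal integration, so a shared instrumental baseline cancels.
    Classified reversible when the ratio is >= 0.95.
    """
    lo = max(scan1.temp_C[0], scan2.temp_C[0])
    hi = min(scan1.temp_C[-1], scan2.temp_C[-1])
    if hi <= lo:
        raise ValueError("scans share no temperature overlap")

    def _area(scan: Thermogram) -> float:
        mask = (scan.temp_C >= lo) & (scan.temp_C <= hi)
        t, c = scan.temp_C[mask], scan.cp[mask]
        if t.size < 2:
            raise ValueError("overlap window contains fewer than 2 points")
        k = max(1, t.size // 20)
        y0, y1 = float(np.mean(c[:k])), float(np.mean(c[-k:]))
        x0, x1 = float(np.mean(t[:k])), float(np.mean(t[-k:]))
        chord = y0 + (y1 - y0) * (t - x0) / max(x1 - x0, 1e-12)
        return float(np.trapezoid(c - chord, t))

    a1 = _area(scan1)
    if a1 <= 0:
        raise ValueError("first scan has non-positive excess-heat area")
    ratio = max(_area(scan2), 0.0) / a1
    return ratio, ratio >= REVERSIBILITY_THRESHOLD


def fit_kirchhoff(
    series: list[tuple[float, float]] | np.ndarray,
    Tm_ref_C: float | None = None,
) -> KirchhoffFit:
    """ΔCp from the Kirchhoff plot: slope of ΔH_cal against Tm.

    ``series`` holds (Tm_C, dH_cal) pairs from denaturant-perturbed scans;
    Tm_ref defaults to the highest (zero-denaturant) Tm.  Unweighted
    ordinary least squares.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (Tm_C, dH_cal) pairs")
    tm, dh = arr[:, 0], arr[:, 1]
    if np.ptp(tm) == 0:
        raise ValueError("all Tm values identical: Kirchhoff regression is rank-deficient")
    if Tm_ref_C is None:
        Tm_ref_C = float(tm.max())
    res = stats.linregress(tm - Tm_ref_C, dh)
    return KirchhoffFit(
        dCp=float(res.slope),
        dH_ref=float(res.intercept),
        Tm_ref_C=float(Tm_ref_C),
        se_dCp=float(res.stderr) if arr.shape[0] > 2 else float("nan"),
        se_dH_ref=float(res.intercept_stderr),
    )


def per_residue_dcp(dCp: float, n_residues: int) -> float:
    """ΔCp per residue in cal/mol/K: 1000·dCp/n, reported to one decimal."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return round(1000.0 * dCp / n_residues, 1)


def fit_tm_sigmoid(curve: ThermalCDCurve) -> SigmoidFit:
    """Tm from a thermal CD trace via a four-parameter logistic fit.

    A non-monotonic trace (beyond ~3 noise sd around the fit) triggers a
    warning, not a failure.
    """
    fit = fit_logistic(curve.temp_C, curve.signal)
    resid_sd = fit.residual_rms if fit.residual_rms > 0 else 1e-12
    dy = np.diff(curve.signal)
    direction = np.sign(fit.upper - fit.lower)
    if np.any(direction * dy < -6.0 * resid_sd * math.sqrt(2.0)):
        warnings.warn("thermal CD trace is not monotonic beyond noise tolerance", UserWarning)
    return fit
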