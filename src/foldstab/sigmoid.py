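"""Shared four-parameter logistic transition fit.

One functional form serves every "sigmoidal function" midpoint in the
pipeline — thermal CD melting (Tm_CD), sedimentation-coefficient
transitions (Cm_AUC) and molar-mass transitions (Cm_SEC-MALLS) — so the
midpoints stay directly comparable:

    y(x) = lower + (upper - lower) / (1 + exp(-(x - midpoint) / width))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["SigmoidFit", "logistic", "fit_logistic"]


@dataclass(frozen=True)
class SigmoidFit:
    """A fitted logistic transition; units of midpoint follow the x axis."""

    lower: float
    upper: float
    midpoint: float
    width: float
    se_midpoint: float
    residual_rms: float = 0.0

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError("width must be positive")

    def __call__(self, x):
        return logistic(x, self.lower, self.upper, self.midpoint, self.width)


def logistic(x, lower, upper, midpoint, width):
    x = np.asarray(x, dtype=float)
    z = np.clip((x - midpoint) / width, -500, 500)
    return lower + (upper - lower) / (1.0 + np.exp(-z))


def fit_logistic(x, y, min_points: int = 5) -> SigmoidFit:
    """Least-squares four-parameter logistic fit.

    Direction (rising or falling) is taken from the data; a flat series
    with no resolvable transition raises a fit-failure ValueError.  The
    midpoint standard error comes from the fit covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.shape != x.shape:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < min_points:
        raise ValueError(f"logistic fit needs at least {min_points} points, got {x.size}")
    amp = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    if amp < 1e-10 * scale:
        raise ValueError("no transition detectable: response is flat")
    k = max(1, x.size // 10)
    lo0, up0 = float(np.mean(y[:k])), float(np.mean(y[-k:]))
    # midpoint guess: where the signal crosses half its range
    half = 0.5 * (lo0 + up0)
    idx = int(np.argmin(np.abs(y - half)))
    mid0 = float(x[idx])
    width0 = max(float(np.ptp(x)) / 20.0, 1e-6)
    span = float(np.ptp(x))
    try:
        popt, pcov = curve_fit(
            logistic,
            x,
            y,
            p0=[lo0, up0, mid0, width0],
            bounds=([-np.inf, -np.inf, x[0] - span, 1e-9], [np.inf, np.inf, x[-1] + span, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"logistic fit failed to converge: {exc}") from exc
    lower, upper, midpoint, width = (float(v) for v in popt)
    se_mid = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("inf")
    resid = y - logistic(x, *popt)
    return SigmoidFit(
        lower=lower,
        upper=upper,
        midpoint=midpoint,
        width=width,
        se_midpoint=se_mid,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
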