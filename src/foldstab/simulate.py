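"""Synthetic instrument-style data with known ground truth.

Every input class the analysis modules consume can be generated here:
three-state chemical-unfolding curves, two-transition DSC thermograms
(first scan plus a rescan at a stated reversibility), Kirchhoff
(Tm, ΔH_cal) series, logistic transition series for sedimentation /
molar-mass / thermal-CD observables, acrylamide quenching series and
Gaussian emission spectra.  Generators are bit-reproducible: the same
SimSpec (including seed) always yields the same arrays.  Each output
array draws from its own deterministic sub-stream, so adding an output
never shifts the draws of an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .equilibrium import ChemUnfoldCurve, ThreeStateParams, three_state_fraction
from .fluor import QuenchSeries
from .hydro import MMSeries, SedSeries
from .thermal import Thermogram, ThermalCDCurve, TransitionFit, model_excess_cp

__all__ = [
    "SimSpec",
    "default_grid",
    "gen_chem_unfold",
    "gen_dsc",
    "gen_kirchhoff_series",
    "gen_logistic_series",
    "gen_quench_series",
    "gen_emission_spectrum",
]

MODEL_KINDS = (
    "chem_three_state",
    "dsc_two_transition",
    "kirchhoff_line",
    "logistic_series",
    "stern_volmer",
    "emission_spectrum",
)

#: grids mirroring the experimental designs the generators emulate
_DEFAULT_GRIDS = {
    "chem_three_state": ("urea 0-6 M step 0.1", lambda: np.round(np.arange(0.0, 6.0 + 1e-9, 0.1), 10)),
    "dsc_two_transition": ("15-90 C step 0.25", lambda: np.round(np.arange(15.0, 90.0 + 1e-9, 0.25), 10)),
    "stern_volmer": ("0-100 mM step 10", lambda: np.round(np.arange(0.0, 0.1 + 1e-9, 0.01), 10)),
    "logistic_series": ("urea 0-6 M step 0.25", lambda: np.round(np.arange(0.0, 6.0 + 1e-9, 0.25), 10)),
    "emission_spectrum": ("300-450 nm step 1", lambda: np.arange(300.0, 450.0 + 1e-9, 1.0)),
}


def default_grid(model_kind: str) -> np.ndarray:
    """The sampling grid each instrument emulation uses unless overridden."""
    if model_kind not in _DEFAULT_GRIDS:
        raise ValueError(f"no default grid for model kind {model_kind!r}")
    return _DEFAULT_GRIDS[model_kind][1]()


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one synthetic dataset.

    ``truth`` holds the generating parameters of ``model_kind``; ``grid``
    the sampling points (None → the kind's default grid); ``noise_sd``
    the Gaussian noise scale in observable units (multiplicative relative
    scale for quenching); ``seed`` the reproducibility seed.
    """

    model_kind: str
    truth: dict[str, Any]
    grid: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.size == 0:
                raise ValueError("grid must be non-empty")
            object.__setattr__(self, "grid", g)

    def resolved_grid(self) -> np.ndarray:
        return self.grid if self.grid is not None else default_grid(self.model_kind)

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic sub-stream ``stream`` of this spec's seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def gen_chem_unfold(spec: SimSpec) -> ChemUnfoldCurve:
    """Fraction-unfolded urea curve from the three-state forward model.

    truth: ``params`` (ThreeStateParams) and optional ``temperature_K``.
    """
    params = spec.truth["params"]
    if not isinstance(params, ThreeStateParams):
        params = ThreeStateParams(**params)
    temp_k = float(spec.truth.get("temperature_K", 293.15))
    d = spec.resolved_grid()
    y = three_state_fraction(d, params, temp_k)
    y = y + spec.rng(0).normal(0.0, spec.noise_sd, size=d.shape) if spec.noise_sd else y
    return ChemUnfoldCurve(denaturant_M=d, signal=y, temperature_K=temp_k, signal_kind="fraction")


def gen_dsc(spec: SimSpec) -> list[Thermogram]:
    """First DSC scan (baseline + transitions + noise) and optional rescan.

    truth: ``transitions`` (list of TransitionFit or dicts), optional
    ``baseline`` (intercept, slope in kcal/mol/K per °C), optional
    ``reversibility`` r ∈ [0, 1] triggering a second scan whose
    transition amplitudes are scaled by r.
    """
    grid = spec.resolved_grid()
    transitions = [
        tr if isinstance(tr, TransitionFit) else TransitionFit(**tr)
        for tr in spec.truth["transitions"]
    ]
    for tr in transitions:
        if not (grid[0] <= tr.Tm_C <= grid[-1]):
            raise ValueError(f"Tm {tr.Tm_C} °C outside the scan grid [{grid[0]}, {grid[-1]}] °C")
    intercept, slope = spec.truth.get("baseline", (0.0, 0.0))
    baseline = intercept + slope * grid
    peak = model_excess_cp(grid, transitions)

    cp1 = baseline + peak
    if spec.noise_sd:
        cp1 = cp1 + spec.rng(0).normal(0.0, spec.noise_sd, size=grid.shape)
    scans = [Thermogram(temp_C=grid, cp=cp1, scan_index=1)]

    r = spec.truth.get("reversibility")
    if r is not None:
        if not 0.0 <= r <= 1.0:
            raise ValueError("reversibility must lie in [0, 1]")
        cp2 = baseline + r * peak
        if spec.noise_sd:
            cp2 = cp2 + spec.rng(1).normal(0.0, spec.noise_sd, size=grid.shape)
        scans.append(Thermogram(temp_C=grid, cp=cp2, scan_index=2))
    return scans


def gen_kirchhoff_series(spec: SimSpec) -> list[tuple[float, float]]:
    """(Tm_C, dH_cal) pairs on a Kirchhoff line, optionally noisy in dH.

    truth: ``dCp`` (kcal/mol/K), ``dH_ref`` (kcal/mol), ``Tm_ref_C`` and
    ``Tm_shifts_C`` — the downward Tm perturbations the denaturant series
    produces (one per condition, e.g. urea 0.25–2 M).
    """
    shifts = np.asarray(spec.truth["Tm_shifts_C"], dtype=float)
    if shifts.size < 3:
        raise ValueError("need at least 3 conditions for a Kirchhoff series")
    tm_ref = float(spec.truth["Tm_ref_C"])
    tm = tm_ref - shifts
    dh = spec.truth["dH_ref"] + spec.truth["dCp"] * (tm - tm_ref)
    if spec.noise_sd:
        dh = dh + spec.rng(0).normal(0.0, spec.noise_sd, size=tm.shape)
    return list(zip(tm.tolist(), dh.tolist()))


def gen_logistic_series(spec: SimSpec, kind: str = "sed"):
    """Logistic transition data: 'sed' → SedSeries, 'mm' → MMSeries,
    'thermal_cd' → ThermalCDCurve.

    truth: ``lower``, ``upper`` (plateaus at low/high x), ``midpoint``,
    ``width``.
    """
    x = spec.resolved_grid()
    lo, up = float(spec.truth["lower"]), float(spec.truth["upper"])
    mid, width = float(spec.truth["midpoint"]), float(spec.truth["width"])
    if width <= 0:
        raise ValueError("width must be positive")
    y = lo + (up - lo) / (1.0 + np.exp(-(x - mid) / width))
    if spec.noise_sd:
        y = y + spec.rng(0).normal(0.0, spec.noise_sd, size=x.shape)
    if kind == "sed":
        return SedSeries(urea_M=x, s0_20w_S=y)
    if kind == "mm":
        return MMSeries(urea_M=x, mm_kDa=y)
    if kind == "thermal_cd":
        return ThermalCDCurve(temp_C=x, signal=y)
    raise ValueError(f"unknown logistic series kind {kind!r}")


def gen_quench_series(spec: SimSpec) -> QuenchSeries:
    """Stern–Volmer quenching series F = F0 / (1 + Ksv [Q]).

    truth: ``F0`` and ``Ksv`` (M^-1); noise_sd is a multiplicative
    relative scale (0.01 → 1% intensity noise).  The zero-quencher point
    is left noise-free so F0 stays the exact reference.
    """
    ksv = float(spec.truth["Ksv"])
    if ksv < 0:
        raise ValueError("Ksv must be non-negative")
    f0 = float(spec.truth.get("F0", 100.0))
    q = spec.resolved_grid()
    f = f0 / (1.0 + ksv * q)
    if spec.noise_sd:
        factors = 1.0 + spec.rng(0).normal(0.0, spec.noise_sd, size=q.shape)
        factors[0] = 1.0
        f = f * np.clip(factors, 1e-6, None)
    return QuenchSeries(quencher_M=q, intensity=f)


def gen_emission_spectrum(spec: SimSpec):
    """Gaussian tryptophan-like emission band.

    truth: ``center_nm``, ``width_nm``, optional ``amplitude``.
    """
    from .fluor import EmissionSpectrum

    lam = spec.resolved_grid()
    center = float(spec.truth["center_nm"])
    width = float(spec.truth["width_nm"])
    amp = float(spec.truth.get("amplitude", 1000.0))
    inten = amp * np.exp(-0.5 * ((lam - center) / width) ** 2)
    if spec.noise_sd:
        inten = inten + spec.rng(0).normal(0.0, spec.noise_sd, size=lam.shape)
    return EmissionSpectrum(lambda_nm=lam, intensity=np.clip(inten, 0.0, None))
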