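"""Config-driven orchestration of the unfolding-analysis stages.

A single YAML config names a protein (with its domain residue counts and
monomer mass), the input files for each stage, and stage options.  Stages
may be omitted independently; the aggregated stability report then simply
lacks those rows.  Outputs are deterministic: identical inputs and seeds
produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as fio
from .equilibrium import fit_three_state
from .fluor import center_of_spectral_mass, fit_stern_volmer
from .hydro import classify_oligomer, fit_transition_midpoint
from .thermal import (
    fit_dsc,
    fit_kirchhoff,
    fit_tm_sigmoid,
    integrate_dHcal,
    per_residue_dcp,
    reversibility_fraction,
    subtract_baseline,
)

__all__ = ["ProteinConfig", "StabilityReport", "run_pipeline", "write_summary"]

#: Report row order: chemical unfolding, hydrodynamic midpoints, calorimetry,
#: thermal CD, per-residue normalization, then fluorescence extras.
REPORT_FIELDS = [
    ("dG_NI", "kcal/mol"),
    ("dG_IU", "kcal/mol"),
    ("m_NI", "kcal/mol/M"),
    ("m_IU", "kcal/mol/M"),
    ("Cm_NI", "M"),
    ("Cm_IU", "M"),
    ("Cm_AUC", "M"),
    ("Cm_SEC_MALLS", "M"),
    ("Tm_1", "C"),
    ("Tm_2", "C"),
    ("dH1_cal", "kcal/mol"),
    ("dH2_cal", "kcal/mol"),
    ("dCp_1", "kcal/mol/K"),
    ("dCp_2", "kcal/mol/K"),
    ("Tm_CD", "C"),
    ("dCp1_residue", "cal/mol/K"),
    ("dCp2_residue", "cal/mol/K"),
    ("Ksv_25C", "1/M"),
    ("Ksv_40C", "1/M"),
    ("center_spectral_mass", "nm"),
    ("oligomer_native", ""),
    ("oligomer_denatured", ""),
    ("reversibility", ""),
]


@dataclass(frozen=True)
class ProteinConfig:
    """Protein metadata the report depends on.

    ``n_residues_ctd`` normalizes the first-transition ΔCp (C-terminal
    domain size); ``n_residues_nterm`` the second (J-domain + G/F region,
    121 residues for the Sis1 constructs).
    """

    name: str
    n_residues_ctd: int | None = None
    n_residues_nterm: int | None = None
    vbar_mL_g: float | None = None
    monomer_mass_kDa: float | None = None

    def __post_init__(self):
        for label, n in (("n_residues_ctd", self.n_residues_ctd),
                         ("n_residues_nterm", self.n_residues_nterm)):
            if n is not None and n <= 0:
                raise ValueError(f"{label} must be positive")


@dataclass
class StabilityReport:
    """Aggregated per-protein results: {field: (value, se)} plus any
    stage-level failure messages."""

    protein: str
    values: dict[str, tuple[float | str, float]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def set(self, key: str, value, se: float = float("nan")) -> None:
        self.values[key] = (value, se)

    @property
    def ok(self) -> bool:
        return not self.failures


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path, plot: bool = False) -> StabilityReport:
    """Run every stage declared in a YAML config and aggregate the report.

    All referenced input files are checked before any computation; a
    missing file raises FileNotFoundError naming it.  A stage that fails
    during fitting is recorded in ``report.failures`` and the remaining
    stages still run.  Writes per-stage fit records, the summary (both
    formats) and a run manifest into the configured output directory.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    protein = ProteinConfig(**cfg.get("protein", {"name": "unnamed"}))
    stages: dict = cfg.get("stages", {})
    out_dir = Path(cfg.get("output_dir", config_path.parent / "foldstab_out"))
    seed = cfg.get("seed")

    # -- validate every declared input before touching any of them
    input_files: list[Path] = []
    for stage, opts in stages.items():
        for key, val in (opts or {}).items():
            vals = val if isinstance(val, list) else [val]
            for v in vals:
                if isinstance(v, str) and v.endswith((".csv", ".tsv", ".fasta", ".fa")):
                    p = (config_path.parent / v).resolve() if not Path(v).is_absolute() else Path(v)
                    if not p.exists():
                        raise FileNotFoundError(f"stage {stage!r}: input file not found: {v}")
                    input_files.append(p)

    out_dir.mkdir(parents=True, exist_ok=True)
    report = StabilityReport(protein=protein.name)

    def _resolve(name: str) -> Path:
        p = Path(name)
        return p if p.is_absolute() else (config_path.parent / p)

    def _log(msg: str) -> None:
        print(f"[foldstab] {msg}", file=sys.stderr)

    # -- chemical unfolding -------------------------------------------------
    if "chem" in stages:
        opts = stages["chem"]
        try:
            curve = fio.read_chem_curve(_resolve(opts["curve"]))
            fit = fit_three_state(curve)
            p = fit.params
            for key, val in (
                ("dG_NI", p.dG_NI), ("dG_IU", p.dG_IU),
                ("m_NI", p.m_NI), ("m_IU", p.m_IU),
                ("Cm_NI", fit.Cm_NI), ("Cm_IU", fit.Cm_IU),
            ):
                report.set(key, val, fit.se.get(key, float("nan")))
            fio.write_fit_records(
                [
                    {"parameter": k, "value": v[0], "standard_error": v[1], "unit": u}
                    for (k, u) in REPORT_FIELDS[:6]
                    for v in [report.values[k]]
                ],
                out_dir / "chem_fit.csv",
            )
            _log(f"chem: Cm_NI={fit.Cm_NI:.2f} M, Cm_IU={fit.Cm_IU:.2f} M")
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report.failures["chem"] = str(exc)
            _log(f"chem stage FAILED: {exc}")

    # -- DSC ----------------------------------------------------------------
    if "dsc" in stages:
        opts = stages["dsc"]
        try:
            scans = [fio.read_thermogram(_resolve(f)) for f in opts["scans"]]
            # scans are used as excess heat capacity unless baseline windows
            # are declared (instrument exports are often already baseline-treated)
            if "pre_range" in opts and "post_range" in opts:
                excess = subtract_baseline(scans[0], tuple(opts["pre_range"]),
                                           tuple(opts["post_range"]))
            else:
                excess = scans[0]
            n_tr = int(opts.get("n_transitions", 2))
            dsc = fit_dsc(excess, n_transitions=n_tr,
                          constrain_vh=bool(opts.get("constrain_vh", False)))
            for i, tr in enumerate(dsc.transitions, start=1):
                report.set(f"Tm_{i}", tr.Tm_C, dsc.se[i - 1]["Tm_C"])
                report.set(f"dH{i}_cal", tr.dH_cal, dsc.se[i - 1]["dH_cal"])
            if len(scans) > 1:
                ratio, ok = reversibility_fraction(scans[0], scans[1])
                report.set("reversibility", ratio)
                _log(f"dsc: reversibility {ratio:.2f} ({'accepted' if ok else 'rejected'})")
            fio.write_fit_records(
                [
                    {"parameter": f"Tm_{i}", "value": tr.Tm_C,
                     "standard_error": dsc.se[i - 1]["Tm_C"], "unit": "C"}
                    for i, tr in enumerate(dsc.transitions, start=1)
                ]
                + [
                    {"parameter": f"dH{i}_cal", "value": tr.dH_cal,
                     "standard_error": dsc.se[i - 1]["dH_cal"], "unit": "kcal/mol"}
                    for i, tr in enumerate(dsc.transitions, start=1)
                ],
                out_dir / "dsc_fit.csv",
            )
            _log("dsc: " + ", ".join(f"Tm={tr.Tm_C:.1f} C dHcal={tr.dH_cal:.0f}" for tr in dsc.transitions))
        except Exception as exc:  # noqa: BLE001
            report.failures["dsc"] = str(exc)
            _log(f"dsc stage FAILED: {exc}")

    # -- Kirchhoff ΔCp ------------------------------------------------------
    if "kirchhoff" in stages:
        opts = stages["kirchhoff"]
        for i in (1, 2):
            key = f"transition{i}"
            if key not in opts:
                continue
            try:
                series = fio.read_kirchhoff_series(_resolve(opts[key]))
                kf = fit_kirchhoff(series)
                report.set(f"dCp_{i}", kf.dCp, kf.se_dCp)
                n = protein.n_residues_ctd if i == 1 else protein.n_residues_nterm
                if n:
                    report.set(f"dCp{i}_residue", per_residue_dcp(kf.dCp, n))
                _log(f"kirchhoff[{i}]: dCp={kf.dCp:.2f} kcal/mol/K")
            except Exception as exc:  # noqa: BLE001
                report.failures[f"kirchhoff_{i}"] = str(exc)
                _log(f"kirchhoff[{i}] stage FAILED: {exc}")

    # -- thermal CD ---------------------------------------------------------
    if "thermal_cd" in stages:
        try:
            curve = fio.read_thermal_cd(_resolve(stages["thermal_cd"]["curve"]))
            sf = fit_tm_sigmoid(curve)
            report.set("Tm_CD", sf.midpoint, sf.se_midpoint)
            _log(f"thermal_cd: Tm_CD={sf.midpoint:.1f} C")
        except Exception as exc:  # noqa: BLE001
            report.failures["thermal_cd"] = str(exc)
            _log(f"thermal_cd stage FAILED: {exc}")

    # -- hydrodynamics ------------------------------------------------------
    if "hydro" in stages:
        opts = stages["hydro"]
        if "sed_series" in opts:
            try:
                sed = fio.read_sed_series(_resolve(opts["sed_series"]))
                sf = fit_transition_midpoint(sed.urea_M, sed.s0_20w_S)
                report.set("Cm_AUC", sf.midpoint, sf.se_midpoint)
                _log(f"hydro: Cm_AUC={sf.midpoint:.2f} M")
            except Exception as exc:  # noqa: BLE001
                report.failures["hydro_sed"] = str(exc)
                _log(f"hydro sed stage FAILED: {exc}")
        if "mm_series" in opts:
            try:
                mm = fio.read_mm_series(_resolve(opts["mm_series"]))
                sf = fit_transition_midpoint(mm.urea_M, mm.mm_kDa)
                report.set("Cm_SEC_MALLS", sf.midpoint, sf.se_midpoint)
                if protein.monomer_mass_kDa:
                    report.set("oligomer_native",
                               classify_oligomer(float(mm.mm_kDa[0]), protein.monomer_mass_kDa))
                    report.set("oligomer_denatured",
                               classify_oligomer(float(mm.mm_kDa[-1]), protein.monomer_mass_kDa))
                _log(f"hydro: Cm_SEC_MALLS={sf.midpoint:.2f} M")
            except Exception as exc:  # noqa: BLE001
                report.failures["hydro_mm"] = str(exc)
                _log(f"hydro mm stage FAILED: {exc}")

    # -- fluorescence -------------------------------------------------------
    if "fluor" in stages:
        opts = stages["fluor"]
        if "spectrum" in opts:
            try:
                sp = fio.read_spectrum(_resolve(opts["spectrum"]))
                report.set("center_spectral_mass", center_of_spectral_mass(sp))
            except Exception as exc:  # noqa: BLE001
                report.failures["fluor_spectrum"] = str(exc)
        for label, key in (("Ksv_25C", "quench"), ("Ksv_25C", "quench_25C"), ("Ksv_40C", "quench_40C")):
            if key not in opts:
                continue
            try:
                qs = fio.read_quench_series(_resolve(opts[key]))
                sv = fit_stern_volmer(qs, force_intercept=bool(opts.get("force_intercept", False)))
                report.set(label, sv.Ksv_per_M, sv.se)
                _log(f"fluor[{key}]: Ksv={sv.Ksv_per_M:.2f} /M (intercept {sv.intercept:.3f})")
            except Exception as exc:  # noqa: BLE001
                report.failures[f"fluor_{key}"] = str(exc)

    # -- outputs ------------------------------------------------------------
    write_summary(report, out_dir / "summary.csv", format="delimited")
    write_summary(report, out_dir / "summary.txt", format="key-value")
    manifest = {
        "protein": protein.name,
        "config": str(config_path),
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in sorted(set(input_files))},
        "failures": report.failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if plot:
        _write_plots(report, out_dir)
    return report


def _write_plots(report: StabilityReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    numeric = [(k, v) for k, (v, _) in report.values.items() if isinstance(v, (int, float))]
    if not numeric:
        return
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(numeric) + 1))
    ax.barh([k for k, _ in numeric], [v for _, v in numeric])
    ax.set_xlabel("fitted value")
    ax.set_title(report.protein)
    fig.tight_layout()
    fig.savefig(out_dir / "summary.png", dpi=100)
    plt.close(fig)


def write_summary(report: StabilityReport, path: str | Path, format: str = "delimited") -> None:
    """Write the aggregated report; one decimal place on every number,
    deterministic row order mirroring the summary-table layout."""
    if not report.values:
        raise ValueError("report is empty: no stage produced a value")
    path = Path(path)
    rows = []
    for key, unit in REPORT_FIELDS:
        if key not in report.values:
            continue
        value, se = report.values[key]
        rows.append((key, value, se, unit))
    if format == "delimited":
        lines = ["parameter,value,uncertainty,unit"]
        for key, value, se, unit in rows:
            lines.append(f"{key},{_fmt(value)},{_fmt(se)},{unit}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "key-value":
        lines = [f"# {report.protein}"]
        for key, value, se, unit in rows:
            sfx = f" +/- {_fmt(se)}" if isinstance(se, float) and se == se else ""
            lines.append(f"{key} = {_fmt(value)}{sfx} {unit}".rstrip())
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown summary format {format!r}")


def _fmt(value) -> str:
    if isinstance(value, str):
        return value
    if value != value:  # NaN
        return ""
    return f"{value:.1f}"
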