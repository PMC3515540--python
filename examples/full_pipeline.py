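"""End-to-end pipeline run on a complete synthetic input bundle.

Generates every input class (chemical unfolding curve, DSC scans,
Kirchhoff series, thermal CD trace, sedimentation and molar-mass series,
quenching series) from known truths, writes them as the delimited text
files the pipeline reads, drives the whole analysis from one YAML
config, and prints the aggregated stability report.
"""

import tempfile
from pathlib import Path

import numpy as np
import yaml

from foldstab import SimSpec, run_pipeline
from foldstab import io as fio
from foldstab.equilibrium import ThreeStateParams
from foldstab.simulate import (
    gen_chem_unfold,
    gen_dsc,
    gen_kirchhoff_series,
    gen_logistic_series,
    gen_quench_series,
)
from foldstab.thermal import TransitionFit

workdir = Path(tempfile.mkdtemp(prefix="foldstab_demo_"))
seed = 11

chem_truth = ThreeStateParams(7.2, 2.1, 8.0, 1.7, Y_N=0.0, Y_I=0.5, Y_U=1.0)
dsc_truth = [TransitionFit(59.0, 154.0, 154.0), TransitionFit(67.7, 29.5, 29.5)]

fio.write_chem_curve(gen_chem_unfold(SimSpec(
    "chem_three_state", {"params": chem_truth}, noise_sd=0.005, seed=seed)),
    workdir / "chem.csv")
scans = gen_dsc(SimSpec("dsc_two_transition",
                        {"transitions": dsc_truth, "reversibility": 0.97},
                        noise_sd=0.02, seed=seed))
fio.write_thermogram(scans[0], workdir / "dsc_scan1.csv")
fio.write_thermogram(scans[1], workdir / "dsc_scan2.csv")
fio.write_kirchhoff_series(np.linspace(0, 2, 8), gen_kirchhoff_series(SimSpec(
    "kirchhoff_line",
    {"dCp": 4.0, "dH_ref": 154.0, "Tm_ref_C": 59.0, "Tm_shifts_C": np.linspace(0, 8, 8)},
    noise_sd=1.0, seed=seed)), workdir / "kirchhoff1.csv")
fio.write_thermal_cd(gen_logistic_series(SimSpec(
    "logistic_series", {"lower": 0.0, "upper": 1.0, "midpoint": 60.1, "width": 2.0},
    grid=np.arange(20.0, 90.0, 0.5), noise_sd=0.01, seed=seed), kind="thermal_cd"),
    workdir / "cd.csv")
fio.write_sed_series(gen_logistic_series(SimSpec(
    "logistic_series", {"lower": 3.5, "upper": 2.0, "midpoint": 3.4, "width": 0.25},
    noise_sd=0.02, seed=seed), kind="sed"), workdir / "sed.csv")
fio.write_mm_series(gen_logistic_series(SimSpec(
    "logistic_series", {"lower": 78.0, "upper": 39.0, "midpoint": 3.5, "width": 0.25},
    noise_sd=0.5, seed=seed), kind="mm"), workdir / "mm.csv")
fio.write_quench_series(gen_quench_series(SimSpec(
    "stern_volmer", {"F0": 100.0, "Ksv": 11.1}, noise_sd=0.005, seed=seed)),
    workdir / "quench.csv")

config = workdir / "config.yaml"
config.write_text(yaml.safe_dump({
    "protein": {"name": "demo-dimer", "n_residues_ctd": 235, "n_residues_nterm": 121,
                "monomer_mass_kDa": 39.0},
    "seed": seed,
    "output_dir": str(workdir / "out"),
    "stages": {
        "chem": {"curve": "chem.csv"},
        "dsc": {"scans": ["dsc_scan1.csv", "dsc_scan2.csv"], "n_transitions": 2},
        "kirchhoff": {"transition1": "kirchhoff1.csv"},
        "thermal_cd": {"curve": "cd.csv"},
        "hydro": {"sed_series": "sed.csv", "mm_series": "mm.csv"},
        "fluor": {"quench": "quench.csv"},
    },
}))

report = run_pipeline(config)
print(f"\naggregated report for {report.protein}:")
for key, (value, se) in report.values.items():
    if isinstance(value, float):
        line = f"  {key:22s} {value:8.2f}"
        if se == se:
            line += f" +/- {se:.2f}"
        print(line)
    else:
        print(f"  {key:22s} {value}")
print(f"\nsummary files written under {workdir / 'out'}")
print("Every value above was recovered from synthetic data generated with")
print("known truths; compare e.g. Tm_1 to 59.0 and Cm_AUC to 3.4.")
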