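# Methods

`foldstab` analyses the equilibrium stability of oligomeric proteins —
the motivating system is the homodimeric yeast Hsp40 co-chaperone Sis1
and its domain-deletion/chimeric variants — from four instrument
families: chemical unfolding followed by circular dichroism (CD),
differential scanning calorimetry (DSC), hydrodynamics (sedimentation
velocity and SEC-MALLS), and tryptophan fluorescence.  This note
documents the models, their assumptions, the defaults, and the limits of
what the synthetic-data tests demonstrate.

## Three-state chemical unfolding (equilibrium module)

The unfolding scheme is N ⇌ I ⇌ U with a linear free-energy dependence
on denaturant concentration *d* (linear extrapolation method):

    ΔG_NI(d) = ΔG°_NI − m_NI·d        K₁ = exp(−ΔG_NI(d)/RT)
    ΔG_IU(d) = ΔG°_IU − m_IU·d        K₂ = exp(−ΔG_IU(d)/RT)

    y(d) = (Y_N + Y_I·K₁ + Y_U·K₁K₂) / (1 + K₁ + K₁K₂)

with R = 1.987×10⁻³ kcal/(mol·K) and T defaulting to 293.15 K (20 °C).
Species fractions are computed in log space and always sum to 1 to
machine precision.  Transition midpoints are the ratios Cm = ΔG°/m.

**Assumptions and limitations.**  The native state is a dimer, but the
model carries no explicit protein-concentration term: it is the
concentration-independent approximation under which the reference
parameter values were derived, appropriate when curves at a fixed
protein concentration are compared between constructs.  A
dissociation-coupled model (ΔG depending on [P]) is deliberately out of
scope.  The m-values absorb the concentration dependence; reported ΔG°
values should be compared only across constructs measured at matched
concentration.

**Fitting.**  Nonlinear least squares (Levenberg–Marquardt via lmfit).
The transitions are parameterized as (Cm_NI, ΔCm, m_NI, m_IU) with
ΔCm > 0, so Cm_NI < Cm_IU holds by construction and ΔG = m·Cm is exact
for every returned fit.  Bounds: m ∈ (0, 10] kcal/mol/M,
ΔG ∈ (0, 50] kcal/mol; plateau signals free.  Self-initialization takes
Y_N/Y_U from the first/last 10 % of points, midpoint guesses from the
25 %/75 % crossings of a lightly smoothed signal, and m = 2 kcal/mol/M.
The intermediate plateau Y_I is free by default; `fix_Y_I` pins it for
the constrained protocol.  Standard errors come from the local curvature
(covariance) of the objective; the error of the derived Cm_IU includes
the Cm_NI–ΔCm covariance.  Both raw-ellipticity and fraction-unfolded
curves are accepted; `raw_to_fraction` normalizes against linear
native/unfolded baselines and rejects baselines that cross.

## DSC analysis (thermal module)

**Excess heat capacity model.**  Each unfolding transition is an
independent quasi-two-state peak with separate calorimetric and van't
Hoff enthalpies ("non-two-state" deconvolution):

    K(T) = exp(−(ΔH_vH/R)(1/T − 1/Tm))
    Cp_exc(T) = ΔH_cal·ΔH_vH/(R·T²) · K/(1+K)²

evaluated as ¼·sech²(ln K/2) for overflow safety.  Its temperature
integral equals ΔH_cal (verified to 1 % over ΔH_vH ∈ [30, 300] kcal/mol);
the peak height at Tm is ΔH_cal·ΔH_vH/(4RTm²).  A thermogram is fitted
as the sum of 1–3 such peaks.  ΔH_vH is free by default; an option pins
ΔH_vH = ΔH_cal because the constraint status of the reference analysis
is not recorded.  Because overlapping unequal transitions make the
least-squares surface multimodal, the fit multistarts from an
equal-area split plus peak-anchored candidates and keeps the lowest-χ²
solution.

**Baseline.**  Straight lines are fitted to user-chosen pre- and
post-transition windows and joined by a progress-weighted connection
(weight = cumulative normalized excess-heat area, iterated three times),
the calorimetric standard; a linear chord is available.  Caveat: a very
broad transition (ΔH_vH ≲ 30 kcal/mol has a half-width of tens of °C)
may not return to baseline inside the scan, in which case a
post-transition window overlaps the tail and baseline subtraction
distorts the deconvolution.  The pipeline therefore treats input scans
as already baseline-treated excess heat capacity unless windows are
explicitly declared.

**Reversibility.**  The rescan-to-first-scan ratio of chord-corrected
excess-heat areas over the shared temperature window; ≥ 0.95 classifies
the transition as reversible.  Only first scans enter the thermodynamic
fits; reversibility is a separate QC gate.

**Kirchhoff ΔCp.**  ΔH_cal(Tm) = ΔH_ref + ΔCp·(Tm − Tm_ref), ΔCp
temperature-independent, fitted by unweighted ordinary least squares to
(Tm, ΔH_cal) pairs from denaturant-perturbed scans (urea 0.25–2 M shifts
Tm by several °C; urea concentration is metadata, never a regression
variable).  Tm_ref defaults to the highest (zero-urea) Tm.  Weighted
regression is not used because per-point errors of the source series are
not recorded.  `per_residue_dcp` reports 1000·ΔCp/n to one decimal
(cal/mol/K per residue), the quantity used to infer how much surface a
domain exposes on unfolding.

**Thermal CD.**  Tm_CD comes from the shared four-parameter logistic
(below).  Non-monotonic traces trigger a warning, not a failure, since
aggregation artifacts commonly dent the upper plateau.

## Shared logistic transition (sigmoid module)

All "sigmoidal" midpoints — Tm_CD, Cm_AUC, Cm_SEC-MALLS — use one form,

    y(x) = lower + (upper − lower)/(1 + exp(−(x − midpoint)/width)),

so midpoints are directly comparable across observables.  The fit is
direction-agnostic; a flat series raises a fit failure; the midpoint
standard error comes from the covariance matrix.  A curve that does not
span both plateaus fits without error but returns a large se_midpoint,
which is the documented flag for an unresolved transition.

## Hydrodynamics

**s20,w standardization.**

    s20,w = s_obs · (η_buffer/η_water,20) · (1 − v̄ρ_water,20)/(1 − v̄ρ_buffer)

with η_water,20 = 1.002 cP, ρ_water,20 = 0.99823 g/mL.  The correction
is the identity in water at 20 °C and fails loudly when 1 − v̄ρ ≤ 0.

**Urea buffer properties.**  Solvent density uses an apparent-molar-
volume model, ρ(M,T) = ρ_w(T) + (M_urea/1000)·M·(1 − ρ_w(T)·0.763),
with urea's standard apparent specific volume 0.763 mL/g; relative
viscosity uses the Kawahara–Tanford cubic
1 + 0.0555·M + 0.00308·M² + 0.000202·M³ (J. Biol. Chem. 241:3228,
1966), multiplying the water viscosity at the experiment temperature.
Water references: Kell (1975) density equation and the Vogel viscosity
equation.  Coefficients ship as versioned package data
(`data/urea_solution.yaml`); valid range 0–9 M.  These empirical
relations replace the desktop solvent-correction program used
historically for this task while matching its physics.

**Partial specific volume.**  Mass-weighted mean of the Cohn–Edsall
consensus residue values (`data/residue_vbar.csv`).  Typical proteins
fall in 0.70–0.76 mL/g; the implementation accepts any standard
sequence and rejects unknown letters by position.

**Concentration extrapolation.**  s20,w versus protein concentration is
modeled as linear only (250–750 µg/mL is well inside the linear
regime); the intercept at 0 mg/mL is s⁰20,w.  A single concentration is
returned as-is with infinite standard error.

**Oligomer classification.**  mass ratio within 2·tol of 2 → dimer,
within tol of 1 → monomer, else other; tol defaults to 0.15 (the dimer
window is proportionally wider).  The tolerance is a pipeline choice,
not a value from the reference analysis.

## Fluorescence

Center of spectral mass ⟨λ⟩ = Σλᵢfᵢ/Σfᵢ — scale-invariant and always
inside the sampled wavelength range.  Stern–Volmer analysis regresses
F₀/F on [Q] (acrylamide, 0–0.1 M).  The regression keeps a free
intercept by default and reports it as a linearity diagnostic
(expected ≈ 1 for purely collisional quenching); a forced-intercept mode
pins it at 1 to match the collisional relation exactly, and that mode is
what the reference-value recomputation uses.

## Synthetic data generator

Generators emulate the statistical structure each instrument produces:
three-state sigmoid curves with Gaussian noise, summed two-state DSC
peaks on an optional linear instrumental baseline with a stated rescan
reversibility, collinear (Tm, ΔH) series, logistic hydrodynamic
transitions, hyperbolic quenching decays with multiplicative noise, and
Gaussian emission bands.  Default grids copy the experimental designs:
urea 0–6 M step 0.1 (CD), 15–90 °C step 0.25 (DSC), 0–100 mM step 10
(quenching).  Each SimSpec owns a seeded generator; every output array
draws from its own deterministic sub-stream
(`SeedSequence(seed, spawn_key=(k,))`), so adding an output (e.g. a
rescan) never shifts existing draws, and identical specs are
bit-reproducible.

What the generators do **not** emulate: thermal lag and scan-rate
kinetics, photobleaching and inner-filter effects, aggregation above
90 °C, baseline drift curvature, and concentration-dependent dimer
dissociation.  Passing recovery tests therefore demonstrate estimator
correctness and precision under the assumed noise model, not robustness
to instrument artifacts.

## Reference-value recomputation

`scripts/acceptance.py` regenerates every headline quantity from
scratch: exact ratio identities (Cm = ΔG/m, per-residue ΔCp) and
parameter recoveries from synthetic data generated at the documented
study conditions (noise sd 0.01 fraction units for CD curves, 0.05
kcal/mol/K for DSC, 2 kcal/mol for Kirchhoff enthalpies, 1 %
multiplicative for quenching, 0.05 S for sedimentation).  Curves whose
source protocol averaged three independent experiments (CD chemical
unfolding, DSC thermograms, the denaturant-perturbed enthalpy series)
are simulated as three seeded replicates and averaged before fitting.
Problem sizes: 61-point urea curves, 301-point thermograms, 8-condition
Kirchhoff series, 11-point quenching and sedimentation series — the
instruments' own grids, so no scaling down was needed.

## Numerical choices

- Temperatures are converted to kelvin internally (T_K = T_C + 273.15);
  every user-facing value is in °C.
- Boltzmann weights are computed in log space (max-subtraction) so no
  parameter regime overflows.
- Trapezoidal integration everywhere an area is needed; on the 0.25 °C
  default grid the two-state peak integral is accurate to well under 1 %.
- Ties/ordering: DSC transitions are returned Tm-ascending and must be
  separated by > 1 °C; the three-state fit enforces Cm_NI < Cm_IU by
  parameterization rather than by penalty.
- Degenerate inputs fail loudly: flat logistic series, all-zero spectra,
  rank-deficient Kirchhoff input, non-positive quench intensities,
  coincident normalization baselines, and buoyancy ≤ 0 all raise
  ValueError with a description of the offending data.

## Known limitations

- No global (denaturant × temperature) fitting; each axis is analysed
  separately as in the source protocol.
- ΔCp from the Kirchhoff slope assumes ΔCp is temperature-independent
  over the perturbed Tm range (~8 °C), the standard approximation.
- The dimer-dissociation coupling of the first transition is not
  modeled explicitly (see above); Cm values remain the robust
  comparator between constructs.
- Sedimentation analysis starts from apparent s values; continuous c(S)
  deconvolution and frictional-ratio modeling are upstream tools'
  responsibility and out of scope.
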