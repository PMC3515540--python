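# Empirical coefficients for aqueous urea solution properties.
#
# viscosity_relative: cubic in urea molarity for the viscosity of aqueous
#   urea relative to water at the same temperature (Kawahara & Tanford,
#   J. Biol. Chem. 241, 3228 (1966)):
#     eta/eta_water = 1 + a1*M + a2*M^2 + a3*M^3
# density: apparent-molar-volume model of urea in water:
#     rho(M, T) = rho_water(T) + (M_urea/1000) * M * (1 - rho_water(T)*vbar_urea)
#   with the urea molar mass in g/mol and the standard apparent specific
#   volume of urea in water, 0.763 mL/g.
viscosity_relative:
  a1: 0.0555
  a2: 0.00308
  a3: 0.000202
density:
  urea_molar_mass_g_mol: 60.056
  urea_apparent_specific_volume_mL_g: 0.763
valid_molarity_range: [0.0, 9.0]
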