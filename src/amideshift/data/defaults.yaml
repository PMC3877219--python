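# amideshift default configuration (overridable via a user YAML file)
hydrogen_bond_gate:
  r_max_angstrom: 2.5
  angle_min_deg: 120.0
backbone_scale:
  a: 1.0
  b: 0.0
# Primary-bond value for solvent-exposed amide protons (water model,
# energy-minimized N-methylacetamide/water geometry), ppm.
water_term_ppm: 2.07
# Gaussian likelihood standard deviations per primary-bond acceptor class, ppm.
sigma_ppm:
  BACKBONE_AMIDE: 0.3
  SIDECHAIN_AMIDE: 0.5
  CARBOXYLATE: 0.8
  ALCOHOL: 0.8
  NONE: 1.2
temperature_kelvin: 300.0
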