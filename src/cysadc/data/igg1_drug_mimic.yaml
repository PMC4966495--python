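# Bundled IgG1 drug-mimic conjugate configuration (SYNTHETIC fixture).
# Chain base masses are back-derived from the observed conjugated sub-unit
# masses (light + 1 drug = 23580.0 Da, heavy(G0F) + 3 drugs = 51630.6 Da);
# the real mAb sequence is proprietary.
chain_species:
  light:
    role: light
    reduced_average_mass: 23203.54
  heavy:
    role: heavy
    reduced_average_mass: 50501.22
    glycoforms:
      - {name: G0F, mass_delta: 0.0}
      - {name: G1F, mass_delta: 162.14}
chain_instances:
  L1: light
  L2: light
  H1: heavy
  H2: heavy
drug:
  formula: C23H24N2O3
  average_mass: 376.46
bonds:
  - id: LC-HC-1
    endpoints:
      - {chain: L1, site_class: LC-HC}
      - {chain: H1, site_class: LC-HC}
  - id: LC-HC-2
    endpoints:
      - {chain: L2, site_class: LC-HC}
      - {chain: H2, site_class: LC-HC}
  - id: hinge-1
    endpoints:
      - {chain: H1, site_class: hinge}
      - {chain: H2, site_class: hinge}
  - id: hinge-2
    endpoints:
      - {chain: H1, site_class: hinge}
      - {chain: H2, site_class: hinge}
# Symmetry generators: the two-fold molecular flip and the exchange of the
# two chemically equivalent hinge bonds.  Each generator lists the bond-id
# pairs it swaps.
symmetries:
  - [[LC-HC-1, LC-HC-2], [hinge-1, hinge-2]]
  - [[hinge-1, hinge-2]]
disulfide_mass_decrement: 2.016
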