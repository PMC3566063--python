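# Mitral cell: four compartments (glomerular tuft - primary dendrite -
# soma - lateral/secondary dendrite), reduced-model lineage.
#
# Maximum conductance densities (S/cm^2) per compartment follow the
# published parameter table; row identities follow the source model's
# channel set (fast Na, slow K, fast delayed rectifier, Ca-activated K,
# A-type K, high-threshold L-type Ca).  Passive constants are calibration
# values (see docs/methods.md).

cell: mitral
geometry:
  - {name: soma, length_um: 100.0, diameter_um: 16.2, parent: null}
  - {name: primary, length_um: 100.0, diameter_um: 104.4, parent: soma}
  - {name: tuft, length_um: 100.0, diameter_um: 26.7, parent: primary}
  - {name: lateral, length_um: 100.0, diameter_um: 170.9, parent: soma}

passive:
  axial_resistivity: 70.0
  specific_capacitance: 1.25
  leak_conductance_density: 2.5e-5
  leak_reversal: -65.0
  resting_potential: -65.0

channel_map:
  Na: mit_na
  Ks: mit_ks
  Kfast: mit_kfast
  KCa: mit_kca
  KA: mit_ka
  LCa: mit_lca

densities:
  Na:    {soma: 0.1532, tuft: 0.0, primary: 0.00134, lateral: 0.0226}
  Ks:    {soma: 0.028, tuft: 0.02, primary: 0.00174, lateral: 0.0}
  Kfast: {soma: 0.1956, tuft: 0.0, primary: 0.00123, lateral: 0.033}
  KCa:   {soma: 0.0142, tuft: 0.0, primary: 0.0, lateral: 0.0}
  KA:    {soma: 0.00587, tuft: 0.0, primary: 0.0, lateral: 0.0}
  LCa:   {soma: 0.004, tuft: 0.0095, primary: 0.0022, lateral: 0.0}

calcium_pool:
  shell_depth_um: 0.1
  removal_tau_ms: 10.0
  resting_mM: 2.4e-4
  external_mM: 2.0
  floor_mM: 1.0e-8

synapse_sites: [primary, lateral, tuft]
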