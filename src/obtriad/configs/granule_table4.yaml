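# Granule cell: three compartments (peripheral dendrite, soma, deep
# dendrite), reduced-model lineage.  Densities (S/cm^2) per the published
# table; rows follow the source model's channel set (fast Na, delayed
# rectifier, A-type K, M-type K).  Passive constants are calibration
# values (see docs/methods.md).

cell: granule
geometry:
  - {name: soma, length_um: 50.0, diameter_um: 0.72321, parent: null}
  - {name: peripheral, length_um: 50.0, diameter_um: 16.378, parent: soma}
  - {name: deep, length_um: 50.0, diameter_um: 36.075, parent: soma}

passive:
  axial_resistivity: 70.0
  specific_capacitance: 1.0
  leak_conductance_density: 2.0e-5
  leak_reversal: -65.0
  resting_potential: -65.0

channel_map:
  Na: grc_na
  Kdr: grc_kdr
  KA: grc_ka
  KM: grc_km

densities:
  Na:  {soma: 0.1611, peripheral: 0.1355, deep: 0.0}
  Kdr: {soma: 0.1313, peripheral: 0.0243, deep: 0.0}
  KA:  {soma: 0.1334, peripheral: 0.0, deep: 0.0}
  KM:  {soma: 0.0088, peripheral: 0.0, deep: 0.0}

synapse_sites: [peripheral]
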